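"""Synthetic six-library small-RNA runs with known planted truth.

The generator emulates one sequencing run carrying up to six barcoded
libraries of 5-45-nt inserts flanked by the library adapters: insert lengths
follow a peaked distribution (peaks at 14/15/16, 22/23, 26, 31 and 37 nt by
default), inserts are substrings of a category-annotated reference
transcript set with Zipf-skewed position preferences (real strata are
dominated by a few processing products), a configurable number of species
are planted as two-group differentials at a chosen fold change, a couple of
species are planted as uniformly abundant across samples, and a fraction of
reads are adapter artifacts (adapter dimers and 5'-adapter fragments).
Every emitted insert is tallied into an exact per-sample truth table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._rna import reverse_complement_rna as _revcomp
from ._rna import to_dna
from .annotation import CATEGORIES, ReferenceSet, Transcript
from .preprocess import (
    DEFAULT_BARCODES,
    FIVE_PRIME_ADAPTER_CORE,
    FIVE_PRIME_REMNANT,
    THREE_PRIME_ADAPTER,
    AdapterConfig,
    SampleLibrary,
    five_prime_adapters,
)

#: 5' 31-mer of Y4 RNA, the dominant plasma species; seeds the Y4 surrogate.
Y4_FRAGMENT_31 = "GGCUGGUCCGAUGGUAGUGGGUUAUCAGAAC"
#: 14-nt 28S rRNA fragment embedded in the rDNA-unit surrogate.
RRNA_28S_FRAGMENT_14 = "CGCGACCUCAGAUC"

_DEFAULT_PEAK_BONUS = {14: 5, 15: 6, 16: 5, 22: 7, 23: 6, 26: 4, 31: 11, 37: 3}

_DEFAULT_MIX = {
    "mRNA": 0.38, "scRNA": 0.25, "miRNA": 0.15, "lncRNA": 0.08,
    "rRNA": 0.06, "tRNA": 0.03, "snRNA": 0.02, "srpRNA": 0.01,
    "piRNA": 0.01, "snoRNA": 0.01,
}

#: Lengths used for planted differential species, peak lengths first.
_DIFFERENTIAL_LENGTHS = (22, 23, 26, 31, 37, 20, 24, 28, 30, 33)
#: Lengths used for planted uniformly-abundant species.
_ABUNDANT_LENGTHS = (14, 15, 16, 13, 17, 18)


def default_length_peaks() -> list[tuple[int, float]]:
    return [(length, 1.0 + _DEFAULT_PEAK_BONUS.get(length, 0.0))
            for length in range(5, 46)]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic run."""

    seed: int = 0
    n_samples: int = 6
    reads_per_sample: int = 10_000
    group_assignment: dict[str, str] = field(default_factory=dict)
    length_peaks: list[tuple[int, float]] = field(
        default_factory=default_length_peaks)
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX))
    n_planted_differential: int = 4
    differential_fold_change: float = 20.0
    n_planted_abundant: int = 2
    base_freq_more: float = 0.005     # group-A stratum share of "more" species
    base_freq_less: float = 0.08      # group-A stratum share of "less" species
    abundant_freq: float = 0.10       # stratum share of uniformly abundant species
    artifact_fraction: float = 0.05
    error_rate: float = 0.0
    zipf_exponent: float = 1.2
    barcode_table: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BARCODES))

    def __post_init__(self):
        if self.n_samples < 1 or self.n_samples > len(self.barcode_table):
            raise ValueError("n_samples exceeds available barcodes")
        if len(set(self.barcode_table.values())) != len(self.barcode_table):
            raise ValueError("barcodes must be pairwise distinct")
        bad = set(self.category_mix) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories in mix: {sorted(bad)}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category mix sums to {total}, not 1")
        for length, w in self.length_peaks:
            if not 5 <= length <= 45:
                raise ValueError(f"length {length} outside [5, 45]")
            if w < 0:
                raise ValueError("length weights must be nonnegative")
        if self.differential_fold_change <= 1:
            raise ValueError("fold change must exceed 1")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must lie in [0, 1]")
        if not self.group_assignment:
            ids = self.sample_ids
            half = len(ids) // 2
            self.group_assignment = {
                sid: ("A" if i < half else "B") for i, sid in enumerate(ids)}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.barcode_table)[: self.n_samples]

    def group(self, sample_id: str) -> str:
        return self.group_assignment[sample_id]


@dataclass
class PlantedTruth:
    """Exact record of what was emitted."""

    differential_species: list[tuple[str, str]]       # (sequence, more|less)
    abundant_species: list[str]
    per_sample_insert_counts: dict[str, Counter]
    artifact_reads: set[str] = field(default_factory=set)

    def libraries(self, spec: SyntheticSpec) -> dict[str, SampleLibrary]:
        """Truth counts wrapped as SampleLibrary objects."""
        return {
            sid: SampleLibrary(sid, group=spec.group(sid),
                               counts=Counter(self.per_sample_insert_counts[sid]))
            for sid in self.per_sample_insert_counts
        }


# --------------------------------------------------------------------------
# reference construction

_BASES = np.array(list("ACGU"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_reference_set(spec: SyntheticSpec) -> ReferenceSet:
    """Fabricate >=1 transcript per category with nonzero mix proportion.

    Special members (present when their category has nonzero proportion):
    an rDNA repeating-unit surrogate carrying the 14-nt 28S fragment, and a
    94-nt Y4-like transcript whose 5' 31-mer is the Y4 fragment.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([spec.seed, 101])
    transcripts: list[Transcript] = []
    rdna_id: Optional[str] = None
    for cat in CATEGORIES:      # fixed order keeps output byte-stable
        if spec.category_mix.get(cat, 0.0) <= 0.0:
            continue
        if cat == "rRNA":
            seq = _random_seq(rng, 600)
            seq = seq[:100] + RRNA_28S_FRAGMENT_14 + seq[100 + 14:]
            rdna_id = "rDNA_repeat_surrogate"
            transcripts.append(Transcript(rdna_id, seq, frozenset({"rRNA"})))
            transcripts.append(Transcript(
                "rRNA_5S_surrogate", _random_seq(rng, 150), frozenset({"rRNA"})))
        elif cat == "scRNA":
            y4 = Y4_FRAGMENT_31 + _random_seq(rng, 94 - len(Y4_FRAGMENT_31))
            transcripts.append(Transcript(
                "Y4_RNA_surrogate", y4, frozenset({"scRNA"})))
            transcripts.append(Transcript(
                "scRNA_surrogate_2", _random_seq(rng, 150), frozenset({"scRNA"})))
        else:
            for i in (1, 2):
                transcripts.append(Transcript(
                    f"{cat}_surrogate_{i}", _random_seq(rng, 150),
                    frozenset({cat})))
    return ReferenceSet(transcripts, rdna_id)


# --------------------------------------------------------------------------
# stratum models: per length, the background species pool and probabilities

_BASE_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGU"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """(n, L) uint8 array of base codes for equal-length sequences."""
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _BASE_CODE[raw.reshape(len(seqs), -1)]


def _window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer codes of every length-k window of each row."""
    n, L = arr.shape
    if L < k:
        return np.empty((n, 0), dtype=np.int64)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = np.empty((n, L - k + 1), dtype=np.int64)
    for o in range(L - k + 1):
        out[:, o] = arr[:, o:o + k].astype(np.int64) @ pow4
    return out


def _neighbor_codes(seq: str, max_mm: int) -> np.ndarray:
    """Integer codes of a sequence and all its <=max_mm-substitution variants."""
    k = len(seq)
    base = _encode([seq])[0].astype(np.int64)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = {int(base @ pow4)}
    if max_mm >= 1:
        for i in range(k):
            for b in range(4):
                if b != base[i]:
                    codes.add(int(base @ pow4 + (b - base[i]) * pow4[i]))
    if max_mm >= 2:
        raise NotImplementedError("only <=1 mismatch neighborhoods needed")
    return np.array(sorted(codes), dtype=np.int64)


def _clean_mask(species: list[str], config: AdapterConfig) -> np.ndarray:
    """Which species the preprocessor can round-trip exactly.

    A species is rejected when (a) the 3'-adapter seed occurs, within the
    trimmer's mismatch tolerance, anywhere in the assembled read before the
    true adapter start — including windows spanning the 5' remnant/barcode
    junction and the insert/adapter junction — which would mistrim it, or
    (b) it carries a local 5'-adapter match, which the artifact filter would
    drop. Keeping such species out of the pool makes noise-free runs exactly
    recoverable.
    """
    if not species:
        return np.zeros(0, dtype=bool)
    seed = config.adapter_seed
    k = len(seed)
    seed_nbrs = _neighbor_codes(seed, config.seed_mismatch)
    ok = np.ones(len(species), dtype=bool)

    for barcode in config.barcode_table.values():
        prefix = FIVE_PRIME_REMNANT + barcode
        ext = [prefix + s + seed for s in species]
        codes = _window_codes(_encode(ext), k)
        # exclude the final window: the genuine adapter occurrence
        hit = np.isin(codes[:, :-1], seed_nbrs).any(axis=1)
        ok &= ~hit

    # local 5'-adapter similarity (the artifact filter's rule)
    L = config.artifact_min_match_len
    if len(species[0]) >= L:
        ref_codes: set[int] = set()
        for ad in five_prime_adapters(config.barcode_table):
            for subj in (ad, _revcomp(ad)):
                for o in range(len(subj) - L + 1):
                    ref_codes.update(
                        _neighbor_codes(subj[o:o + L],
                                        config.artifact_mismatch).tolist())
        ref_arr = np.array(sorted(ref_codes), dtype=np.int64)
        codes10 = _window_codes(_encode(species), L)
        ok &= ~np.isin(codes10, ref_arr).any(axis=1)
    return ok


class _StratumModel:
    """Background species (sequences + sampling probabilities) of one length."""

    __slots__ = ("length", "species", "probs")

    def __init__(self, length: int, species: list[str], probs: np.ndarray):
        self.length = length
        self.species = species
        self.probs = probs


def build_stratum_models(spec: SyntheticSpec, refs: ReferenceSet,
                         config: Optional[AdapterConfig] = None,
                         ) -> dict[int, _StratumModel]:
    if config is None:
        config = AdapterConfig(barcode_table=dict(spec.barcode_table))
    rng = np.random.default_rng([spec.seed, 202])
    by_cat: dict[str, list[Transcript]] = {c: [] for c in CATEGORIES}
    for t in refs:
        for c in t.categories:
            by_cat[c].append(t)
    models: dict[int, _StratumModel] = {}
    for length, _w in spec.length_peaks:
        if length in models:
            continue
        weights: dict[str, float] = {}
        for cat in CATEGORIES:
            mix = spec.category_mix.get(cat, 0.0)
            txs = by_cat[cat]
            if mix <= 0.0 or not txs:
                continue
            usable = [t for t in txs if len(t.sequence) >= length]
            if not usable:
                continue
            for t in usable:
                npos = len(t.sequence) - length + 1
                # Zipf-skewed position preference under a seeded permutation:
                # a few "hotspot" products dominate each transcript.
                ranks = rng.permutation(npos)
                zw = (ranks + 1.0) ** (-spec.zipf_exponent)
                zw /= zw.sum()
                w_tx = mix / len(usable)
                for pos in range(npos):
                    s = t.sequence[pos: pos + length]
                    weights[s] = weights.get(s, 0.0) + w_tx * zw[pos]
        all_species = sorted(weights)
        mask = _clean_mask(all_species, config)
        clean = {s: weights[s] for s, keep in zip(all_species, mask) if keep}
        if not clean:
            continue
        species = sorted(clean, key=lambda s: (-clean[s], s))
        probs = np.array([clean[s] for s in species])
        probs /= probs.sum()
        models[length] = _StratumModel(length, species, probs)
    return models


# --------------------------------------------------------------------------
# planting and sampling

@dataclass
class _Planted:
    sequence: str
    length: int
    kind: str               # "more" | "less" | "abundant"
    freq_a: float
    freq_b: float


def _select_planted(spec: SyntheticSpec,
                    models: dict[int, _StratumModel]) -> list[_Planted]:
    planted: list[_Planted] = []
    used: set[str] = set()

    def take(length: int, offset: int) -> Optional[str]:
        model = models.get(length)
        if model is None:
            return None
        # mid-ranked pool species: abundant enough to be realistic carriers,
        # deterministic, and removed from the background afterwards
        for s in model.species[offset:]:
            if s not in used:
                used.add(s)
                return s
        return None

    directions = ["more", "less"]
    for i in range(spec.n_planted_differential):
        length = _DIFFERENTIAL_LENGTHS[i % len(_DIFFERENTIAL_LENGTHS)]
        seq = take(length, 10 + i)
        if seq is None:
            raise ValueError(f"no pool species available at length {length}")
        direction = directions[i % 2]
        if direction == "more":
            fa = spec.base_freq_more
            fb = fa * spec.differential_fold_change
        else:
            fa = spec.base_freq_less
            fb = fa / spec.differential_fold_change
        planted.append(_Planted(seq, length, direction, fa, fb))
    for i in range(spec.n_planted_abundant):
        length = _ABUNDANT_LENGTHS[i % len(_ABUNDANT_LENGTHS)]
        seq = take(length, 10 + i)
        if seq is None:
            raise ValueError(f"no pool species available at length {length}")
        planted.append(_Planted(seq, length, "abundant",
                                spec.abundant_freq, spec.abundant_freq))
    return planted


def simulate_counts(spec: SyntheticSpec, refs: ReferenceSet,
                    models: Optional[dict[int, _StratumModel]] = None,
                    ) -> tuple[dict[str, SampleLibrary], PlantedTruth]:
    """Draw per-sample insert multisets with exact truth, no read emission.

    The per-sample insert counts returned here are exactly what
    :func:`simulate_libraries` will expand into reads (error rate 0).
    """
    if spec.reads_per_sample == 0 and spec.n_planted_differential > 0:
        raise ValueError("cannot plant differentials with zero reads per sample")
    if models is None:
        models = build_stratum_models(spec, refs)
    planted = _select_planted(spec, models)
    planted_by_len: dict[int, list[_Planted]] = {}
    for p in planted:
        planted_by_len.setdefault(p.length, []).append(p)

    # aggregated length distribution (duplicate entries summed)
    length_w: dict[int, float] = {}
    for length, w in spec.length_peaks:
        length_w[length] = length_w.get(length, 0.0) + w
    lengths = sorted(length_w)
    lw = np.array([length_w[k] for k in lengths], dtype=float)
    lw /= lw.sum()

    # per-length sampling vectors, shared across samples (built once)
    stratum: dict[int, tuple[list[str], dict[str, np.ndarray]]] = {}
    for length in lengths:
        model = models.get(length)
        plist = planted_by_len.get(length, [])
        planted_seqs = {p.sequence for p in plist}
        if model is None and not plist:
            continue
        bg_species, bg_probs = [], np.array([])
        if model is not None:
            keep = [i for i, s in enumerate(model.species)
                    if s not in planted_seqs]
            bg_species = [model.species[i] for i in keep]
            bg_probs = model.probs[keep]
            bg_probs = bg_probs / bg_probs.sum()
        seqs = [p.sequence for p in plist] + bg_species
        pvecs = {}
        for grp in ("A", "B"):
            pf = np.array([(p.freq_a if grp == "A" else p.freq_b)
                           for p in plist])
            if bg_species:
                vec = np.concatenate([pf, bg_probs * (1.0 - pf.sum())])
            else:
                vec = pf
            pvecs[grp] = vec / vec.sum()
        stratum[length] = (seqs, pvecs)

    rng = np.random.default_rng([spec.seed, 303])
    n_artifact = round(spec.artifact_fraction * spec.reads_per_sample)
    n_inserts = spec.reads_per_sample - n_artifact

    libraries: dict[str, SampleLibrary] = {}
    truth_counts: dict[str, Counter] = {}
    for sid in spec.sample_ids:
        group = spec.group(sid)
        counts: Counter = Counter()
        per_len = rng.multinomial(n_inserts, lw) if n_inserts else \
            np.zeros(len(lengths), dtype=int)
        for length, m in zip(lengths, per_len):
            if m == 0 or length not in stratum:
                continue
            seqs, pvecs = stratum[length]
            draw = rng.multinomial(m, pvecs[group])
            nz = np.nonzero(draw)[0]
            for i in nz:
                counts[seqs[i]] += int(draw[i])
        libraries[sid] = SampleLibrary(sid, group=group, counts=counts)
        truth_counts[sid] = Counter(counts)

    truth = PlantedTruth(
        differential_species=[(p.sequence, p.kind) for p in planted
                              if p.kind in ("more", "less")],
        abundant_species=[p.sequence for p in planted if p.kind == "abundant"],
        per_sample_insert_counts=truth_counts,
    )
    return libraries, truth


# --------------------------------------------------------------------------
# read emission

@dataclass
class SimulatedRun:
    """One multiplexed run: raw reads plus the planted truth."""

    spec: SyntheticSpec
    refs: ReferenceSet
    reads: list[tuple[str, str]]        # (read id, DNA-space bases)
    truth: PlantedTruth

    def write_fastq(self, path: str | Path, quality: str = "I") -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f">{rid}\n{seq}\n")


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = str(rng.choice([x for x in "ACGU" if x != b]))
    return "".join(out)


def simulate_libraries(spec: SyntheticSpec, refs: ReferenceSet,
                       ) -> SimulatedRun:
    """Emit one multiplexed raw-read run with exact planted truth.

    Each read is [5'-adapter remnant | barcode | insert | 3' adapter] in DNA
    space; ``artifact_fraction`` of each library are adapter artifacts
    (dimers and 5'-adapter fragments, alternating). With a nonzero error
    rate substitutions hit insert bases and the truth tallies the mutated
    inserts (truth always matches what was emitted).
    """
    libraries, truth = simulate_counts(spec, refs)
    rng = np.random.default_rng([spec.seed, 404])
    n_artifact = round(spec.artifact_fraction * spec.reads_per_sample)

    entries: list[tuple[str, str, bool]] = []   # (sample, insert/None, artifact)
    if spec.error_rate > 0.0:
        for sid in spec.sample_ids:
            mutated: Counter = Counter()
            for seq, c in truth.per_sample_insert_counts[sid].items():
                for _ in range(c):
                    mutated[_mutate(seq, rng, spec.error_rate)] += 1
            truth.per_sample_insert_counts[sid] = mutated
            libraries[sid].counts = Counter(mutated)

    for sid in spec.sample_ids:
        for seq, c in sorted(truth.per_sample_insert_counts[sid].items()):
            entries.extend([(sid, seq, False)] * c)
        core = FIVE_PRIME_ADAPTER_CORE + spec.barcode_table[sid]
        for i in range(n_artifact):
            if i % 2 == 0:
                entries.append((sid, "", True))                 # adapter dimer
            else:
                frag_len = int(rng.integers(12, 21))
                start = int(rng.integers(0, len(core) - frag_len + 1))
                entries.append((sid, core[start:start + frag_len], True))

    order = rng.permutation(len(entries))
    reads: list[tuple[str, str]] = []
    artifact_ids: set[str] = set()
    for k, idx in enumerate(order):
        sid, insert, is_artifact = entries[idx]
        rid = f"read_{k:07d}"
        bases = (FIVE_PRIME_REMNANT + spec.barcode_table[sid] + insert
                 + THREE_PRIME_ADAPTER)
        reads.append((rid, to_dna(bases)))
        if is_artifact:
            artifact_ids.add(rid)
    truth.artifact_reads = artifact_ids
    return SimulatedRun(spec, refs, reads, truth)


def raw_read_multiset(spec: SyntheticSpec, truth: PlantedTruth,
                      ) -> Counter:
    """The run's raw reads as a multiset (DNA-space read string -> count).

    Exactly the reads :func:`simulate_libraries` would emit for this truth,
    without per-read identifiers or ordering; artifact reads are regenerated
    from the same seed stream position (tag 404) used at emission.
    """
    rng = np.random.default_rng([spec.seed, 404])
    n_artifact = round(spec.artifact_fraction * spec.reads_per_sample)
    out: Counter = Counter()
    for sid in spec.sample_ids:
        prefix = FIVE_PRIME_REMNANT + spec.barcode_table[sid]
        for seq, c in truth.per_sample_insert_counts[sid].items():
            out[to_dna(prefix + seq + THREE_PRIME_ADAPTER)] += c
        core = FIVE_PRIME_ADAPTER_CORE + spec.barcode_table[sid]
        for i in range(n_artifact):
            if i % 2 == 0:
                insert = ""
            else:
                frag_len = int(rng.integers(12, 21))
                start = int(rng.integers(0, len(core) - frag_len + 1))
                insert = core[start:start + frag_len]
            out[to_dna(prefix + insert + THREE_PRIME_ADAPTER)] += 1
    return out


def write_truth_tsv(truth: PlantedTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tsequence\tdirection_or_sample\tcount\n")
        for seq, direction in truth.differential_species:
            fh.write(f"differential\t{seq}\t{direction}\t\n")
        for seq in truth.abundant_species:
            fh.write(f"abundant\t{seq}\t\t\n")
        for sid in sorted(truth.per_sample_insert_counts):
            for seq, c in sorted(truth.per_sample_insert_counts[sid].items()):
                fh.write(f"count\t{seq}\t{sid}\t{c}\n")
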