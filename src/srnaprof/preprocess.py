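"""Raw reads to per-sample insert multisets.

A read is laid out as

    [5' adapter remnant | 4-nt barcode | insert 5-45 nt | 3' adapter ...]

The sequencing primer covers the first 21 nt of the 30-nt 5' adapter, so
every read begins with a constant 5-nt remnant of the adapter followed by the
library barcode. Preprocessing canonicalizes to RNA space, demultiplexes on
the barcode, locates the 3'-adapter seed and strips it together with the 5'
remnant, removes inserts that are themselves 5'-adapter fragments (library
artifacts), and applies the 5-40-nt analysis window. Every read is accounted
to exactly one fate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import pandas as pd

from ._rna import AlphabetError, canonicalize, hamming, reverse_complement_rna

# Adapters of the library protocol, canonicalized to RNA space.
THREE_PRIME_ADAPTER = "AUCUCGUAUGCCGUCUUCUGCUUGU"
FIVE_PRIME_ADAPTER_CORE = "GUUCAGAGUUCUACAGUCCGACGAUC"  # 26 nt, barcode follows
#: The 4-nt variable suffixes of the six 5' adapters, used as barcodes.
DEFAULT_BARCODES: dict[str, str] = {
    "S1": "GAAA", "S2": "AAAA", "S3": "AGAA",
    "S4": "ACAA", "S5": "CAAA", "S6": "UAAA",
}
#: Constant remnant of the 5' adapter left 5' of the barcode on each read.
FIVE_PRIME_REMNANT = FIVE_PRIME_ADAPTER_CORE[21:]  # "CGAUC"

UNASSIGNED = "UNASSIGNED"


def five_prime_adapters(barcodes: Mapping[str, str] | None = None) -> list[str]:
    """Full 30-nt 5' adapter sequences (core + barcode), RNA space."""
    barcodes = DEFAULT_BARCODES if barcodes is None else barcodes
    return [FIVE_PRIME_ADAPTER_CORE + bc for bc in barcodes.values()]


@dataclass
class AdapterConfig:
    """All preprocessing thresholds in one place.

    barcode_table maps sample id -> 4-nt barcode (RNA space). The remnant
    length counts the constant remnant plus the barcode, i.e. the number of
    bases stripped from the 5' end of each read.
    """

    barcode_table: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BARCODES))
    three_prime_adapter: str = THREE_PRIME_ADAPTER
    seed_len: int = 8
    seed_mismatch: int = 1
    barcode_offset: int = len(FIVE_PRIME_REMNANT)
    max_bc_mismatch: int = 0
    artifact_min_match_len: int = 10
    artifact_mismatch: int = 1
    length_lo: int = 5
    length_hi: int = 40

    def __post_init__(self):
        lens = {len(b) for b in self.barcode_table.values()}
        if lens != {4}:
            raise ValueError("all barcodes must be 4 nt")
        if len(set(self.barcode_table.values())) != len(self.barcode_table):
            raise ValueError("barcodes must be pairwise distinct")
        if self.length_lo > self.length_hi:
            raise ValueError("length window lo > hi")

    @property
    def barcode_len(self) -> int:
        return 4

    @property
    def remnant_length(self) -> int:
        """Total fixed-length 5' prefix (constant remnant + barcode)."""
        return self.barcode_offset + self.barcode_len

    @property
    def adapter_seed(self) -> str:
        return self.three_prime_adapter[: self.seed_len]


@dataclass
class SmallRNARead:
    read_id: str
    bases: str                      # RNA space after canonicalization
    source_sample: str = UNASSIGNED


@dataclass
class SampleLibrary:
    """One sample's demultiplexed insert multiset."""

    sample_id: str
    group: str = ""
    source: str = ""                # plasma | PBMC | cell line
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def length_totals(self) -> Counter:
        out = Counter()
        for seq, n in self.counts.items():
            out[len(seq)] += n
        return out


def demultiplex(read: SmallRNARead, barcode_table: Mapping[str, str],
                barcode_offset: int = len(FIVE_PRIME_REMNANT),
                max_bc_mismatch: int = 0) -> str:
    """Assign a read to the unique sample whose barcode matches.

    Returns the sample id, or UNASSIGNED when no barcode (or more than one)
    lies within ``max_bc_mismatch`` of the read's barcode field.
    """
    sid, _ = demultiplex_with_flag(read, barcode_table, barcode_offset,
                                   max_bc_mismatch)
    return sid


def demultiplex_with_flag(read: SmallRNARead,
                          barcode_table: Mapping[str, str],
                          barcode_offset: int = len(FIVE_PRIME_REMNANT),
                          max_bc_mismatch: int = 0) -> tuple[str, str]:
    """Like :func:`demultiplex` but also reports why a read was unassigned.

    The flag is "ok", "no_match", "ambiguous" (two barcodes within
    tolerance) or "truncated" (read too short to carry a barcode).
    """
    field_ = read.bases[barcode_offset: barcode_offset + 4]
    if len(field_) < 4:
        return UNASSIGNED, "truncated"
    hits = [sid for sid, bc in barcode_table.items()
            if hamming(field_, bc) <= max_bc_mismatch]
    if len(hits) == 1:
        return hits[0], "ok"
    return UNASSIGNED, ("ambiguous" if len(hits) > 1 else "no_match")


def _find_adapter_seed(bases: str, seed: str, max_mm: int) -> int:
    """Leftmost start of the 3'-adapter seed with <= max_mm mismatches, or -1.

    Pigeonhole: a window with <= 1 mismatch against the seed matches one of
    its halves exactly, so only half-matches need verification.
    """
    exact = bases.find(seed)
    if max_mm == 0:
        return exact
    if max_mm > 1:
        raise ValueError("seed mismatch tolerance above 1 not supported")
    k = len(seed)
    half = k // 2
    limit = (exact if exact != -1 else len(bases) - k)
    candidates = set()
    for piece, shift in ((seed[:half], 0), (seed[half:], half)):
        pos = bases.find(piece)
        while pos != -1:
            start = pos - shift
            if 0 <= start <= limit:
                candidates.add(start)
            pos = bases.find(piece, pos + 1)
    for start in sorted(candidates):
        if start == exact:
            return start
        mm = 0
        for a, b in zip(bases[start:start + k], seed):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return start
    return exact


class TrimReject(Exception):
    """Read rejected during adapter trimming; ``reason`` says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def trim_adapters(read: SmallRNARead, config: AdapterConfig) -> str:
    """Strip the 3' adapter (seed match, <=1 mismatch) and the 5' remnant.

    Returns the insert; raises :class:`TrimReject` with reason "no adapter"
    when no seed is found or "adapter-dimer" when the insert is empty.
    """
    pos = _find_adapter_seed(read.bases, config.adapter_seed,
                             config.seed_mismatch)
    if pos == -1:
        raise TrimReject("no adapter")
    insert = read.bases[config.remnant_length: pos]
    if len(insert) < 1:
        raise TrimReject("adapter-dimer")
    return insert


_CHARVAL = {"A": 0, "C": 1, "G": 2, "U": 3}


@lru_cache(maxsize=8)
def _artifact_screen(subjects: tuple[str, ...], window: int,
                     max_mm: int) -> frozenset[int]:
    """Base-4 codes of every length-``window`` subject substring and all its
    <=max_mm-substitution variants. Membership of an insert window in this
    set is exactly "aligns to a subject with <= max_mm mismatches"."""
    if max_mm > 1:
        raise ValueError("artifact mismatch tolerance above 1 not supported")
    codes: set[int] = set()
    pow4 = [4 ** (window - 1 - i) for i in range(window)]
    for subj in subjects:
        for o in range(len(subj) - window + 1):
            w = subj[o:o + window]
            base = sum(_CHARVAL[c] * p for c, p in zip(w, pow4))
            codes.add(base)
            if max_mm >= 1:
                for i, c in enumerate(w):
                    for b in range(4):
                        if b != _CHARVAL[c]:
                            codes.add(base + (b - _CHARVAL[c]) * pow4[i])
    return frozenset(codes)


def filter_artifacts(insert: str, config: AdapterConfig) -> bool:
    """True (KEEP) unless the insert locally matches a 5' adapter.

    DROP when any window of ``artifact_min_match_len`` insert bases aligns
    somewhere on any full 5' adapter (or its reverse complement) with
    <= ``artifact_mismatch`` mismatches.
    """
    L = config.artifact_min_match_len
    if len(insert) < L:
        return True
    subjects = []
    for ad in five_prime_adapters(config.barcode_table):
        subjects.append(ad)
        subjects.append(reverse_complement_rna(ad))
    screen = _artifact_screen(tuple(subjects), L, config.artifact_mismatch)
    # rolling base-4 hash over the insert's windows
    top = 4 ** (L - 1)
    code = 0
    for i, c in enumerate(insert):
        code = (code % top) * 4 + _CHARVAL[c] if i >= L else code * 4 + _CHARVAL[c]
        if i >= L - 1 and code in screen:
            return False
    return True


def length_select(insert: str, lo: int = 5, hi: int = 40) -> bool:
    """True (KEEP) iff lo <= len(insert) <= hi."""
    if lo > hi:
        raise ValueError("length window lo > hi")
    return lo <= len(insert) <= hi


#: Read fates tracked by the accounting table.
FATES = ("kept", "unassigned", "rejected_no_adapter", "rejected_adapter_dimer",
         "dropped_artifact", "dropped_length", "rejected_alphabet")


def preprocess_reads(
    records: Iterable[tuple[str, str]],
    config: AdapterConfig,
    sample_sheet: Optional[Mapping[str, Mapping[str, str]]] = None,
    apply_artifact_filter: bool = True,
) -> tuple[dict[str, SampleLibrary], pd.DataFrame]:
    """Run the full preprocessing chain over ``(read_id, raw_bases)`` records.

    sample_sheet optionally maps sample id -> {"group": ..., "source": ...}.
    Returns per-sample libraries and a read-fate accounting table whose rows
    (samples plus UNASSIGNED) sum exactly to the raw read count.
    """
    read_counts = Counter(raw for _rid, raw in records)
    return preprocess_read_multiset(read_counts, config, sample_sheet,
                                    apply_artifact_filter)


def preprocess_read_multiset(
    read_counts: Mapping[str, int],
    config: AdapterConfig,
    sample_sheet: Optional[Mapping[str, Mapping[str, str]]] = None,
    apply_artifact_filter: bool = True,
) -> tuple[dict[str, SampleLibrary], pd.DataFrame]:
    """As :func:`preprocess_reads`, but over a raw-read multiset.

    Identical raw reads share one fate, so working on distinct reads with
    multiplicities is exactly equivalent and much faster on deep libraries.
    """
    libraries = {
        sid: SampleLibrary(
            sid,
            group=(sample_sheet or {}).get(sid, {}).get("group", ""),
            source=(sample_sheet or {}).get(sid, {}).get("source", ""),
        )
        for sid in config.barcode_table
    }
    acct = {sid: Counter() for sid in [*config.barcode_table, UNASSIGNED]}
    artifact_memo: dict[str, bool] = {}

    def classify(raw: str) -> tuple[str, str, Optional[str]]:
        try:
            bases = canonicalize(raw)
        except AlphabetError:
            return UNASSIGNED, "rejected_alphabet", None
        read = SmallRNARead("", bases)
        sid = demultiplex(read, config.barcode_table, config.barcode_offset,
                          config.max_bc_mismatch)
        if sid == UNASSIGNED:
            return UNASSIGNED, "unassigned", None
        try:
            insert = trim_adapters(read, config)
        except TrimReject as rej:
            key = ("rejected_adapter_dimer" if rej.reason == "adapter-dimer"
                   else "rejected_no_adapter")
            return sid, key, None
        if apply_artifact_filter:
            keep = artifact_memo.get(insert)
            if keep is None:
                keep = filter_artifacts(insert, config)
                artifact_memo[insert] = keep
            if not keep:
                return sid, "dropped_artifact", None
        if not length_select(insert, config.length_lo, config.length_hi):
            return sid, "dropped_length", None
        return sid, "kept", insert

    for raw, n in read_counts.items():
        sid, key, insert = classify(raw)
        acct[sid][key] += n
        if insert is not None:
            libraries[sid].counts[insert] += n

    table = pd.DataFrame(
        [[acct[sid][f] for f in FATES] for sid in acct],
        index=list(acct), columns=list(FATES),
    )
    table["total"] = table.sum(axis=1)
    return libraries, table


def read_fasta_or_fastq(path) -> Iterable[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA or FASTQ file, sniffed by extension."""
    from Bio import SeqIO

    path = str(path)
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    for rec in SeqIO.parse(path, fmt):
        yield rec.id, str(rec.seq)
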