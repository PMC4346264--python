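"""Transcript-space annotation of small-RNA inserts.

Each insert is matched, as a contiguous substring with up to ``max_mm``
mismatches, against a category-annotated reference transcript set. Reads
hitting the ribosomal DNA repeating-unit surrogate within two mismatches are
classified rRNA up front and excluded from further transcript matching, a
desk-scale stand-in for the genome-wide pre-mapping rRNA filter. The set of
categories of all matching transcripts is the insert's annotation; an empty
set means "unidentified RNA fragment".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from ._rna import canonicalize, reverse_complement_rna

#: The ten RNA categories used for relative-frequency profiles.
CATEGORIES: tuple[str, ...] = (
    "mRNA", "rRNA", "scRNA", "snRNA", "srpRNA",
    "miRNA", "lncRNA", "piRNA", "snoRNA", "tRNA",
)


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str           # RNA space
    categories: frozenset[str]

    def __post_init__(self):
        bad = self.categories - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)} on {self.id}")


@dataclass
class ReferenceSet:
    """Category-annotated transcripts, with a designated rDNA repeating unit.

    ``rdna_unit`` may be None for degenerate references (e.g. a single-category
    mix without rRNA); :func:`rdna_filter` then refuses to run.
    """

    transcripts: list[Transcript]
    rdna_unit: Optional[str] = None

    def __post_init__(self):
        ids = [t.id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate transcript ids in reference")
        if self.rdna_unit is not None and self.rdna_unit not in ids:
            raise ValueError(f"rdna_unit {self.rdna_unit!r} not in reference")

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self):
        return len(self.transcripts)

    def get(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise KeyError(transcript_id)

    # ---- persistence: FASTA + category TSV --------------------------------

    def write(self, fasta_path: str | Path, tsv_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.id}\n{t.sequence}\n")
        with open(tsv_path, "w") as fh:
            fh.write("transcript_id\tcategory\tis_rdna_unit\n")
            for t in self.transcripts:
                cats = ",".join(sorted(t.categories))
                fh.write(f"{t.id}\t{cats}\t{int(t.id == self.rdna_unit)}\n")

    @classmethod
    def read(cls, fasta_path: str | Path, tsv_path: str | Path) -> "ReferenceSet":
        seqs = {rec.id: canonicalize(str(rec.seq))
                for rec in SeqIO.parse(str(fasta_path), "fasta")}
        transcripts, rdna = [], None
        with open(tsv_path) as fh:
            header = fh.readline()
            if not header.startswith("transcript_id"):
                raise ValueError("annotation TSV must start with a header line")
            for line in fh:
                tid, cats, is_rdna = line.rstrip("\n").split("\t")
                transcripts.append(Transcript(
                    tid, seqs[tid], frozenset(cats.split(","))))
                if is_rdna == "1":
                    rdna = tid
        return cls(transcripts, rdna)


def match_with_mismatches(query: str, subject: str,
                          max_mm: int) -> list[tuple[int, int]]:
    """All alignments of *query* as a contiguous substring of *subject*.

    Returns ``(position, mismatches)`` pairs, 1-based, Hamming distance
    <= ``max_mm``. Uses pigeonhole seed-and-verify: the query is split into
    ``max_mm + 1`` fragments, one of which must match exactly; candidate
    offsets from exact fragment hits are then verified in full. Equivalent to
    the naive scan over every position.
    """
    q, n, m = query, len(subject), len(query)
    if m == 0 or m > n:
        return []
    if max_mm >= m:  # every placement trivially matches
        return [(i + 1, sum(a != b for a, b in zip(q, subject[i:i + m])))
                for i in range(n - m + 1)]

    k = max_mm + 1
    frag = m // k
    candidates: set[int] = set()
    for j in range(k):
        start = j * frag
        end = start + frag if j < k - 1 else m
        piece = q[start:end]
        pos = subject.find(piece)
        while pos != -1:
            off = pos - start
            if 0 <= off <= n - m:
                candidates.add(off)
            pos = subject.find(piece, pos + 1)

    hits = []
    for off in sorted(candidates):
        mm = 0
        window = subject[off:off + m]
        for a, b in zip(q, window):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            hits.append((off + 1, mm))
    return hits


@dataclass
class AnnotationIndex:
    """Per-transcript matcher with a k-mer presence filter.

    The k-mer set over all transcripts lets most non-matching inserts be
    dismissed without a scan: an insert matching some transcript with
    <= max_mm mismatches must (pigeonhole) contain an exact fragment of
    length ``len(insert) // (max_mm + 1)``; if that is >= seed_len, one of
    its seed_len-mers appears in the index.
    """

    refs: ReferenceSet
    seed_len: int = 8
    match_reverse: bool = False
    _kmers: set[str] = field(default_factory=set, repr=False)

    def __post_init__(self):
        for t in self.refs:
            seq = t.sequence
            for i in range(len(seq) - self.seed_len + 1):
                self._kmers.add(seq[i:i + self.seed_len])

    def _subjects(self, t: Transcript) -> Iterable[str]:
        yield t.sequence
        if self.match_reverse:
            yield reverse_complement_rna(t.sequence)

    def _maybe_present(self, insert: str, max_mm: int) -> bool:
        frag = len(insert) // (max_mm + 1)
        if frag < self.seed_len or self.match_reverse:
            return True  # filter inapplicable; fall through to full scan
        return any(insert[i:i + self.seed_len] in self._kmers
                   for i in range(len(insert) - self.seed_len + 1))

    def matching_transcripts(self, insert: str, max_mm: int = 2) -> list[Transcript]:
        if not self._maybe_present(insert, max_mm):
            return []
        out = []
        for t in self.refs:
            if any(match_with_mismatches(insert, s, max_mm)
                   for s in self._subjects(t)):
                out.append(t)
        return out


def rdna_filter(insert: str, refs: ReferenceSet, max_mm: int = 2,
                match_reverse: bool = False) -> bool:
    """True iff the insert matches the rDNA repeating unit within max_mm."""
    if refs.rdna_unit is None:
        raise ValueError("reference set has no designated rDNA unit")
    subject = refs.get(refs.rdna_unit).sequence
    if match_with_mismatches(insert, subject, max_mm):
        return True
    if match_reverse:
        return bool(match_with_mismatches(
            insert, reverse_complement_rna(subject), max_mm))
    return False


def assign_categories(insert: str, index: AnnotationIndex,
                      max_mm: int = 2) -> frozenset[str]:
    """Categories of all transcripts containing the insert at <= max_mm.

    Empty set = unidentified fragment.
    """
    cats: set[str] = set()
    for t in index.matching_transcripts(insert, max_mm):
        cats |= t.categories
    return frozenset(cats)


@dataclass
class CategoryProfile:
    """Relative category frequencies (%) over a sample's annotated reads."""

    percentages: dict[str, float]
    annotated_reads: int
    unannotated_reads: int
    empty: bool = False


def annotate_sample(counts: Mapping[str, int], refs: ReferenceSet,
                    index: Optional[AnnotationIndex] = None, max_mm: int = 2,
                    rdna_max_mm: int = 2) -> dict[str, frozenset[str]]:
    """Per-sequence category sets for an insert multiset.

    rDNA-matching inserts short-circuit to {rRNA} and never reach the
    transcript matcher.
    """
    if index is None:
        index = AnnotationIndex(refs)
    out: dict[str, frozenset[str]] = {}
    for seq in counts:
        if refs.rdna_unit is not None and rdna_filter(seq, refs, rdna_max_mm):
            out[seq] = frozenset({"rRNA"})
        else:
            out[seq] = assign_categories(seq, index, max_mm)
    return out


def category_profile(counts: Mapping[str, int],
                     annotations: Mapping[str, frozenset[str]],
                     mode: str = "fractional") -> CategoryProfile:
    """Percentage of each category among annotated reads.

    ``fractional``: a read matching k >= 1 categories contributes 1/k to each,
    so the stacked percentages total 100 exactly. ``priority``: the read
    counts fully toward its single highest-priority category (the order of
    :data:`CATEGORIES`).
    """
    if mode not in ("fractional", "priority"):
        raise ValueError(f"unknown mode {mode!r}")
    weights = defaultdict(float)
    annotated = 0
    unannotated = 0
    for seq, n in counts.items():
        cats = annotations.get(seq, frozenset())
        if not cats:
            unannotated += n
            continue
        annotated += n
        if mode == "fractional":
            w = n / len(cats)
            for c in cats:
                weights[c] += w
        else:
            best = min(cats, key=CATEGORIES.index)
            weights[best] += n
    if annotated == 0:
        return CategoryProfile({c: 0.0 for c in CATEGORIES}, 0, unannotated,
                               empty=True)
    pct = {c: 100.0 * weights[c] / annotated for c in CATEGORIES}
    return CategoryProfile(pct, annotated, unannotated)
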