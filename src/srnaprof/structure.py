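"""tRNase Z^L small-guide-RNA structure rules and cleavage-site prediction.

A 5'-half-tRNA-type guide folds into an unpaired 5'-terminal acceptor arm
followed by an internal stem-loop (a D-arm mimic). Bound to a target it
rebuilds a pre-tRNA-like complex: the guide's acceptor arm pairs a
complementary stretch of the target (the acceptor pseudo-stem), the target
contributes a T-arm-like stem-loop upstream, and the single unpaired target
nucleotide just 3' of the duplex is the discriminator. tRNase Z^L cleaves
the bond immediately 3' of the discriminator. Everything here is
combinatorial pattern matching over Watson-Crick/G.U pairing — structure by
diagram, not free-energy folding — so every claim is an enumerable fact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._rna import pairs, reverse_complement_rna  # noqa: F401  (re-exported)

SGRNA_CLASSES = ("heptamer", "linear14", "half_tRNA", "hook")


@dataclass(frozen=True)
class HairpinFold:
    """An intramolecular stem-loop. Coordinates 1-based, inclusive."""

    stem5_start: int
    stem5_end: int
    loop_len: int
    stem3_start: int
    stem3_end: int
    stem_len: int

    @property
    def loop_span(self) -> tuple[int, int]:
        return self.stem5_end + 1, self.stem3_start - 1


@dataclass(frozen=True)
class HalfTRNAFold:
    """5'-half-tRNA-like fold: unpaired acceptor arm + D-arm-mimic stem-loop."""

    sequence: str
    arm_len: int            # length of the unpaired 5'-terminal segment
    hairpin: HairpinFold

    @property
    def acceptor_arm(self) -> str:
        return self.sequence[: self.arm_len]


def _hairpins(seq: str, stem_min: int, stem_max: int, loop_min: int,
              loop_max: int, first_stem5: int = 0, allow_gu: bool = True):
    """Enumerate stem-loops; stem5 start offset >= first_stem5 (0-based)."""
    n = len(seq)
    for i in range(first_stem5, n):
        for s in range(stem_min, stem_max + 1):
            for loop in range(loop_min, loop_max + 1):
                j = i + s + loop          # 0-based start of the 3' stem side
                if j + s > n:
                    continue
                if all(pairs(seq[i + k], seq[j + s - 1 - k], allow_gu)
                       for k in range(s)):
                    yield HairpinFold(i + 1, i + s, loop, j + 1, j + s, s)


def has_hairpin(seq: str, stem_min: int = 4, loop_min: int = 3,
                loop_max: int = 11, first_stem5: int = 0) -> bool:
    """Any stem-loop with >= stem_min bp (G.U included) in the sequence?"""
    return next(_hairpins(seq, stem_min, len(seq), loop_min, loop_max,
                          first_stem5), None) is not None


def fold_half_trna(sequence: str, stem_min: int = 3, stem_max: int = 7,
                   loop_min: int = 3, loop_max: int = 11,
                   arm_min: int = 7) -> Optional[HalfTRNAFold]:
    """Best 5'-half-tRNA-like fold, or None.

    Searches stem-loops (stem 3-7 bp incl. G.U, loop 3-11 nt) whose 5' stem
    side starts at least ``arm_min`` nt into the sequence, leaving the 5'
    terminus unpaired as the acceptor-arm mimic. Maximizes stem length; ties
    go to the 5'-most stem, then the shortest loop.
    """
    best: Optional[HairpinFold] = None
    for hp in _hairpins(sequence, stem_min, stem_max, loop_min, loop_max,
                        first_stem5=arm_min):
        if best is None or (-hp.stem_len, hp.stem5_start, hp.loop_len) < (
                -best.stem_len, best.stem5_start, best.loop_len):
            best = hp
    if best is None:
        return None
    return HalfTRNAFold(sequence, best.stem5_start - 1, best)


def classify_sgrna(sequence: str) -> frozenset[str]:
    """Potential guide classes of a small RNA (classes may overlap).

    heptamer: 5-8 nt. linear14: 12-16 nt with no internal >=4-bp stem-loop.
    half_tRNA: 26-40 nt folding as a 5'-half-tRNA mimic. hook: 15-25 nt with
    a 3' stem-loop (>=4 bp) leaving a >=7-nt unpaired 5' guide segment.
    """
    n = len(sequence)
    classes = set()
    if 5 <= n <= 8:
        classes.add("heptamer")
    if 12 <= n <= 16 and not has_hairpin(sequence, stem_min=4):
        classes.add("linear14")
    if 26 <= n <= 40 and fold_half_trna(sequence) is not None:
        classes.add("half_tRNA")
    if 15 <= n <= 25 and has_hairpin(sequence, stem_min=4, first_stem5=7):
        classes.add("hook")
    return frozenset(classes)


@dataclass(frozen=True)
class SgRNACandidate:
    sequence: str
    classes: frozenset[str]
    fold: Optional[HalfTRNAFold] = None


def scan_candidates(sequences) -> list[SgRNACandidate]:
    """Classify a collection of small RNAs as potential guides."""
    out = []
    for seq in sequences:
        classes = classify_sgrna(seq)
        if classes:
            fold = fold_half_trna(seq) if "half_tRNA" in classes else None
            out.append(SgRNACandidate(seq, classes, fold))
    return out


@dataclass(frozen=True)
class PreTRNAComplex:
    """A guide:target pre-tRNA-like complex. All coordinates 1-based."""

    guide: str
    target: str
    duplex_len: int
    guide_positions: tuple[int, int]       # guide 5' arm span in the duplex
    target_positions: tuple[int, int]      # acceptor pseudo-stem on the target
    tarm: HairpinFold                      # T-arm-like stem-loop on the target
    tarm_ggttc: bool                       # loop carries the GGUUC consensus
    discriminator: int                     # target position just 3' of duplex
    cleavage_site: int                     # bond between cleavage_site, +1

    def __post_init__(self):
        # geometry sanity: T-arm < acceptor pairing < discriminator < cleavage
        if not self.tarm.stem3_end < self.target_positions[0]:
            raise ValueError("T-arm must lie 5' of the acceptor pairing")
        if self.discriminator != self.target_positions[1] + 1:
            raise ValueError("discriminator must abut the acceptor pairing")
        if self.cleavage_site != self.discriminator:
            raise ValueError("cleavage bond must sit 3' of the discriminator")


def _pair_run(guide: str, target: str, end: int, allow_gu: bool = True) -> int:
    """Length of the contiguous duplex guide[0]:target[end], guide[1]:target[end-1], ..."""
    L = 0
    while L < len(guide) and end - L >= 0 and pairs(guide[L], target[end - L],
                                                    allow_gu):
        L += 1
    return L


def find_target_sites(guide: str, target: str, min_acceptor_bp: int = 7,
                      window_upstream: int = 30, tstem_min: int = 4,
                      tloop_min: int = 5, tloop_max: int = 9,
                      allow_gu: bool = True) -> list[PreTRNAComplex]:
    """All pre-tRNA-like complexes a half-tRNA-type guide can form on a target.

    For every target position, the maximal contiguous duplex between the
    guide's 5' terminus and the target is measured (Watson-Crick + G.U) and
    capped at the guide's unpaired acceptor-arm length — guide bases inside
    the intramolecular D-stem mimic are not available for intermolecular
    pairing. A complex requires a duplex of >= ``min_acceptor_bp``, a
    T-arm-like stem-loop (stem >= ``tstem_min`` bp, loop ``tloop_min``-
    ``tloop_max`` nt) on the target within ``window_upstream`` nt 5' of the
    duplex, and at least one target nucleotide 3' of the duplex (the
    discriminator). Ranked by duplex length, then GGUUC-loop bonus, then
    target position.
    """
    fold = fold_half_trna(guide)
    if fold is None:
        return []
    arm = fold.arm_len
    out = []
    for end in range(len(target) - 1):      # need >=1 nt 3' of the duplex
        run = _pair_run(guide, target, end, allow_gu)
        L = min(run, arm)
        if L < min_acceptor_bp:
            continue
        site_start = end - L + 2            # 1-based
        site_end = end + 1
        upstream_lo = max(0, site_start - 1 - window_upstream)
        upstream = target[upstream_lo: site_start - 1]
        best_tarm, best_ggttc = None, False
        for hp in _hairpins(upstream, tstem_min, len(upstream),
                            tloop_min, tloop_max):
            loop_seq = upstream[hp.stem5_end: hp.stem3_start - 1]
            ggttc = "GGUUC" in loop_seq
            key = (hp.stem_len, ggttc, -hp.stem5_start)
            if best_tarm is None or key > (best_tarm.stem_len, best_ggttc,
                                           -best_tarm.stem5_start):
                best_tarm, best_ggttc = hp, ggttc
        if best_tarm is None:
            continue
        # shift the hairpin back into full-target coordinates
        tarm = HairpinFold(
            best_tarm.stem5_start + upstream_lo, best_tarm.stem5_end + upstream_lo,
            best_tarm.loop_len,
            best_tarm.stem3_start + upstream_lo, best_tarm.stem3_end + upstream_lo,
            best_tarm.stem_len,
        )
        out.append(PreTRNAComplex(
            guide=guide, target=target, duplex_len=L,
            guide_positions=(1, L),
            target_positions=(site_start, site_end),
            tarm=tarm, tarm_ggttc=best_ggttc,
            discriminator=site_end + 1,
            cleavage_site=site_end + 1,
        ))
    out.sort(key=lambda c: (-c.duplex_len, -int(c.tarm_ggttc),
                            c.target_positions[0]))
    return out


def predict_cleavage(cplx: PreTRNAComplex) -> tuple[int, int, int]:
    """Cleavage bond and product lengths: (position d, 5' product, 3' product).

    The bond cut lies between target positions d and d+1, immediately 3' of
    the discriminator; product lengths always sum to the target length. A 3'
    product of length 0 marks a terminal discriminator.
    """
    d = cplx.cleavage_site
    return d, d, len(cplx.target) - d
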