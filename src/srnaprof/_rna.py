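"""RNA alphabet helpers shared across the package.

All analysis happens in RNA space (A, C, G, U). Sequencer output arrives in
DNA space; :func:`canonicalize` is the single entry point that maps it in.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_CANON = str.maketrans("acgtuACGTU", "ACGUUACGUU")

# Watson-Crick plus the G.U wobble, the pairs tRNA stems actually use.
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})
ALL_PAIRS = WC_PAIRS | WOBBLE_PAIRS

_RC = str.maketrans("ACGU", "UGCA")


class AlphabetError(ValueError):
    """Sequence contains a character outside the accepted alphabet."""


def canonicalize(sequence: str) -> str:
    """Uppercase a sequence and map T to U.

    Raises :class:`AlphabetError` for anything outside {A,C,G,T,U} in
    either case — ambiguity codes (N etc.) are rejected, mirroring the
    read-level policy of dropping uncalled bases.
    """
    out = sequence.translate(_CANON)
    if not RNA_ALPHABET.issuperset(out):
        bad = sorted(set(out) - RNA_ALPHABET)
        raise AlphabetError(f"non-ACGTU character(s) {bad!r} in sequence")
    return out


def reverse_complement_rna(sequence: str) -> str:
    """Reverse complement in RNA space (A<->U, G<->C)."""
    if not RNA_ALPHABET.issuperset(sequence):
        bad = sorted(set(sequence) - RNA_ALPHABET)
        raise AlphabetError(f"non-ACGU character(s) {bad!r} in sequence")
    return sequence.translate(_RC)[::-1]


def to_dna(sequence: str) -> str:
    """Map an RNA-space sequence to DNA space (U -> T) for read emission."""
    return sequence.replace("U", "T")


def pairs(a: str, b: str, allow_gu: bool = True) -> bool:
    """True if bases *a* and *b* can pair (Watson-Crick, optionally G.U)."""
    if (a, b) in WC_PAIRS:
        return True
    return allow_gu and (a, b) in WOBBLE_PAIRS


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
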