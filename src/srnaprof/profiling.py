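"""Length-frequency profiles and the species-frequency statistic.

A species frequency is a sequence's read count as a percentage of all reads
of the same length in the same sample (the per-length denominator); the
alternate denominator — all reads in the 5-40-nt analysis window — is used
for single-species abundance plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .preprocess import SampleLibrary


@dataclass
class LengthProfile:
    """Read counts per insert length over the analysis window, zero-filled."""

    counts: dict[int, int]
    total: int
    lo: int = 5
    hi: int = 40

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name="reads").sort_index()


def length_profile(sample: SampleLibrary, lo: int = 5,
                   hi: int = 40) -> LengthProfile:
    counts = {length: 0 for length in range(lo, hi + 1)}
    for seq, n in sample.counts.items():
        if lo <= len(seq) <= hi:
            counts[len(seq)] += n
    return LengthProfile(counts, sum(counts.values()), lo, hi)


def find_peaks(profile: LengthProfile) -> list[int]:
    """Strict local maxima of the length histogram, plateaus merged.

    A run of equal counts is a peak when both flanking counts are strictly
    lower; at the window edges the comparison is one-sided. A run spanning
    the whole window (a flat profile) is not a peak. All member lengths of a
    plateau are reported, mirroring "14/15/16"-style peak naming.
    """
    lengths = sorted(profile.counts)
    values = [profile.counts[k] for k in lengths]
    peaks: list[int] = []
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == len(values) - 1 or values[j + 1] < values[i]
        spans_all = i == 0 and j == len(values) - 1
        if left_ok and right_ok and not spans_all:
            peaks.extend(lengths[i:j + 1])
        i = j + 1
    return peaks


def species_frequency(sample: SampleLibrary, sequence: str,
                      denominator: str = "same_length",
                      lo: int = 5, hi: int = 40) -> Optional[float]:
    """Percent frequency of one sequence in one sample.

    denominator "same_length": reads of the same length; "all_5_40": all
    reads in the analysis window. Returns None (missing, not 0) when the
    denominator is zero.
    """
    if denominator not in ("same_length", "all_5_40"):
        raise ValueError(f"unknown denominator {denominator!r}")
    count = sample.counts.get(sequence, 0)
    if denominator == "same_length":
        denom = sample.length_totals()[len(sequence)]
    else:
        denom = sum(n for s, n in sample.counts.items() if lo <= len(s) <= hi)
    if denom == 0:
        return None
    return 100.0 * count / denom


def species_frequency_table(samples: Sequence[SampleLibrary],
                            sequences: Iterable[str],
                            denominator: str = "same_length") -> pd.DataFrame:
    """Frequencies (%) of the given sequences in every sample.

    Rows are indexed by sequence with a ``length`` column; one column per
    sample. A sequence absent from a sample is imputed frequency 0 — a
    sequence in one person's top-N may simply be unobserved in another.
    """
    sequences = list(dict.fromkeys(sequences))
    data = {}
    for sample in samples:
        totals = sample.length_totals()
        col = []
        for seq in sequences:
            denom = totals[len(seq)]
            col.append(100.0 * sample.counts.get(seq, 0) / denom
                       if denom else 0.0)
        data[sample.sample_id] = col
    df = pd.DataFrame(data, index=pd.Index(sequences, name="sequence"))
    df.insert(0, "length", [len(s) for s in sequences])
    return df
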