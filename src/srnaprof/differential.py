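"""Per-length top-N comparing sets and two-sample differential abundance.

The comparing set is the de-duplicated union, over samples and insert
lengths, of each sample's N most abundant sequences per length. Each
comparing sequence is then tested for a group difference of its per-length
percentage frequency with a pooled-variance two-tailed Student's t-test;
raw P < alpha defines significance (no multiple-testing correction by
default, Benjamini-Hochberg available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SampleLibrary
from .profiling import species_frequency_table

logger = logging.getLogger(__name__)


def top_n_species(sample: SampleLibrary, n: int, lo: int = 5,
                  hi: int = 40) -> dict[int, list[str]]:
    """Per-length lists of the N highest-count sequences in one sample.

    Ties at rank N are broken lexicographically (deterministic) and logged.
    Lengths with no reads map to empty lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    by_len: dict[int, list[tuple[str, int]]] = {k: [] for k in range(lo, hi + 1)}
    for seq, c in sample.counts.items():
        if lo <= len(seq) <= hi:
            by_len[len(seq)].append((seq, c))
    out = {}
    for length, items in by_len.items():
        items.sort(key=lambda t: (-t[1], t[0]))
        if len(items) > n and items[n - 1][1] == items[n][1]:
            logger.info("top-%d tie at length %d in %s broken lexicographically",
                        n, length, sample.sample_id)
        out[length] = [seq for seq, _ in items[:n]]
    return out


def comparing_set(samples: Sequence[SampleLibrary], n: int, lo: int = 5,
                  hi: int = 40) -> list[str]:
    """De-duplicated union of per-sample per-length top-N sequences.

    Deterministic order: by length, then lexicographically.
    """
    if len(samples) < 2:
        raise ValueError("comparing set needs at least two samples")
    union: set[str] = set()
    for sample in samples:
        for seqs in top_n_species(sample, n, lo, hi).values():
            union.update(seqs)
    return sorted(union, key=lambda s: (len(s), s))


def t_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t-test, two-tailed.

    df = n_a + n_b - 2. Degenerate zero-variance inputs: equal means give
    (0, 1); unequal means give (+-inf, 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return (np.inf if diff > 0 else -np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def _t_test_matrix(freq: np.ndarray, case_idx: np.ndarray,
                   control_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled t (case - control) and two-tailed p over a matrix."""
    a = freq[:, case_idx]
    b = freq[:, control_idx]
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)
           ) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.where(np.isnan(t), 1.0, 2.0 * stats.t.sf(np.abs(t), na + nb - 2))
    t = np.where(np.isnan(t), 0.0, t)   # 0/0: equal means, no variance
    p = np.where(np.isinf(t), 0.0, p)   # x/0: degenerate separation
    return t, p


@dataclass
class ComparisonResult:
    sequence: str
    length: int
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    t: float
    p: float
    direction: str          # "more" | "less" in the case group
    significant: bool
    degenerate: bool = False


def significant_species(
    table: pd.DataFrame,
    grouping: tuple[Sequence[str], Sequence[str]],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[ComparisonResult]:
    """Test every comparing sequence for a case-vs-control difference.

    ``table`` is a :func:`~srnaprof.profiling.species_frequency_table` frame;
    ``grouping`` is (case sample ids, control sample ids). Returns one
    :class:`ComparisonResult` per row, ordered as the table.
    """
    case_ids, control_ids = grouping
    cols = [c for c in table.columns if c != "length"]
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control groups overlap")
    freq = table[cols].to_numpy(dtype=float)
    case_idx = np.array([cols.index(s) for s in case_ids])
    ctl_idx = np.array([cols.index(s) for s in control_ids])
    t, p = _t_test_matrix(freq, case_idx, ctl_idx)
    p_eff = p
    if bh_correct:
        p_eff = _benjamini_hochberg(p)
    mean_case = freq[:, case_idx].mean(axis=1)
    mean_ctl = freq[:, ctl_idx].mean(axis=1)
    sd_case = freq[:, case_idx].std(axis=1, ddof=1)
    sd_ctl = freq[:, ctl_idx].std(axis=1, ddof=1)
    out = []
    for i, (seq, length) in enumerate(zip(table.index, table["length"])):
        out.append(ComparisonResult(
            sequence=seq, length=int(length),
            mean_case=float(mean_case[i]), mean_control=float(mean_ctl[i]),
            sd_case=float(sd_case[i]), sd_control=float(sd_ctl[i]),
            t=float(t[i]), p=float(p[i]),
            direction="more" if mean_case[i] > mean_ctl[i] else "less",
            significant=bool(p_eff[i] < alpha),
            degenerate=bool(np.isinf(t[i])),
        ))
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up)."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def run_comparison(samples: Sequence[SampleLibrary], n: int,
                   grouping: tuple[Sequence[str], Sequence[str]],
                   alpha: float = 0.05, lo: int = 5, hi: int = 40,
                   ) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Comparing set -> frequency table -> per-sequence tests, in one call."""
    seqs = comparing_set(samples, n, lo, hi)
    table = species_frequency_table(samples, seqs)
    return table, significant_species(table, grouping, alpha)


def results_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    """Flatten ComparisonResults to a table (TSV-ready)."""
    rows = [vars(r) for r in results]
    return pd.DataFrame(rows)
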