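"""Group-segregation statistic over balanced sample bipartitions.

Six samples admit C(6,3)/2 = 10 unordered 3-vs-3 bipartitions, one of which
is the actual case/control split. Counting, for every bipartition, how many
comparing sequences are significant for that split gives n significant
events in total; under uniform allocation each bipartition expects n/10 of
them. The probability of the observed case count is the exact binomial
point mass C(n, k) (1/10)^k (9/10)^(n-k), computed in log space — at the
10^-43 scale naive products underflow. Upper-tail and two-tailed variants
are reported alongside as labelled alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import exp, log, log1p
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .differential import significant_species
import pandas as pd


@dataclass(frozen=True, order=True)
class Bipartition:
    """Unordered balanced split; the side holding the smallest id is side_a."""

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    @classmethod
    def of(cls, side_a: Sequence[str], side_b: Sequence[str]) -> "Bipartition":
        a, b = tuple(sorted(side_a)), tuple(sorted(side_b))
        if set(a) & set(b):
            raise ValueError("bipartition sides overlap")
        if len(a) != len(b):
            raise ValueError("bipartition sides must be equal-sized")
        if b[0] < a[0]:
            a, b = b, a
        return cls(a, b)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted(self.side_a + self.side_b))


def enumerate_bipartitions(sample_ids: Sequence[str]) -> list[Bipartition]:
    """All C(2m, m)/2 unordered balanced bipartitions, canonical order."""
    ids = sorted(sample_ids)
    if len(ids) % 2 != 0:
        raise ValueError("balanced bipartitions need an even sample count")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    m = len(ids) // 2
    anchor = ids[0]  # fixing the smallest id on side_a kills the mirror image
    out = []
    for rest in combinations(ids[1:], m - 1):
        side_a = (anchor, *rest)
        side_b = tuple(s for s in ids if s not in side_a)
        out.append(Bipartition.of(side_a, side_b))
    return sorted(out)


def count_significant_per_bipartition(
    table: pd.DataFrame, alpha: float = 0.05,
    sample_ids: Sequence[str] | None = None,
) -> dict[Bipartition, int]:
    """Significant comparing-sequence count for every balanced bipartition.

    ``table`` is a species-frequency table covering all samples. A sequence
    significant under several bipartitions counts toward each of them.
    """
    if sample_ids is None:
        sample_ids = [c for c in table.columns if c != "length"]
    out = {}
    for bp in enumerate_bipartitions(sample_ids):
        results = significant_species(table, (list(bp.side_a), list(bp.side_b)),
                                      alpha)
        out[bp] = sum(r.significant for r in results)
    return out


def expected_count(s_case: int, s_other: int, n_bipartitions: int = 10) -> float:
    """Expected case-bipartition count under uniform allocation: (k+rest)/B."""
    if n_bipartitions <= 0:
        raise ValueError("number of bipartitions must be positive")
    if s_case < 0 or s_other < 0:
        raise ValueError("counts must be nonnegative")
    return (s_case + s_other) / n_bipartitions


def log_binomial_point_probability(k: int, n: int, p: float) -> float:
    """log of C(n,k) p^k (1-p)^(n-k), via log-gamma."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("need 0 <= p <= 1")
    if p == 0.0:
        return 0.0 if k == 0 else -np.inf
    if p == 1.0:
        return 0.0 if k == n else -np.inf
    return (float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
            + k * log(p) + (n - k) * log1p(-p))


def binomial_point_probability(k: int, n: int, p: float) -> float:
    """Exact binomial point mass at k, computed in log space."""
    return exp(log_binomial_point_probability(k, n, p))


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by log-sum-exp over the tail."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    logs = np.array([log_binomial_point_probability(j, n, p)
                     for j in range(k, n + 1)])
    top = logs.max()
    if top == -np.inf:
        return 0.0
    return float(exp(top) * np.exp(logs - top).sum())


@dataclass
class SegregationResult:
    per_bipartition: dict[Bipartition, int]
    case_bipartition: Bipartition
    s_case: int
    s_other: int
    n_bipartitions: int
    expected: float
    p_alloc: float
    point_probability: float
    upper_tail_probability: float
    case_rank: int          # 1 = largest count among the bipartitions
    counts: list[int] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return self.s_case + self.s_other

    def to_dict(self) -> dict:
        return {
            "counts": {" | ".join([",".join(bp.side_a), ",".join(bp.side_b)]): c
                       for bp, c in self.per_bipartition.items()},
            "case": " | ".join([",".join(self.case_bipartition.side_a),
                                ",".join(self.case_bipartition.side_b)]),
            "s_case": self.s_case,
            "s_other": self.s_other,
            "n_bipartitions": self.n_bipartitions,
            "expected": self.expected,
            "p_alloc": self.p_alloc,
            "point_probability": self.point_probability,
            "upper_tail_probability": self.upper_tail_probability,
            "case_rank": self.case_rank,
        }


def segregation_from_counts(per_bipartition: Mapping[Bipartition, int],
                            case_bipartition: Bipartition) -> SegregationResult:
    """Assemble the segregation statistic from per-bipartition counts."""
    if case_bipartition not in per_bipartition:
        raise ValueError("case bipartition not among the enumerated ones")
    b = len(per_bipartition)
    s_case = per_bipartition[case_bipartition]
    s_other = sum(per_bipartition.values()) - s_case
    n = s_case + s_other
    p_alloc = 1.0 / b
    counts = list(per_bipartition.values())
    rank = 1 + sum(c > s_case for c in counts)
    return SegregationResult(
        per_bipartition=dict(per_bipartition),
        case_bipartition=case_bipartition,
        s_case=s_case, s_other=s_other, n_bipartitions=b,
        expected=expected_count(s_case, s_other, b),
        p_alloc=p_alloc,
        point_probability=binomial_point_probability(s_case, n, p_alloc),
        upper_tail_probability=binomial_upper_tail(s_case, n, p_alloc),
        case_rank=rank, counts=counts,
    )


def segregation_test(table: pd.DataFrame, case_bipartition: Bipartition,
                     alpha: float = 0.05) -> SegregationResult:
    """Full segregation analysis of a species-frequency table."""
    per_bp = count_significant_per_bipartition(table, alpha)
    return segregation_from_counts(per_bp, case_bipartition)
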