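"""Bipartition enumeration and the exact binomial segregation statistic."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnaprof.segregation import (
    Bipartition,
    binomial_point_probability,
    binomial_upper_tail,
    count_significant_per_bipartition,
    enumerate_bipartitions,
    expected_count,
    segregation_from_counts,
)


def exact_point_probability(k, n, p_num, p_den):
    """Independent oracle: exact rational binomial point mass."""
    p = Fraction(p_num, p_den)
    return comb(n, k) * p ** k * (1 - p) ** (n - k)


class TestEnumerate:
    @pytest.mark.parametrize("n_ids, expected", [(6, 10), (4, 3), (2, 1)])
    def test_counts(self, n_ids, expected):
        ids = [f"S{i}" for i in range(n_ids)]
        bps = enumerate_bipartitions(ids)
        assert len(bps) == expected
        assert len(set(bps)) == expected          # no duplicates
        for bp in bps:
            assert set(bp.side_a) | set(bp.side_b) == set(ids)
            assert bp.side_a[0] == "S0"           # canonical anchoring

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            enumerate_bipartitions(["a", "b", "c"])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(1, 4))
    def test_matches_closed_form(self, m):
        ids = [f"x{i}" for i in range(2 * m)]
        assert len(enumerate_bipartitions(ids)) == comb(2 * m, m) // 2


class TestExpectedCount:
    @pytest.mark.parametrize("case, other, expected", [
        (79, 54, 13.3),       # plasma
        (109, 141, 25.0),     # PBMC
        (0, 0, 0.0),
    ])
    def test_values(self, case, other, expected):
        assert expected_count(case, other) == pytest.approx(expected)

    def test_invalid_bipartition_count(self):
        with pytest.raises(ValueError):
            expected_count(1, 1, 0)


class TestBinomialPointProbability:
    def test_symmetric_half(self):
        assert binomial_point_probability(1, 2, 0.5) == pytest.approx(0.5)

    def test_pbmc_published_value(self):
        v = binomial_point_probability(109, 250, 0.1)
        assert v == pytest.approx(4.2e-43, abs=0.05e-43)

    def test_plasma_recomputation(self):
        # recomputes to 2.4e-44; the printed value is 2.4e-43 (see docs)
        v = binomial_point_probability(79, 133, 0.1)
        assert v == pytest.approx(2.4e-44, rel=0.02)
        assert v <= 2.4e-43

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            binomial_point_probability(5, 3, 0.1)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 300), st.data())
    def test_against_exact_rational_oracle(self, n, data):
        k = data.draw(st.integers(0, n))
        exact = float(exact_point_probability(k, n, 1, 10))
        got = binomial_point_probability(k, n, 0.1)
        assert got == pytest.approx(exact, rel=1e-10, abs=5e-324)

    @pytest.mark.parametrize("n", [1, 7, 133, 250, 500])
    def test_pmf_sums_to_one(self, n):
        total = sum(binomial_point_probability(k, n, 0.1) for k in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_upper_tail_consistency(self):
        k, n, p = 6, 20, 0.3
        expected = sum(binomial_point_probability(j, n, p)
                       for j in range(k, n + 1))
        assert binomial_upper_tail(k, n, p) == pytest.approx(expected,
                                                             rel=1e-12)


class TestSegregationResult:
    def _bp(self, ids=("S1", "S2", "S3", "S4", "S5", "S6")):
        return Bipartition.of(ids[:3], ids[3:])

    def test_empty_counts(self):
        bps = enumerate_bipartitions([f"S{i}" for i in range(1, 7)])
        res = segregation_from_counts({bp: 0 for bp in bps}, bps[0])
        assert res.expected == 0.0
        assert res.point_probability == pytest.approx(1.0)

    def test_published_plasma_arithmetic(self):
        bps = enumerate_bipartitions([f"S{i}" for i in range(1, 7)])
        case = self._bp()
        # the 9 non-case bipartitions carry 54 events in total
        others = [bp for bp in bps if bp != case]
        counts = {bp: 6 for bp in others}
        counts[case] = 79
        res = segregation_from_counts(counts, case)
        assert res.s_case == 79 and res.s_other == 54
        assert res.expected == pytest.approx(13.3)
        assert res.case_rank == 1

    def test_published_pbmc_probability(self):
        bps = enumerate_bipartitions([f"S{i}" for i in range(1, 7)])
        case = self._bp()
        others = [bp for bp in bps if bp != case]
        counts = {bp: c for bp, c in zip(others,
                                         [16, 16, 16, 16, 16, 16, 16, 16, 13])}
        counts[case] = 109
        res = segregation_from_counts(counts, case)
        assert res.s_other == 141
        assert res.expected == pytest.approx(25.0)
        assert res.point_probability == pytest.approx(4.2e-43, abs=0.05e-43)

    def test_expected_invariant_under_other_relabelling(self):
        bps = enumerate_bipartitions([f"S{i}" for i in range(1, 7)])
        case = self._bp()
        others = [bp for bp in bps if bp != case]
        base = dict(zip(others, [9, 0, 3, 7, 5, 8, 2, 11, 9]))
        rng = np.random.default_rng(3)
        expectations = set()
        for _ in range(5):
            perm = rng.permutation(9)
            counts = {bp: base[others[j]] for bp, j in zip(others, perm)}
            counts[case] = 17
            expectations.add(segregation_from_counts(counts, case).expected)
        assert len(expectations) == 1

    def test_all_identical_samples_count_zero(self):
        from collections import Counter
        from srnaprof.preprocess import SampleLibrary
        from srnaprof.profiling import species_frequency_table

        libs = [SampleLibrary(f"S{i}", counts=Counter({"AAAAA": 5}))
                for i in range(6)]
        table = species_frequency_table(libs, ["AAAAA"])
        per = count_significant_per_bipartition(table)
        assert set(per.values()) == {0}
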