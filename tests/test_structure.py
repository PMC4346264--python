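"""Guide-RNA classification, half-tRNA folding, complex building, cleavage."""

import pytest
from hypothesis import given, settings, strategies as st

from srnaprof._rna import pairs
from srnaprof.structure import (
    classify_sgrna,
    find_target_sites,
    fold_half_trna,
    predict_cleavage,
    reverse_complement_rna,
)
from .conftest import RNA_Y_46, Y4_31

rna = st.text(alphabet="ACGU", min_size=1, max_size=60)


class TestReverseComplement:
    @pytest.mark.parametrize("seq, expected", [
        ("A", "U"),
        ("GGCUGGUCC", "GGACCAGCC"),   # guide arm vs its target site
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement_rna(seq) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(rna)
    def test_involution(self, seq):
        assert reverse_complement_rna(reverse_complement_rna(seq)) == seq

    def test_invalid_base(self):
        with pytest.raises(ValueError):
            reverse_complement_rna("ACGT")


class TestClassify:
    def test_heptamer_by_length(self):
        assert "heptamer" in classify_sgrna("ACGUACG")

    def test_printed_14mer_is_linear(self):
        assert "linear14" in classify_sgrna("CGCGACCUCAGAUC")

    def test_y4_fragment_is_half_trna(self):
        assert "half_tRNA" in classify_sgrna(Y4_31)

    def test_structured_14mer_is_not_linear(self):
        # GGGC....GCCC folds a 4-bp hairpin, excluding the linear class
        assert "linear14" not in classify_sgrna("GGGCAAAAAAGCCC")

    def test_hook_needs_5prime_guide_segment(self):
        hook = "AAGAAGAAGGGCAAAAGCCCA"      # 21 nt, hairpin after 7-nt arm
        assert "hook" in classify_sgrna(hook)


class TestFold:
    def test_homopolymer_cannot_fold(self):
        assert fold_half_trna("A" * 25) is None

    def test_constructed_hairpin(self):
        # 8-nt arm + GCGC stem + AAAA loop + GCGC complement + AU tail
        seq = "AAGAAGAA" + "GCGC" + "AAAA" + "GCGC" + "AU"
        fold = fold_half_trna(seq)
        assert fold is not None
        assert fold.arm_len == 8
        assert fold.hairpin.stem_len == 4
        assert fold.hairpin.loop_len == 4

    def test_constructed_matches_exhaustive_oracle(self):
        seq = "AAGAAGAA" + "GCGC" + "AAAA" + "GCGC" + "AU"
        best = max(self._oracle(seq), key=lambda t: (t[0], -t[1], -t[2]))
        fold = fold_half_trna(seq)
        assert (fold.hairpin.stem_len, fold.hairpin.stem5_start - 1,
                fold.hairpin.loop_len) == (best[0], best[1], best[2])

    def test_y4_arm_covers_first_nine(self):
        fold = fold_half_trna(Y4_31)
        assert fold.acceptor_arm == "GGCUGGUCC"
        assert fold.arm_len == 9

    @staticmethod
    def _oracle(seq, stem_range=(3, 7), loop_range=(3, 11), arm_min=7):
        """Brute-force stem-loop enumeration, written independently."""
        found = []
        for i in range(arm_min, len(seq)):
            for s in range(stem_range[0], stem_range[1] + 1):
                for loop in range(loop_range[0], loop_range[1] + 1):
                    j = i + s + loop
                    if j + s > len(seq):
                        continue
                    if all(pairs(seq[i + k], seq[j + s - 1 - k])
                           for k in range(s)):
                        found.append((s, i, loop))
        return found


class TestTargetSites:
    def test_y4_rnay_single_top_complex(self):
        complexes = find_target_sites(Y4_31, RNA_Y_46)
        assert len(complexes) >= 1
        top = complexes[0]
        assert top.duplex_len == 9
        assert top.guide_positions == (1, 9)
        assert top.target_positions == (29, 37)
        assert top.discriminator == 38
        # no other complex reaches 9 bp
        assert sum(c.duplex_len == 9 for c in complexes) == 1

    def test_pairings_verified_base_by_base(self):
        for c in find_target_sites(Y4_31, RNA_Y_46):
            lo, hi = c.target_positions
            for k in range(c.duplex_len):
                assert pairs(c.guide[k], c.target[hi - 1 - k])

    def test_no_complement_no_complex(self):
        assert find_target_sites(Y4_31, "A" * 40) == []

    def test_duplex_without_discriminator_rejected(self):
        # target = exact complement of the guide's 9-nt arm, nothing 3' of it
        target = "GGGCAAAAAGCCC" + reverse_complement_rna(Y4_31[:9])
        with_disc = target + "G"
        assert find_target_sites(Y4_31, target) == []
        hits = find_target_sites(Y4_31, with_disc)
        assert hits and hits[0].discriminator == len(with_disc)

    def test_exhaustive_vs_bruteforce_random(self):
        import numpy as np
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGU"))
        checked = 0
        for _ in range(40):
            guide = "".join(rng.choice(bases, size=int(rng.integers(26, 41))))
            target = "".join(rng.choice(bases, size=int(rng.integers(20, 61))))
            got = find_target_sites(guide, target)
            expected = self._bruteforce(guide, target)
            assert sorted((c.duplex_len, c.target_positions) for c in got) == \
                sorted(expected)
            checked += len(got)
        assert checked >= 0

    @staticmethod
    def _bruteforce(guide, target, min_bp=7, window=30,
                    tstem_min=4, tloop=(5, 9)):
        """Independent scan over all duplex end positions."""
        fold = fold_half_trna(guide)
        if fold is None:
            return []
        found = []
        for e in range(len(target) - 1):
            L = 0
            while (L < len(guide) and e - L >= 0
                   and pairs(guide[L], target[e - L])):
                L += 1
            L = min(L, fold.arm_len)
            if L < min_bp:
                continue
            start = e - L + 1                      # 0-based site start
            up = target[max(0, start - window):start]
            ok = False
            for i in range(len(up)):
                for s in range(tstem_min, len(up)):
                    for loop in range(tloop[0], tloop[1] + 1):
                        j = i + s + loop
                        if j + s > len(up):
                            continue
                        if all(pairs(up[i + k], up[j + s - 1 - k])
                               for k in range(s)):
                            ok = True
            if ok:
                found.append((L, (start + 1, e + 1)))
        found.sort(key=lambda t: (-t[0], t[1][0]))
        return found


class TestPredictCleavage:
    def test_y4_rnay_products(self):
        top = find_target_sites(Y4_31, RNA_Y_46)[0]
        d, p5, p3 = predict_cleavage(top)
        assert (d, p5, p3) == (38, 38, 8)

    def test_products_sum_to_target_length(self):
        for c in find_target_sites(Y4_31, RNA_Y_46):
            _, p5, p3 = predict_cleavage(c)
            assert p5 + p3 == len(RNA_Y_46)

    def test_terminal_discriminator(self):
        target = "GGGCAAAAAGCCC" + reverse_complement_rna(Y4_31[:9]) + "G"
        c = find_target_sites(Y4_31, target)[0]
        d, p5, p3 = predict_cleavage(c)
        assert p3 == 0 and p5 == len(target)

    def test_translation_covariance(self):
        base = "GGGCAAAAAGCCC" + reverse_complement_rna(Y4_31[:9])
        site1 = find_target_sites(Y4_31, base + "GA")[0]
        site2 = find_target_sites(Y4_31, "A" + base + "GA")[0]
        assert site2.cleavage_site == site1.cleavage_site + 1
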