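"""Canonicalization, demultiplexing, trimming, artifact and length filters."""

from collections import Counter

import pytest

from srnaprof._rna import AlphabetError
from srnaprof.preprocess import (
    FIVE_PRIME_ADAPTER_CORE,
    FIVE_PRIME_REMNANT,
    THREE_PRIME_ADAPTER,
    AdapterConfig,
    SmallRNARead,
    TrimReject,
    canonicalize,
    demultiplex,
    demultiplex_with_flag,
    filter_artifacts,
    length_select,
    preprocess_reads,
    trim_adapters,
)
from .conftest import Y4_31


@pytest.mark.parametrize("raw, expected", [
    ("acgt", "ACGU"),
    ("GGCUGGUCC", "GGCUGGUCC"),     # fixed point
    ("TtUu", "UUUU"),
])
def test_canonicalize(raw, expected):
    assert canonicalize(raw) == expected


def test_canonicalize_rejects_ambiguity_codes():
    with pytest.raises(AlphabetError):
        canonicalize("ACGN")


class TestDemultiplex:
    table = {"S1": "GAAA", "S5": "CAAA"}

    def _read(self, barcode):
        return SmallRNARead("r", FIVE_PRIME_REMNANT + barcode + "GGCC")

    def test_exact_match(self):
        assert demultiplex(self._read("GAAA"), self.table) == "S1"

    def test_no_match_at_zero_tolerance(self):
        assert demultiplex(self._read("GCAA"), self.table) == "UNASSIGNED"

    def test_ambiguous_within_tolerance(self):
        # AAAA is Hamming distance 1 from both GAAA and CAAA
        sid, flag = demultiplex_with_flag(self._read("AAAA"), self.table,
                                          max_bc_mismatch=1)
        assert sid == "UNASSIGNED" and flag == "ambiguous"

    def test_unique_within_tolerance(self):
        sid = demultiplex(self._read("GAUA"), self.table, max_bc_mismatch=1)
        assert sid == "S1"


class TestTrim:
    cfg = AdapterConfig()

    def _read(self, insert, barcode="GAAA"):
        return SmallRNARead("r", FIVE_PRIME_REMNANT + barcode + insert
                            + THREE_PRIME_ADAPTER)

    def test_exact_surgery(self):
        assert trim_adapters(self._read("GGCUGGU"), self.cfg) == "GGCUGGU"

    def test_adapter_dimer_rejected(self):
        with pytest.raises(TrimReject, match="adapter-dimer"):
            trim_adapters(self._read(""), self.cfg)

    def test_one_seed_mismatch_tolerated(self):
        bases = FIVE_PRIME_REMNANT + "GAAA" + "GGCUGGU" + \
            "AUGUCGUA" + THREE_PRIME_ADAPTER[8:]   # seed with 1 substitution
        assert trim_adapters(SmallRNARead("r", bases), self.cfg) == "GGCUGGU"

    def test_two_seed_mismatches_rejected(self):
        bases = FIVE_PRIME_REMNANT + "GAAA" + "GGCUGGU" + \
            "AGGUCGUA" + THREE_PRIME_ADAPTER[8:]
        with pytest.raises(TrimReject, match="no adapter"):
            trim_adapters(SmallRNARead("r", bases), self.cfg)

    def test_leftmost_occurrence_wins(self):
        insert = "CCAUG"
        bases = (FIVE_PRIME_REMNANT + "GAAA" + insert + THREE_PRIME_ADAPTER
                 + THREE_PRIME_ADAPTER)
        assert trim_adapters(SmallRNARead("r", bases), self.cfg) == insert


class TestArtifactFilter:
    cfg = AdapterConfig()

    def test_adapter_substring_dropped(self):
        fragment = FIVE_PRIME_ADAPTER_CORE[5:17]       # 12-nt exact substring
        assert filter_artifacts(fragment, self.cfg) is False

    def test_y4_fragment_kept(self):
        assert filter_artifacts(Y4_31, self.cfg) is True

    def test_below_min_match_len_kept(self):
        assert filter_artifacts(FIVE_PRIME_ADAPTER_CORE[:7], self.cfg) is True

    def test_one_mismatch_still_dropped(self):
        frag = list(FIVE_PRIME_ADAPTER_CORE[5:17])
        frag[6] = "A" if frag[6] != "A" else "C"
        assert filter_artifacts("".join(frag), self.cfg) is False


@pytest.mark.parametrize("length, lo, hi, keep", [
    (31, 5, 40, True),
    (4, 5, 40, False),
    (41, 5, 40, False),
    (7, 7, 7, True),       # degenerate lo == hi window
])
def test_length_select(length, lo, hi, keep):
    assert length_select("A" * length, lo, hi) is keep


def test_length_select_rejects_inverted_window():
    with pytest.raises(ValueError):
        length_select("AAAAA", 10, 5)


@pytest.fixture(scope="module")
def processed(simulated_run, adapter_config):
    return preprocess_reads(simulated_run.reads, adapter_config)


class TestRoundTrip:
    """Noise-free synthetic reads are recovered exactly, with full accounting."""

    def test_insert_multiset_recovered_exactly(self, simulated_run, processed):
        libraries, _ = processed
        truth = simulated_run.truth.per_sample_insert_counts
        for sid, lib in libraries.items():
            in_window = Counter({s: c for s, c in truth[sid].items()
                                 if 5 <= len(s) <= 40})
            assert lib.counts == in_window

    def test_window_overflow_goes_to_length_fate(self, simulated_run, processed):
        _, acct = processed
        truth = simulated_run.truth.per_sample_insert_counts
        for sid in truth:
            over = sum(c for s, c in truth[sid].items() if len(s) > 40)
            assert acct.loc[sid, "dropped_length"] == over

    def test_artifacts_dropped_exactly(self, simulated_run, processed):
        _, acct = processed
        spec = simulated_run.spec
        n_art = round(spec.artifact_fraction * spec.reads_per_sample)
        for sid in spec.sample_ids:
            dropped = (acct.loc[sid, "dropped_artifact"]
                       + acct.loc[sid, "rejected_adapter_dimer"])
            assert dropped == n_art

    def test_accounting_conserves_reads(self, simulated_run, processed):
        _, acct = processed
        assert acct["total"].sum() == len(simulated_run.reads)
        assert (acct.drop(columns="total").sum(axis=1) == acct["total"]).all()
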