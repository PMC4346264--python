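"""Shared fixtures: printed reference sequences and one reusable synthetic run."""

import pytest

from srnaprof.preprocess import AdapterConfig
from srnaprof.synthetic import (SyntheticSpec, build_stratum_models,
                                make_reference_set, simulate_libraries)

# the two sequences every structural claim is exercised on
Y4_31 = "GGCUGGUCCGAUGGUAGUGGGUUAUCAGAAC"
RNA_Y_46 = "GGAGUUCUAGAUUCCAGGUUCGACUCCUGGACCAGCCGGUGUAAGC"


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=11, reads_per_sample=10_000)


@pytest.fixture(scope="session")
def reference(default_spec):
    return make_reference_set(default_spec)


@pytest.fixture(scope="session")
def stratum_models(default_spec, reference):
    return build_stratum_models(default_spec, reference)


@pytest.fixture(scope="session")
def simulated_run(default_spec, reference):
    """One full read-level synthetic run shared by preprocessing tests."""
    return simulate_libraries(default_spec, reference)


@pytest.fixture(scope="session")
def adapter_config(default_spec):
    return AdapterConfig(barcode_table=dict(default_spec.barcode_table))
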