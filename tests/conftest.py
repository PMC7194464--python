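from __future__ import annotations

import pytest

from phasilens import preprocess, synth


@pytest.fixture(scope="session")
def truth42() -> synth.TruthSet:
    return synth.build_truth_set(seed=42)


@pytest.fixture(scope="session")
def reads42(truth42):
    return synth.simulate_srna_library(truth42)


@pytest.fixture(scope="session")
def records42(reads42):
    return preprocess.collapse_reads([r.sequence for r in reads42])


@pytest.fixture(scope="session")
def clean_truth() -> synth.TruthSet:
    """Noise-free truth set for exact-recovery tests."""
    return synth.build_truth_set(synth.clean_config(), seed=7)


@pytest.fixture(scope="session")
def clean_reads(clean_truth):
    return synth.simulate_srna_library(clean_truth)


@pytest.fixture(scope="session")
def clean_records(clean_reads):
    return preprocess.collapse_reads([r.sequence for r in clean_reads])
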