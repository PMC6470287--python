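import numpy as np
import pytest

from bsfc import synth
from bsfc.netstats import load_partition


@pytest.fixture(scope="session")
def region_labels():
    return list(load_partition().index)


@pytest.fixture(scope="session")
def small_labels():
    return [f"P{i:02d}" for i in range(20)]


@pytest.fixture(scope="session")
def bs_pattern():
    """A 400 s burst-suppression pattern with its exact intervals."""
    params = synth.BSSimParams(total_duration=400.0, sample_rate=500.0)
    return synth.simulate_bs_pattern(params, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_labels):
    """14 BS + 6 SW runs, 20 parcels, two subjects, with ground truth."""
    runs = (
        tuple(synth.RunSpec("O", "BS", 5.0 + 2.0 * i, f"O-b{i}") for i in range(10))
        + tuple(synth.RunSpec("T", "BS", 5.0 + 2.0 * i, f"T-b{i}") for i in range(4))
        + tuple(synth.RunSpec("O", "SW", 0.0, f"O-s{i}") for i in range(4))
        + tuple(synth.RunSpec("T", "SW", 0.0, f"T-s{i}") for i in range(2))
    )
    spec = synth.CohortSpec(("O", "T"), runs)
    bold = synth.BOLDSimParams(n_parcels=len(small_labels))
    records = synth.simulate_cohort(
        spec, bold, seed=2024, region_labels=small_labels,
        with_eeg=False, pattern_sample_rate=100.0,
    )
    return spec, records
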