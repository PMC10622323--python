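import pytest

from epivef import templates_from_pairs
from epivef.bs_simulator import SimProfile, make_reference, simulate_templates


@pytest.fixture(scope="session")
def small_ref():
    """6 kb balanced-GC reference shared by simulation-based tests."""
    return make_reference(6_000, 0.5, seed=101)


@pytest.fixture(scope="session")
def mixed_pairs(small_ref):
    """300 half-methylated read pairs — a heterogeneous small sample."""
    profile = SimProfile(n_templates=300, cg_methylation=0.5,
                         ch_conversion=0.97, seed=202)
    pairs, truth = simulate_templates(small_ref, profile)
    return pairs, truth


@pytest.fixture(scope="session")
def mixed_templates(mixed_pairs):
    return templates_from_pairs(mixed_pairs[0], min_mapq=0, min_baseq=0)
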