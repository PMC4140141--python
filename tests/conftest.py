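import hypothesis
import pytest

from methylprofile import SimConfig, compute_probe_stats, filter_significant, simulate

hypothesis.settings.register_profile(
    "det", derandomize=True, database=None, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("det")

SMALL_GROUPS = {"immune": 300, "cellcycle": 100, "stable": 80}


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study: three groups, strong immune hypomethylation."""
    return simulate(SimConfig(genes_per_group=dict(SMALL_GROUPS), seed=7))


@pytest.fixture(scope="session")
def small_stats(small_study):
    return compute_probe_stats(small_study.beta, small_study.annotation)


@pytest.fixture(scope="session")
def small_sig(small_stats):
    return filter_significant(small_stats)
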