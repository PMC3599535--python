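import numpy as np
import pytest

from domainage.phylostrata import Clade, CladeRanking, DEFAULT_RANKING


@pytest.fixture
def ranking():
    return DEFAULT_RANKING


@pytest.fixture
def small_ranking():
    """Reduced two-clade/four-species ranking for exhaustive profile scans."""
    return CladeRanking(
        clades=(
            Clade("young", ("a1", "a2")),
            Clade("old", ("b1", "b2")),
        ),
        merged_ranks=frozenset({1}),
        merged_label="Old",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20130220)
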