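import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Phase I legitimately warns when condition (*) fails on unlucky forests.
warnings.filterwarnings("ignore", message=".*condition \\(\\*\\).*")


@pytest.fixture
def default_costs():
    from dtlslice import EventCosts

    return EventCosts()


@pytest.fixture
def two_species_slices():
    from dtlslice import slice_species_tree

    return slice_species_tree("(A,B);")


@pytest.fixture
def one_dup_instance(two_species_slices, default_costs):
    """Gene tree with one duplication against the (A,B) species tree."""
    from dtlslice import compute_cost_matrix, parse_gene_tree

    G = parse_gene_tree("((A-1,B-1),(A-2,B-2));")
    M = compute_cost_matrix(G, two_species_slices, default_costs)
    return G, two_species_slices, M
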