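import random

import pytest

from dcjsub.genome_model import genome_from_lists, partition_markers
from dcjsub.adjacency_graph import build_adjacencies, build_graph, components
from dcjsub.potentials import PotentialSummary, upper_bound_distance
from dcjsub.recombination import dcjsub_distance


def make_pair(chroms_a, chroms_b):
    """Build a genome pair from (markers, circular) chromosome lists."""
    return (
        genome_from_lists("A", chroms_a),
        genome_from_lists("B", chroms_b),
    )


def graph_of(a, b):
    p = partition_markers(a, b)
    g = build_graph(build_adjacencies(a, p, "A"), build_adjacencies(b, p, "B"), p)
    return p, g, components(g)


def bound_of(a, b):
    p, g, comps = graph_of(a, b)
    return upper_bound_distance(g, p, PotentialSummary.from_components(comps))


@pytest.fixture
def substitution_pair():
    """One linear chromosome each; s,u in A replaced by x,y in B."""
    return make_pair(
        [(["a", "s", "u", "b"], False)],
        [(["a", "x", "y", "b"], False)],
    )


def random_small_pair(trial, max_common=4, max_unique=2, max_dcj=2, max_subst=2):
    """Seeded small instance from the planted-scenario generator, or None."""
    from dcjsub.oracle_sim import random_genome_pair

    rng = random.Random(trial)
    n_common = rng.randint(0, max_common)
    n_subst = rng.randint(0, max_subst)
    nua = rng.randint(0, max_unique) if n_subst else 0
    nub = rng.randint(0, max_unique) if n_subst else 0
    if n_subst > nua + nub:
        n_subst = 1 if (nua + nub) else 0
    if n_common == 0 and nua == 0:
        n_common = 1
    n_dcj = rng.randint(0, max_dcj)
    try:
        return random_genome_pair(n_common, nua, nub, n_dcj, n_subst, seed=trial)
    except ValueError:
        return None
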