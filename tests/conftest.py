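import itertools

import numpy as np
import pytest

from morphoclock.mk_likelihood import mk_transition_matrix
from morphoclock.trees import TimeTree


@pytest.fixture
def cherry4() -> TimeTree:
    """Balanced 4-tip tree, root age 2."""
    return TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def caterpillar5() -> TimeTree:
    return TimeTree.from_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


def brute_force_loglik(
    tree: TimeTree,
    branch_lengths: np.ndarray,
    column: np.ndarray,
    k: int,
    site_rates: np.ndarray,
) -> float:
    """Independent oracle: sum the joint probability over every assignment
    of states to internal nodes and missing tips (uniform root), averaged
    over equal-weight site-rate categories."""
    free = [i for i in range(tree.n_tips) if column[i] < 0]
    free += list(range(tree.n_tips, tree.n_nodes - 1))
    total = 0.0
    for r in site_rates:
        mats = [mk_transition_matrix(k, branch_lengths[v] * r)
                for v in range(tree.n_nodes - 1)]
        for root_state in range(k):
            for assign in itertools.product(range(k), repeat=len(free)):
                st = list(column) + [0] * (tree.n_tips - 1)
                st[tree.n_nodes - 1] = root_state
                for i, v in enumerate(free):
                    st[v] = assign[i]
                p = 1.0 / k
                for v in range(tree.n_nodes - 1):
                    p *= mats[v][st[tree.parent[v]], st[v]]
                total += p
    return float(np.log(total / len(site_rates)))
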