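"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized log-space
code paths: they enumerate the product-sum likelihood and Bayes posterior
with exact ``fractions.Fraction`` arithmetic (for rational inputs) or
naive Python loops, so the tests compare two independent routes.
"""

from fractions import Fraction

import numpy as np
import pytest

from yhap import (
    HaplogroupTree,
    SimulationSpec,
    build_marker_matrix,
    parse_tree,
    simulate_dataset,
    simulate_markers,
    simulate_tree,
)


@pytest.fixture
def tiny_tree() -> HaplogroupTree:
    return parse_tree("(A,B)R;")


@pytest.fixture(scope="session")
def tree20() -> HaplogroupTree:
    return simulate_tree(20, seed=42)


@pytest.fixture(scope="session")
def dataset():
    """Default study-condition cohort (20 leaves, M=40, 1.5x, 0.5% error)."""
    return simulate_dataset(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def dataset_h_star(dataset):
    from yhap import augment

    H = build_marker_matrix(dataset.tree, dataset.markers)
    return augment(H, dataset.likelihoods)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def exact_posterior(alt_probs, lik, prior):
    """Bayes posterior over nodes by direct product-sum enumeration with
    Fraction arithmetic.

    alt_probs: (N, L) rationals; lik: (N, 2) rationals for one sample;
    prior: length-L rationals.  Returns (posteriors, evidence) as Fractions.
    """
    L = len(alt_probs[0])
    joint = []
    for l in range(L):
        p = Fraction(prior[l])
        for i in range(len(alt_probs)):
            a = Fraction(alt_probs[i][l])
            g0, g1 = Fraction(lik[i][0]), Fraction(lik[i][1])
            p *= g0 * (1 - a) + g1 * a
        joint.append(p)
    ev = sum(joint)
    return [p / ev for p in joint], ev


def naive_log_likelihood(alt_col, lik_col):
    """Non-log product over sites for one node and one sample (floats)."""
    p = 1.0
    for a, (g0, g1) in zip(alt_col, lik_col):
        p *= g0 * (1.0 - a) + g1 * a
    return np.log(p)


def random_rational_instance(rng, n_sites, n_nodes, denom=16):
    """Random small instance with k/denom rational entries (exactly
    representable as floats), suitable for the Fraction oracle."""
    alt = [
        [Fraction(int(rng.integers(0, denom + 1)), denom) for _ in range(n_nodes)]
        for _ in range(n_sites)
    ]
    lik = [
        (
            Fraction(int(rng.integers(1, denom + 1)), denom),
            Fraction(int(rng.integers(1, denom + 1)), denom),
        )
        for _ in range(n_sites)
    ]
    w = [1 + int(rng.integers(0, 5)) for _ in range(n_nodes)]
    prior = [Fraction(x, sum(w)) for x in w]
    return alt, lik, prior


def make_h_star(alt, node_labels, marker_rows=(), positions=None):
    """Hand-build an AugmentedMatrix from a (N, L) alt-prob array."""
    from yhap import AugmentedMatrix, Site

    alt = np.asarray(alt, dtype=float)
    n = alt.shape[0]
    positions = positions or [100 * (i + 1) for i in range(n)]
    sites = [Site(p, "A", "G") for p in positions]
    marker_rows = np.asarray(sorted(marker_rows), dtype=int)
    free_rows = np.array([i for i in range(n) if i not in set(marker_rows.tolist())])
    return AugmentedMatrix(sites, list(node_labels), alt, marker_rows, free_rows)


@pytest.fixture(scope="session")
def markers20(tree20):
    return simulate_markers(tree20, markers_per_branch=2, seed=7)
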