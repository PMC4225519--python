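import math

import numpy as np
import pytest

from conftest import make_h_star
from yhap import (
    EMConfig,
    HaplogroupPrior,
    LikelihoodMatrix,
    SimulationSpec,
    Site,
    assign_cohort,
    augment,
    build_marker_matrix,
    e_step,
    m_step,
    observed_log_likelihood,
    restrict_nodes,
    run_em,
    sample_log_likelihood,
    simulate_dataset,
)


def make_G(lik):
    lik = np.asarray(lik, dtype=float)
    sites = [Site(100 * (i + 1), "A", "G") for i in range(lik.shape[0])]
    return LikelihoodMatrix(sites, [f"S{j}" for j in range(lik.shape[1])], lik)


class TestEStep:
    def test_uniform_everything_gives_uniform_responsibilities(self):
        h = make_h_star([[0.5, 0.5]], ["X", "Y"], marker_rows=())
        G = make_G(np.ones((1, 1, 2)))
        r = e_step(G, h, HaplogroupPrior.uniform(["X", "Y"]), ["X", "Y"])
        np.testing.assert_allclose(r, [[0.5, 0.5]])

    def test_equals_assignment_posteriors(self, dataset, dataset_h_star):
        h_star, g = dataset_h_star
        active = dataset.tree.leaf_labels
        prior = HaplogroupPrior.uniform(active)
        r = e_step(g, h_star, prior, active)
        res = assign_cohort(g, h_star, prior, active)
        for j in range(g.n_samples):
            np.testing.assert_array_equal(r[j], res[j].posterior)
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    def test_hard_assignment_hard_genotypes_degenerate_average(self):
        """All samples assigned to one node, all carrying the alt allele at a
        free site, no smoothing: the free vector becomes {0,1}."""
        h = make_h_star([[0.5, 0.5]], ["X", "Y"])
        G = make_G(np.tile([0.0, 1.0], (1, 4, 1)))
        r = np.tile([1.0, 0.0], (4, 1))
        cfg = EMConfig(pseudocount=0.0)
        new, prior = m_step(G, r, h, ["X", "Y"], cfg)
        assert new.alt_probs[0, 0] == 1.0
        np.testing.assert_allclose(prior.probs, [1.0, 0.0])

    def test_split_responsibility_updates_symmetrically(self):
        h = make_h_star([[0.5, 0.5]], ["X", "Y"])
        G = make_G(np.array([[[0.0, 1.0]]]))
        r = np.array([[0.5, 0.5]])
        new, _ = m_step(G, r, h, ["X", "Y"], EMConfig(pseudocount=0.0))
        assert new.alt_probs[0, 0] == new.alt_probs[0, 1] == 1.0

    @pytest.mark.parametrize("mode", ["posterior", "likelihood"])
    def test_matches_explicit_loop_oracle(self, mode):
        """Random 5-site, 3-node, 8-sample instance: the vectorized update
        equals a brute-force weighted-average computed with plain loops."""
        rng = np.random.default_rng(21)
        F, M, A = 5, 8, 3
        alt = rng.uniform(0.05, 0.95, size=(F, A))
        lik = rng.uniform(0.01, 1.0, size=(F, M, 2))
        r = rng.dirichlet(np.ones(A), size=M)
        labels = ["X", "Y", "Z"]
        h = make_h_star(alt, labels)
        cfg = EMConfig(pseudocount=0.3, soft_genotype=mode)
        new, prior = m_step(make_G(lik), r, h, labels, cfg)
        c = cfg.pseudocount
        for i in range(F):
            for a in range(A):
                num, den = c, 2 * c
                for j in range(M):
                    if mode == "posterior":
                        w0 = lik[i, j, 0] * (1 - alt[i, a])
                        w1 = lik[i, j, 1] * alt[i, a]
                    else:
                        w0, w1 = lik[i, j, 0], lik[i, j, 1]
                    q1 = w1 / (w0 + w1)
                    num += r[j, a] * q1
                    den += r[j, a]
                assert new.alt_probs[i, a] == pytest.approx(num / den, abs=1e-12)
        expected_prior = (r.sum(axis=0) + c / A) / (M + c)
        np.testing.assert_allclose(prior.probs, expected_prior / expected_prior.sum(), atol=1e-12)

    def test_marker_rows_never_updated(self):
        alt = np.array([[1.0, 0.0], [0.5, 0.5]])
        h = make_h_star(alt, ["X", "Y"], marker_rows=(0,))
        G = make_G(np.tile([0.0, 1.0], (2, 3, 1)))
        r = np.tile([0.6, 0.4], (3, 1))
        new, _ = m_step(G, r, h, ["X", "Y"], EMConfig())
        np.testing.assert_array_equal(new.alt_probs[0], alt[0])
        assert not np.array_equal(new.alt_probs[1], alt[1])


class TestObservedLogLikelihood:
    def test_single_sample_single_node(self):
        alt = np.array([[0.3], [0.8]])
        lik = np.array([[[0.9, 0.2]], [[0.1, 1.0]]])
        h = make_h_star(alt, ["X"])
        val = observed_log_likelihood(make_G(lik), h, HaplogroupPrior(["X"], [1.0]), ["X"])
        expect = sample_log_likelihood(lik[:, 0, :], np.stack([1 - alt[:, 0], alt[:, 0]], axis=1))
        assert val == pytest.approx(expect, abs=1e-12)

    def test_rescaling_shifts_by_additive_constant(self):
        rng = np.random.default_rng(4)
        alt = rng.uniform(0, 1, size=(4, 3))
        lik = rng.uniform(0.01, 1, size=(4, 5, 2))
        labels = ["X", "Y", "Z"]
        h = make_h_star(alt, labels)
        prior = HaplogroupPrior.uniform(labels)
        base = observed_log_likelihood(make_G(lik), h, prior, labels)
        scale = rng.uniform(0.5, 3.0, size=(4, 5, 1))
        scaled = observed_log_likelihood(make_G(lik * scale), h, prior, labels)
        assert scaled - base == pytest.approx(float(np.log(scale).sum()), rel=1e-10)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(6)
        alt = rng.uniform(0, 1, size=(6, 4))
        lik = rng.uniform(0.01, 1, size=(6, 5, 2))
        labels = list("WXYZ")
        h = make_h_star(alt, labels)
        pr = rng.dirichlet(np.ones(4))
        prior = HaplogroupPrior(labels, pr)
        expect = 0.0
        for j in range(5):
            tot = 0.0
            for a in range(4):
                p = pr[a]
                for i in range(6):
                    p *= lik[i, j, 0] * (1 - alt[i, a]) + lik[i, j, 1] * alt[i, a]
                tot += p
            expect += math.log(tot)
        got = observed_log_likelihood(make_G(lik), h, prior, labels)
        assert got == pytest.approx(expect, rel=1e-10)


class TestRunEM:
    def test_no_free_rows_converges_immediately(self, tiny_tree):
        from yhap import MarkerRecord

        H = build_marker_matrix(tiny_tree, [MarkerRecord("m", 10, "A", "G", "A", True)])
        lik = np.array([[[1.0, 1e-10], [1e-10, 1.0]]])
        G = LikelihoodMatrix([Site(10, "A", "G")], ["S1", "S2"], lik)
        h_star, g = augment(H, G)
        state = run_em(g, h_star, ["A", "B"], EMConfig())
        assert state.converged
        np.testing.assert_array_equal(state.h_star.alt_probs, h_star.alt_probs)
        # assignments under the final state equal plain assignment with its prior
        res = assign_cohort(g, state.h_star, state.prior, ["A", "B"])
        for j, r in enumerate(res):
            np.testing.assert_allclose(r.posterior, state.responsibilities[j], atol=1e-12)

    def test_trace_nondecreasing_across_seeds(self):
        """Observed-data log-likelihood never decreases (1e-8 slack) on
        seeded random cohorts."""
        for seed in range(5):
            data = simulate_dataset(
                SimulationSpec(n_leaves=8, cohort_size=12, mean_depth=1.0, seed=seed)
            )
            H = build_marker_matrix(data.tree, data.markers)
            h_star, g = augment(H, data.likelihoods)
            state = run_em(
                g, h_star, restrict_nodes(data.tree, "leaves"),
                EMConfig(max_iters=40), strict=True,
            )
            deltas = np.diff(state.loglik_trace)
            assert np.all(deltas >= -1e-8)

    def test_marker_rows_bit_identical_after_em(self, dataset, dataset_h_star):
        h_star, g = dataset_h_star
        before = h_star.alt_probs[h_star.marker_rows].copy()
        state = run_em(g, h_star, dataset.tree.leaf_labels, EMConfig(max_iters=10))
        np.testing.assert_array_equal(
            state.h_star.alt_probs[state.h_star.marker_rows], before
        )

    def test_recovers_clade_private_alleles(self):
        """Free rows at clade-private sites converge toward the planted
        allele when carriers are well covered."""
        data = simulate_dataset(
            SimulationSpec(
                n_leaves=5, markers_per_branch=2, private_free_sites_per_leaf=3,
                shared_noise_sites=5, cohort_size=25, mean_depth=4.0, seed=9,
            )
        )
        H = build_marker_matrix(data.tree, data.markers)
        h_star, g = augment(H, data.likelihoods)
        active = data.tree.leaf_labels
        state = run_em(g, h_star, active, EMConfig())
        pos2row = {s.pos: i for i, s in enumerate(state.h_star.sites)}
        col = {lab: state.h_star.node_order.index(lab) for lab in active}
        vals = [
            state.h_star.alt_probs[pos2row[data.truth.sites[i].pos],
                                   col[data.truth.private_leaf[i]]]
            for i in data.truth.planted_sites()
        ]
        assert np.mean(np.asarray(vals) > 0.9) >= 0.8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EMConfig(max_iters=0)
        with pytest.raises(ValueError):
            EMConfig(tol=0)
        with pytest.raises(ValueError):
            EMConfig(pseudocount=-1)
        with pytest.raises(ValueError):
            EMConfig(soft_genotype="other")
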