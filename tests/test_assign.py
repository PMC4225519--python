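import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import exact_posterior, make_h_star, random_rational_instance
from yhap import (
    HaplogroupPrior,
    LikelihoodMatrix,
    Site,
    assign_cohort,
    posterior_for_sample,
    read_assignments,
    restrict_nodes,
    rollup_major,
    sample_log_likelihood,
    simulate_tree,
    write_assignments,
)
from yhap.errors import EmptyNodeSetError, NumericalUnderflowError, ShapeError, UnknownNodeError


class TestSampleLogLikelihood:
    def test_perfect_match_has_probability_one(self):
        assert sample_log_likelihood([[1.0, 0.0]], [[1.0, 0.0]]) == 0.0

    def test_uninformative_node_gives_half(self):
        assert sample_log_likelihood([[1.0, 0.0]], [[0.5, 0.5]]) == pytest.approx(
            math.log(0.5)
        )

    def test_missing_site_contributes_zero(self):
        base = sample_log_likelihood([[0.7, 0.2]], [[0.4, 0.6]])
        extended = sample_log_likelihood(
            [[0.7, 0.2], [1.0, 1.0]], [[0.4, 0.6], [0.3, 0.7]]
        )
        assert extended == pytest.approx(base, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            sample_log_likelihood([[1.0, 0.0]], [[1.0, 0.0], [0.5, 0.5]])

    def test_matches_naive_product_oracle(self):
        rng = np.random.default_rng(8)
        G = rng.uniform(0.01, 1.0, size=(50, 2))
        a = rng.uniform(0.0, 1.0, size=50)
        H = np.stack([1 - a, a], axis=1)
        naive = float(np.log(np.prod(G[:, 0] * H[:, 0] + G[:, 1] * H[:, 1])))
        assert sample_log_likelihood(G, H) == pytest.approx(naive, rel=1e-10)


class TestPosterior:
    def test_symmetric_nodes_split_mass(self):
        h = make_h_star([[0.3, 0.3]], ["X", "Y"])
        prior = HaplogroupPrior.uniform(["X", "Y"])
        r = posterior_for_sample([[0.5, 0.9]], h, prior, ["X", "Y"])
        np.testing.assert_allclose(r.posterior, [0.5, 0.5])
        assert r.map_prob == 0.5
        assert r.map_call == "X" and r.tie  # preorder tie-break, flagged

    def test_hand_worked_bayes_example(self):
        """3 nodes, 4 sites, rational inputs: matches the exact Fraction
        computation (values frozen from the oracle)."""
        alt = [[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 0.5], [0.25, 0.75, 0.5]]
        lik = [[1, 0.1], [0.25, 1], [1, 1], [0.5, 1]]
        h = make_h_star(np.array(alt, dtype=float), ["X", "Y", "Z"])
        prior = HaplogroupPrior.uniform(["X", "Y", "Z"])
        r = posterior_for_sample(np.array(lik, float), h, prior, ["X", "Y", "Z"])
        np.testing.assert_allclose(
            r.posterior,
            [0.013605442176870748, 0.7619047619047619, 0.22448979591836735],
            atol=1e-12,
        )
        assert r.map_call == "Y"
        assert r.log_evidence == pytest.approx(-0.9602099658089905, abs=1e-12)

    def test_matches_fraction_oracle_on_small_instances(self):
        """Posteriors agree with exact rational Bayes enumeration to 1e-12
        on random instances with N <= 6 sites and L <= 5 nodes."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            n, L = int(rng.integers(1, 7)), int(rng.integers(2, 6))
            alt, lik, prior_fracs = random_rational_instance(rng, n, L)
            expected, _ = exact_posterior(alt, lik, prior_fracs)
            labels = [f"N{k}" for k in range(L)]
            h = make_h_star(np.array(alt, dtype=float), labels)
            prior = HaplogroupPrior(labels, np.array(prior_fracs, dtype=float))
            r = posterior_for_sample(np.array(lik, dtype=float), h, prior, labels)
            np.testing.assert_allclose(
                r.posterior, [float(p) for p in expected], atol=1e-12
            )

    def test_degenerate_prior_forces_posterior(self):
        h = make_h_star([[0.9, 0.1]], ["X", "Y"])
        prior = HaplogroupPrior(["X", "Y"], [0.0, 1.0])
        r = posterior_for_sample([[1.0, 1e-10]], h, prior, ["X", "Y"])
        np.testing.assert_array_equal(r.posterior, [0.0, 1.0])

    def test_uninformative_site_changes_nothing(self):
        rng = np.random.default_rng(3)
        alt = rng.uniform(0, 1, size=(5, 3))
        lik = rng.uniform(0.01, 1, size=(5, 2))
        labels = ["X", "Y", "Z"]
        prior = HaplogroupPrior.uniform(labels)
        base = posterior_for_sample(lik, make_h_star(alt, labels), prior, labels)
        alt2 = np.vstack([alt, [[0.5, 0.5, 0.5]]])
        lik2 = np.vstack([lik, [[1.0, 1.0]]])
        ext = posterior_for_sample(lik2, make_h_star(alt2, labels), prior, labels)
        np.testing.assert_allclose(ext.posterior, base.posterior, atol=1e-12)

    def test_underflow_without_floor_is_reported(self):
        h = make_h_star([[1.0, 1.0]], ["X", "Y"])  # both nodes require alt
        prior = HaplogroupPrior.uniform(["X", "Y"])
        with pytest.raises(NumericalUnderflowError):
            posterior_for_sample([[1.0, 0.0]], h, prior, ["X", "Y"])

    def test_empty_active_set(self):
        h = make_h_star([[0.5]], ["X"])
        with pytest.raises(EmptyNodeSetError):
            HaplogroupPrior.uniform([])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_scale_invariance(self, seed):
        """Multiplying any sample's likelihood vectors by positive constants
        leaves every posterior unchanged (likelihoods, not probabilities)."""
        rng = np.random.default_rng(seed)
        alt = rng.uniform(0, 1, size=(6, 4))
        lik = rng.uniform(0.01, 1, size=(6, 2))
        labels = list("WXYZ")
        prior = HaplogroupPrior.uniform(labels)
        h = make_h_star(alt, labels)
        base = posterior_for_sample(lik, h, prior, labels)
        scaled = posterior_for_sample(
            lik * rng.uniform(0.5, 200.0, size=(6, 1)), h, prior, labels
        )
        np.testing.assert_allclose(scaled.posterior, base.posterior, atol=1e-12)


class TestRestrictNodes:
    def test_levels_on_tiny_tree(self, tiny_tree):
        assert restrict_nodes(tiny_tree, "leaves") == ["A", "B"]
        assert restrict_nodes(tiny_tree, "all") == ["R", "A", "B"]
        # single-letter labels A, B and R all fall in the default A-T set
        assert restrict_nodes(tiny_tree, "major") == ["A", "B", "R"]

    def test_finest_level_has_311_haplogroups(self):
        t = simulate_tree(311, seed=1)
        assert len(restrict_nodes(t, "leaves")) == 311

    def test_configured_major_must_exist(self, tiny_tree):
        assert restrict_nodes(tiny_tree, "major", ["R"]) == ["R"]
        with pytest.raises(UnknownNodeError):
            restrict_nodes(tiny_tree, "major", ["Q"])


class TestCohort:
    def test_single_sample_cohort_matches_scalar_path(self, dataset, dataset_h_star):
        h_star, g = dataset_h_star
        active = dataset.tree.leaf_labels
        prior = HaplogroupPrior.uniform(active)
        res = assign_cohort(g, h_star, prior, active)
        r0 = posterior_for_sample(
            g.lik[:, 0, :], h_star, prior, active, sample_id=g.sample_ids[0]
        )
        # pairwise summation order differs between the (N,1) and (N,M) paths
        np.testing.assert_allclose(res[0].posterior, r0.posterior, rtol=1e-12, atol=1e-300)

    def test_permutation_equivariance(self, dataset, dataset_h_star):
        h_star, g = dataset_h_star
        active = dataset.tree.leaf_labels
        prior = HaplogroupPrior.uniform(active)
        res = assign_cohort(g, h_star, prior, active)
        perm = np.random.default_rng(2).permutation(g.n_samples)
        g2 = LikelihoodMatrix(
            g.sites, [g.sample_ids[j] for j in perm], g.lik[:, perm, :]
        )
        res2 = assign_cohort(g2, h_star, prior, active)
        for k, j in enumerate(perm):
            assert res2[k].sample_id == res[j].sample_id
            assert res2[k].map_call == res[j].map_call
            # identical up to summation-order float noise in the N-site product
            np.testing.assert_allclose(
                res2[k].posterior, res[j].posterior, rtol=1e-10, atol=1e-300
            )

    def test_posteriors_normalized(self, dataset, dataset_h_star):
        h_star, g = dataset_h_star
        active = dataset.tree.leaf_labels
        res = assign_cohort(g, h_star, HaplogroupPrior.uniform(active), active)
        for r in res:
            assert r.posterior.sum() == pytest.approx(1.0, abs=1e-9)
            assert r.map_prob == r.posterior.max()


class TestReports:
    def test_rollup_sums_leaf_posteriors(self, dataset, dataset_h_star):
        h_star, g = dataset_h_star
        tree = dataset.tree
        active = tree.leaf_labels
        res = assign_cohort(g, h_star, HaplogroupPrior.uniform(active), active)
        majors = [tree.labels[c] for c in tree.children[tree.index[tree.root]]]
        df = rollup_major(res, tree, majors)
        for r, (_, row) in zip(res, df.iterrows()):
            for m in majors:
                manual = sum(
                    p for lab, p in zip(r.node_order, r.posterior)
                    if lab in tree.leaf_set(m)
                )
                assert row[m] == pytest.approx(manual, abs=1e-12)
            assert sum(row[m] for m in majors) == pytest.approx(1.0, abs=1e-9)

    def test_assignment_tsv_round_trip(self, tmp_path, dataset, dataset_h_star):
        h_star, g = dataset_h_star
        active = dataset.tree.leaf_labels
        res = assign_cohort(g, h_star, HaplogroupPrior.uniform(active), active)
        path = tmp_path / "assignments.tsv"
        write_assignments(res, path)
        back = read_assignments(path)
        for a, b in zip(res, back):
            assert (a.sample_id, a.map_call, a.tie) == (b.sample_id, b.map_call, b.tie)
            np.testing.assert_array_equal(a.posterior, b.posterior)
            assert a.log_evidence == b.log_evidence
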