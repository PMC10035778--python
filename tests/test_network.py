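import warnings

import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.network import assemble_network, nodewise_fit

FAST = dict(folds=5, l1_ratios=(0.5, 1.0), n_alphas=20)


def make_fit(node, neighbors, treatment=0.0, interactions=None, p=4):
    nb = np.zeros(p)
    for j, w in neighbors.items():
        nb[j] = w
    it = np.zeros(p)
    for j, w in (interactions or {}).items():
        it[j] = w
    return {
        "node": node,
        "neighbors": nb,
        "treatment": treatment,
        "interactions": it,
        "alpha": 0.1,
        "l1_ratio": 1.0,
        "n_rows": 100,
    }


class TestAssembly:
    def test_and_rule_requires_both_directions(self):
        fits = [
            make_fit(0, {1: 0.3}),
            make_fit(1, {0: 0.0}),
            make_fit(2, {}),
            make_fit(3, {}),
        ]
        pairwise, *_ = assemble_network(fits)
        assert pairwise[0, 1] == 0.0

    def test_edge_weight_is_mean_of_both_directions(self):
        fits = [
            make_fit(0, {1: 0.2}),
            make_fit(1, {0: 0.4}),
            make_fit(2, {3: 0.5}, interactions={3: 0.1}),
            make_fit(3, {2: -0.5}, interactions={2: 0.3}),
        ]
        pairwise, direct, moderation, _, _ = assemble_network(fits)
        assert pairwise[0, 1] == pytest.approx(0.3)
        assert pairwise[1, 0] == pytest.approx(0.3)
        # conflicting signs zero the edge; the moderation term still averages
        assert pairwise[2, 3] == 0.0
        assert moderation[2, 3] == pytest.approx(0.2)

    def test_direct_comes_from_own_regression_only(self):
        fits = [make_fit(j, {}, treatment=0.1 * j) for j in range(4)]
        _, direct, *_ = assemble_network(fits)
        np.testing.assert_allclose(direct, [0.0, 0.1, 0.2, 0.3])

    def test_inconsistent_node_sets_rejected(self):
        fits = [make_fit(0, {}), make_fit(2, {}), make_fit(3, {}), make_fit(4, {})]
        with pytest.raises(ValueError, match="one fit per node"):
            assemble_network(fits)


def simulate_linear(n, seed, beta=(0.5, 0.5)):
    gen = np.random.default_rng(seed)
    X = gen.standard_normal((n, 4))
    y = X[:, 0] * beta[0] + X[:, 1] * beta[1] + gen.standard_normal(n)
    t = gen.binomial(1, 0.5, n)
    frame = np.column_stack([y, X])
    return frame, t


class TestNodewise:
    def test_full_shrinkage_zeroes_everything(self):
        frame, t = simulate_linear(200, 0)
        fit = nodewise_fit(frame, t, 0, alpha=1e6)
        assert (fit["neighbors"] == 0).all()
        assert fit["treatment"] == 0.0
        assert (fit["interactions"] == 0).all()

    def test_near_zero_penalty_recovers_ols(self):
        """With the penalty pushed to ~0 the coefficients approach the
        unpenalized least-squares oracle."""
        frame, t = simulate_linear(2000, 1)
        fit = nodewise_fit(frame, t, 0, alpha=1e-6, threshold=None)
        X = frame[:, 1:]
        Z = (X - X.mean(0)) / X.std(0)
        y = frame[:, 0]
        y = (y - y.mean()) / y.std()
        design = np.column_stack([Z, t, t[:, None] * Z])
        design = np.column_stack([np.ones(len(y)), design])
        ols = np.linalg.lstsq(design, y, rcond=None)[0][1:]
        est = np.concatenate(
            [fit["neighbors"][1:], [fit["treatment"]], fit["interactions"][1:]]
        )
        np.testing.assert_allclose(est, ols, atol=0.05)

    def test_permuted_outcome_selects_nothing(self):
        """With the outcome permuted there is no signal; the selected
        model should retain no predictors in nearly all repeats."""
        frame, t = simulate_linear(2000, 2)
        clean = 0
        reps = 20
        for seed in range(reps):
            gen = np.random.default_rng(seed)
            noisy = frame.copy()
            noisy[:, 0] = gen.permutation(noisy[:, 0])
            fit = nodewise_fit(noisy, t, 0, random_state=seed, **FAST)
            n_sel = (
                (fit["neighbors"] != 0).sum()
                + (fit["interactions"] != 0).sum()
                + (fit["treatment"] != 0)
            )
            clean += n_sel == 0
        assert clean >= 0.9 * reps

    def test_constant_outcome_warns_and_zeroes(self):
        frame, t = simulate_linear(100, 3)
        frame[:, 0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fit = nodewise_fit(frame, t, 0, **FAST)
        assert (fit["neighbors"] == 0).all()


class TestEstimator:
    def test_symmetry_and_zero_diagonal(self, item_frames, small_cohort):
        pre, post = item_frames
        cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
        est = sn.ModeratedNetworkEstimator(random_state=0, **FAST)
        est.fit(cm.values, small_cohort["treatment"].to_numpy())
        for mat in (est.pairwise_, est.moderation_):
            np.testing.assert_array_equal(mat, mat.T)
            np.testing.assert_array_equal(np.diag(mat), 0.0)
        assert est.node_labels_ == sn.NODE_LABELS

    def test_shrinkage_monotonicity(self, item_frames, small_cohort):
        """Edge count is non-increasing in the penalty weight on a fixed
        grid without re-CV."""
        pre, post = item_frames
        cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
        t = small_cohort["treatment"].to_numpy()
        counts = []
        for alpha in (0.01, 0.03, 0.1, 0.3, 1.0):
            est = sn.ModeratedNetworkEstimator(
                alpha=alpha, l1_ratio=1.0, threshold=None
            )
            est.fit(cm.values, t)
            counts.append(int((est.pairwise_ != 0).sum() // 2))
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_condition_on_treatment_additivity(self):
        est = sn.ModeratedNetworkEstimator()
        est.pairwise_ = np.array([[0, 0.03], [0.03, 0]])
        est.moderation_ = np.array([[0, 0.02], [0.02, 0]])
        est.node_labels_ = ["a", "b"]
        np.testing.assert_allclose(est.condition_on_treatment(1)[0, 1], 0.05)
        np.testing.assert_allclose(est.condition_on_treatment(0)[0, 1], 0.03)
        est.moderation_ = np.zeros((2, 2))
        np.testing.assert_array_equal(
            est.condition_on_treatment(0), est.condition_on_treatment(1)
        )
        with pytest.raises(ValueError):
            est.condition_on_treatment(2)

    def test_arm_specific_couplings_ordered_correctly(self):
        """Couplings of 0.1 (CfD) vs 0.4 (CBT) on one pair: the
        arm-conditional estimates recover the ordering."""
        from symptomnet.items import NODE_LABELS, item_columns

        wins = 0
        reps = 5
        for seed in range(reps):
            cfg = sn.CohortConfig(
                n_per_arm=2000,
                couplings=[(8, 6, 0.1)],
                moderation_effects=[(8, 6, 0.3)],
                direct_effects=np.zeros(16),
                seed=seed,
            )
            c = sn.generate_cohort(cfg)
            pre = c[item_columns("s2")].set_axis(NODE_LABELS, axis=1)
            post = c[item_columns("final")].set_axis(NODE_LABELS, axis=1)
            cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
            est = sn.ModeratedNetworkEstimator(random_state=seed, **FAST)
            est.fit(cm.values, c["treatment"].to_numpy())
            arm1 = est.condition_on_treatment(1)[8, 6]
            arm0 = est.condition_on_treatment(0)[8, 6]
            wins += arm1 > arm0
        assert wins >= 0.8 * reps

    def test_treatment_vector_validated(self, item_frames):
        pre, post = item_frames
        cm = sn.compute_change(pre, post, sn.ChangeSpec("DS"))
        est = sn.ModeratedNetworkEstimator(**FAST)
        with pytest.raises(ValueError, match="binary"):
            est.fit(cm.values, np.full(len(cm.values), 2.0))
        with pytest.raises(ValueError, match="same number of rows"):
            est.fit(cm.values, np.zeros(3))

    def test_edge_list_export(self, item_frames, small_cohort):
        pre, post = item_frames
        cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
        est = sn.ModeratedNetworkEstimator(random_state=0, **FAST)
        est.fit(cm.values, small_cohort["treatment"].to_numpy())
        edges = est.to_edge_list()
        assert set(edges["type"]) <= {"pairwise", "moderation", "direct"}
        n_pair = (edges["type"] == "pairwise").sum()
        assert n_pair == (est.pairwise_ != 0).sum() // 2
        g = est.to_networkx()
        assert g.number_of_edges() == n_pair


class TestBootstrap:
    def test_single_resample_inclusion_binary(self, item_frames, small_cohort):
        pre, post = item_frames
        cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
        summary = sn.bootstrap_network(
            cm.values, small_cohort["treatment"].to_numpy(), n_boot=1, seed=0, **FAST
        )
        for kind in ("pairwise", "direct", "moderation"):
            assert np.isin(summary.inclusion[kind], [0.0, 1.0]).all()
            assert (
                summary.quantile_low[kind] <= summary.quantile_high[kind] + 1e-12
            ).all()

    def test_seeded_determinism(self, item_frames, small_cohort):
        pre, post = item_frames
        cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
        t = small_cohort["treatment"].to_numpy()
        s1 = sn.bootstrap_network(cm.values, t, n_boot=3, seed=5, **FAST)
        s2 = sn.bootstrap_network(cm.values, t, n_boot=3, seed=5, **FAST)
        for kind in ("pairwise", "direct", "moderation"):
            np.testing.assert_array_equal(s1.inclusion[kind], s2.inclusion[kind])
            np.testing.assert_array_equal(s1.quantile_low[kind], s2.quantile_low[kind])

    def test_strong_edge_always_included(self):
        """A generating coupling of 0.5 at n=2000 is retained in every
        bootstrap resample."""
        from symptomnet.items import NODE_LABELS, item_columns

        cfg = sn.CohortConfig(
            n_per_arm=1000,
            couplings=[(0, 1, 0.5)],
            moderation_effects=[],
            direct_effects=np.zeros(16),
            seed=3,
        )
        c = sn.generate_cohort(cfg)
        pre = c[item_columns("s2")].set_axis(NODE_LABELS, axis=1)
        post = c[item_columns("final")].set_axis(NODE_LABELS, axis=1)
        cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
        summary = sn.bootstrap_network(
            cm.values, c["treatment"].to_numpy(), n_boot=20, seed=9, **FAST
        )
        assert summary.inclusion["pairwise"][0, 1] >= 0.95

    def test_invalid_n_boot(self, item_frames, small_cohort):
        pre, post = item_frames
        cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
        with pytest.raises(ValueError):
            sn.bootstrap_network(cm.values, small_cohort["treatment"], n_boot=0)

    def test_bootstrap_frame_layout(self, item_frames, small_cohort):
        pre, post = item_frames
        cm = sn.compute_change(pre, post, sn.ChangeSpec("RC"))
        summary = sn.bootstrap_network(
            cm.values, small_cohort["treatment"].to_numpy(), n_boot=2, seed=1, **FAST
        )
        frame = summary.to_frame()
        assert len(frame) == 2 * 120 + 16
        assert frame["inclusion"].between(0, 1).all()


class TestRedundancy:
    def test_duplicate_node_flagged(self, rng):
        X = rng.standard_normal((500, 5))
        X[:, 1] = X[:, 0]  # exact duplicate
        flagged = sn.redundancy_check(X)
        assert [(r.node_i, r.node_j) for r in flagged.itertuples()] == [(0, 1)]

    def test_independent_nodes_not_flagged(self):
        for seed in range(5):
            X = np.random.default_rng(seed).standard_normal((2000, 16))
            assert len(sn.redundancy_check(X)) == 0

    def test_strict_threshold_with_discordant_third_node(self, rng):
        # i and j highly correlated, but k tracks i only -> one clearly
        # discordant comparison defeats a threshold of 1.0
        n = 2000
        base = rng.standard_normal(n)
        X = np.column_stack(
            [
                base,
                0.9 * base + 0.45 * rng.standard_normal(n),
                base + 0.3 * rng.standard_normal(n),
                rng.standard_normal(n),
            ]
        )
        cfg = sn.RedundancyConfig(shared_threshold=1.0)
        flagged = sn.redundancy_check(X, cfg)
        assert not ((flagged.get("node_i") == 0) & (flagged.get("node_j") == 1)).any()

    def test_too_few_nodes_rejected(self, rng):
        with pytest.raises(ValueError, match="3 nodes"):
            sn.redundancy_check(rng.standard_normal((100, 2)))

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            sn.RedundancyConfig(shared_threshold=0.0)
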