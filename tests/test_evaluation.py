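"""Cross-validation folds, error measures and design accounting."""

import numpy as np
import pytest

import latentconn as lc
from latentconn import evaluation, synthetic


def masked_conn(p, n_observed, seed=0, K=2):
    rng = np.random.default_rng(seed)
    cells = np.argwhere(~np.eye(p, dtype=bool))
    keep = rng.choice(len(cells), size=n_observed, replace=False)
    mask = np.zeros((p, p), bool)
    mask[cells[keep, 0], cells[keep, 1]] = True
    w = rng.integers(0, K, size=(p, p))
    return lc.OrdinalConnectome([f"n{i}" for i in range(p)], w, mask, K)


class TestMakeFolds:
    def test_even_partition(self):
        conn = masked_conn(11, 100)
        folds = evaluation.make_folds(conn, 10, seed=1)
        assert [len(f.edges) for f in folds] == [10] * 10

    def test_remainder_distribution(self):
        conn = masked_conn(11, 101)
        folds = evaluation.make_folds(conn, 10, seed=1)
        sizes = sorted(len(f.edges) for f in folds)
        assert sizes == [10] * 9 + [11]

    def test_folds_partition_observed_edges(self):
        conn = masked_conn(9, 60)
        folds = evaluation.make_folds(conn, 7, seed=2)
        seen = np.vstack([f.edges for f in folds])
        assert len(seen) == 60
        assert len({(i, j) for i, j in seen}) == 60
        observed = {(i, j) for i, j in conn.observed_edges()}
        assert {(i, j) for i, j in seen} == observed

    def test_seed_determinism(self):
        conn = masked_conn(9, 40)
        a = evaluation.make_folds(conn, 5, seed=3)
        b = evaluation.make_folds(conn, 5, seed=3)
        c = evaluation.make_folds(conn, 5, seed=4)
        assert all(np.array_equal(x.edges, y.edges) for x, y in zip(a, b))
        assert any(
            not np.array_equal(x.edges, y.edges) for x, y in zip(a, c)
        )

    def test_too_few_edges_rejected(self):
        conn = masked_conn(4, 3)
        with pytest.raises(lc.ValidationError):
            evaluation.make_folds(conn, 10, seed=0)

    def test_masking_is_the_only_train_test_difference(self):
        conn = masked_conn(9, 50)
        folds = evaluation.make_folds(conn, 5, seed=5)
        train = conn.mask_edges(folds[0].edges)
        expect = conn.observed_mask.copy()
        expect[folds[0].edges[:, 0], folds[0].edges[:, 1]] = False
        assert np.array_equal(train.observed_mask, expect)
        assert np.array_equal(train.weights, conn.weights)


class TestErrorMeasures:
    def test_perfect_imputation_has_zero_mae(self):
        obs = np.array([0, 1, 2])
        assert evaluation.mae(np.tile(obs, (5, 1)), obs) == 0.0

    def test_single_edge_range_endpoint(self):
        assert evaluation.mae(np.array([[3]]), np.array([0])) == 3.0

    def test_hand_computed_mae(self):
        pred = np.array([[2, 0, 1]])
        obs = np.array([0, 0, 3])
        assert evaluation.mae(pred, obs) == pytest.approx(4 / 3)

    def test_perfect_predictions_have_zero_rates(self):
        obs = np.array([0, 1, 0, 2])
        rates = evaluation.fpr_fnr(np.tile(obs, (3, 1)), obs)
        assert rates == (0.0, 0.0)

    def test_all_predicted_present(self):
        obs = np.array([0, 0, 1, 1])
        fpr, fnr = evaluation.fpr_fnr(np.ones((2, 4), int), obs)
        assert (fpr, fnr) == (1.0, 0.0)

    def test_hand_computed_rates(self):
        # 4 truly absent (one falsely present), 6 truly present (two
        # falsely absent) -> FPR 1/4, FNR 2/6
        obs = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        pred = np.array([[1, 0, 0, 0, 0, 0, 1, 1, 1, 1]])
        fpr, fnr = evaluation.fpr_fnr(pred, obs)
        assert fpr == pytest.approx(0.25)
        assert fnr == pytest.approx(1 / 3)

    def test_one_sided_folds_flagged(self):
        obs = np.ones(3, int)
        with pytest.warns(UserWarning, match="FPR"):
            fpr, fnr = evaluation.fpr_fnr(np.ones((2, 3), int), obs)
        assert np.isnan(fpr) and fnr == 0.0

    def test_uniform_probabilities_score_log_K(self):
        f = np.full((5, 4), 0.25)
        obs = np.array([0, 1, 2, 3, 0])
        assert evaluation.held_out_nll(f, obs) == pytest.approx(np.log(4))

    def test_certain_truth_scores_zero(self):
        f = np.eye(3)[np.array([0, 1, 2])]
        assert evaluation.held_out_nll(f, np.array([0, 1, 2])) == 0.0

    def test_nll_matches_per_edge_loop(self, rng):
        f = rng.dirichlet(np.ones(4), size=8)
        obs = rng.integers(0, 4, size=8)
        expect = -np.mean([np.log(f[i, obs[i]]) for i in range(8)])
        assert evaluation.held_out_nll(f, obs) == pytest.approx(
            expect, abs=1e-12
        )

    def test_zero_probability_floored_with_warning(self):
        f = np.array([[1.0, 0.0]])
        with pytest.warns(UserWarning, match="clamped"):
            nll = evaluation.held_out_nll(f, np.array([1]))
        assert nll == pytest.approx(-np.log(1e-12))

    def test_empty_fold_rejected(self):
        with pytest.raises(lc.ValidationError):
            evaluation.mae(np.zeros((2, 0)), np.zeros(0))


class TestDesignCounts:
    def test_full_design_possible_connections(self):
        possible, observed, unobserved = evaluation.design_counts(32, 32, 32)
        assert possible == 992
        assert observed == 992
        assert unobserved == 0

    def test_injection_design(self):
        possible, observed, unobserved = evaluation.design_counts(91, 91, 29)
        assert (observed, unobserved) == (2610, 5580)

    def test_full_design_observed(self):
        _, observed, _ = evaluation.design_counts(49, 49, 49)
        assert observed == 2352

    @pytest.mark.parametrize("seed", range(5))
    def test_observed_plus_unobserved_is_always_p_p_minus_1(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 60))
        s = int(rng.integers(1, p + 1))
        t = int(rng.integers(1, s + 1))
        possible, observed, unobserved = evaluation.design_counts(p, s, t)
        assert possible == p * (p - 1)
        assert observed + unobserved == possible

    def test_label_sets_with_explicit_overlap(self):
        labels = list("abcde")
        possible, observed, _ = evaluation.design_counts(
            5, ["a", "b", "c"], ["c", "d"], labels=labels
        )
        assert observed == 3 * 2 - 1

    def test_labels_outside_region_list_rejected(self):
        with pytest.raises(lc.ValidationError, match="outside"):
            evaluation.design_counts(3, ["a", "z"], ["a"], labels=["a", "b", "c"])


class TestCrossvalSweep:
    @pytest.fixture(scope="class")
    def sweep(self):
        params = lc.generate_params(10, 2, 3, seed=31)
        inst = synthetic.generate_connectome(params, seed=32)
        cfg = lc.RunConfig(n_chains=1, n_warmup=80, n_samples=80, seed=33)
        return evaluation.crossval_sweep(
            inst.data, cfg, D_values=[1, 2], models=["lsm", "empirical"],
            n_folds=2,
        )

    def test_table_shape(self, sweep):
        # folds x D x models rows per metric
        assert len(sweep.table) == 2 * 2 * 2 * 4

    def test_empirical_scores_constant_in_D(self, sweep):
        t = sweep.table
        for metric in evaluation.METRICS:
            sel = t[(t["model"] == "empirical") & (t["metric"] == metric)]
            by_d = sel.groupby("D")["value"].apply(list)
            assert by_d[1] == by_d[2]

    def test_selected_D_is_nll_argmin(self, sweep):
        nll = {
            d: sweep.mean_metric("lsm", d, "nll") for d in (1, 2)
        }
        assert sweep.selected_D == min(nll, key=nll.get)

    def test_mae_within_range(self, sweep):
        vals = sweep.table[sweep.table["metric"] == "mae"]["value"]
        assert (vals >= 0).all() and (vals <= 2).all()


class TestReciprocity:
    def test_breakdown_emits_grouped_metrics(self):
        params = lc.generate_params(10, 1, 3, seed=35)
        inst = synthetic.generate_connectome(params, seed=36)
        # injection-style partial design so both groups are populated
        masked = synthetic.apply_design(inst, ("injection", 10, 6))
        cfg = lc.RunConfig(n_chains=1, n_warmup=60, n_samples=60, seed=37)
        rep = evaluation.crossval_sweep(
            masked.data, cfg, D_values=[1], models=["lsm"], n_folds=2,
            reciprocity_breakdown=True,
        )
        metrics = set(rep.table["metric"])
        assert {"nll_bidir", "nll_onedir", "mae_bidir", "mae_onedir"} <= metrics

    def test_groups_reflect_opposite_direction_mask(self):
        conn = masked_conn(6, 12, seed=9)
        edges = conn.observed_edges()
        both = evaluation.reciprocity_groups(conn, edges)
        for (i, j), flag in zip(edges, both):
            assert flag == conn.observed_mask[j, i]
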