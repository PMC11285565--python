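import numpy as np
import pytest

from memcpm import (CPMConfig, EdgeSelection, fit_fold, median_model, predict,
                    run_cpm, select_edges, summed_connectivity, transfer_model)
from memcpm.cpm import make_folds

from conftest import oracle_partial_selection


def _cov(rng, n):
    return {"ffd": np.abs(rng.normal(0.12, 0.05, n)),
            "age": rng.uniform(36, 100, n)}


class TestSelectEdges:
    def test_edge_equal_to_score_selected_positive(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        X = np.column_stack([y, rng.standard_normal(30)])
        sel = select_edges(X, y, None, alpha=0.01)
        assert 0 in sel.positive
        assert sel.negative.size == 0

    def test_confounded_edge_not_selected(self):
        # edge == covariate, score independent of both: residualizing on the
        # covariate removes the edge entirely, so partial r = 0 exactly
        rng = np.random.default_rng(1)
        c = rng.standard_normal(200)
        y = rng.standard_normal(200)
        sel = select_edges(c[:, None], y, c[:, None], alpha=0.5, keep_stats=True)
        assert sel.positive.size == 0 and sel.negative.size == 0
        assert abs(sel.r[0]) < 1e-6

    @pytest.mark.parametrize("n_cov", [0, 1, 3])
    def test_matches_residualization_oracle(self, n_cov):
        rng = np.random.default_rng(2)
        n, e = 50, 100
        X = rng.standard_normal((n, e))
        y = rng.standard_normal(n)
        C = rng.standard_normal((n, n_cov)) if n_cov else None
        # plant a few real associations so both sets are non-empty
        X[:, 0] += 2 * y
        X[:, 1] -= 2 * y
        sel = select_edges(X, y, C, alpha=0.05, keep_stats=True)
        pos_o, neg_o, r_o, p_o = oracle_partial_selection(X, y, C, 0.05)
        assert np.array_equal(sel.positive, pos_o)
        assert np.array_equal(sel.negative, neg_o)
        assert np.allclose(sel.r, r_o, atol=1e-10)
        assert np.allclose(sel.p, p_o, atol=1e-10)

    def test_no_covariates_equals_plain_pearson(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 30))
        y = rng.standard_normal(40)
        sel = select_edges(X, y, None, alpha=0.1, keep_stats=True)
        plain = np.array([np.corrcoef(X[:, e], y)[0, 1] for e in range(30)])
        assert np.allclose(sel.r, plain, atol=1e-10)

    def test_constant_edge_never_selected(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(30)
        X = np.column_stack([np.full(30, 2.0), y])
        sel = select_edges(X, y, None, alpha=0.5, keep_stats=True)
        assert 0 not in sel.positive and 0 not in sel.negative
        assert sel.r[0] == 0.0

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant score"):
            select_edges(np.random.default_rng(0).standard_normal((10, 3)),
                         np.ones(10), None)

    def test_disjoint_sign_sets_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            EdgeSelection(positive=[1, 2], negative=[2, 3])


class TestSummedConnectivity:
    def test_combined_arithmetic(self):
        sel = EdgeSelection(positive=[0], negative=[1])
        v = np.array([0.5, 0.2, 9.9])
        assert summed_connectivity(v, sel, "combined") == pytest.approx(0.3)
        assert summed_connectivity(v, sel, "positive") == pytest.approx(0.5)
        assert summed_connectivity(v, sel, "negative") == pytest.approx(0.2)

    def test_empty_negative_set_combined_equals_positive(self):
        sel = EdgeSelection(positive=[0, 2], negative=[])
        v = np.array([1.0, 5.0, 2.0])
        assert summed_connectivity(v, sel, "combined") == \
            summed_connectivity(v, sel, "positive")

    def test_all_zero_weights(self):
        sel = EdgeSelection(positive=[0], negative=[1])
        assert summed_connectivity(np.zeros(3), sel) == 0.0


class TestFitPredict:
    def test_two_point_line(self):
        sel = EdgeSelection(positive=[0], negative=[])
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 3.0])
        m = fit_fold(np.vstack([X, [[0.5]]]), np.array([1.0, 3.0, 2.0]), sel)
        assert m.slope == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert predict(m, np.array([[2.0]]))[0] == pytest.approx(5.0)

    def test_constant_scores_give_flat_model(self):
        sel = EdgeSelection(positive=[0], negative=[])
        X = np.array([[0.0], [1.0], [2.0]])
        m = fit_fold(X, np.full(3, 4.0), sel)
        assert m.slope == 0.0
        assert predict(m, np.array([[9.0]]))[0] == pytest.approx(4.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 200
        X = rng.standard_normal((n, 10))
        y = rng.standard_normal(n) + X[:, 0]
        sel = EdgeSelection(positive=[0, 3], negative=[7])
        m = fit_fold(X, y, sel)
        s = X[:, [0, 3]].sum(axis=1) - X[:, 7]
        D = np.column_stack([np.ones(n), s])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        assert m.slope == pytest.approx(beta[1], abs=1e-10)

    def test_empty_selection_degenerate_mean_fallback(self):
        sel = EdgeSelection(positive=[], negative=[])
        y = np.array([1.0, 2.0, 6.0])
        m = fit_fold(np.zeros((3, 4)), y, sel)
        assert m.degenerate
        assert predict(m, np.zeros((2, 4))) == pytest.approx([3.0, 3.0])


class TestRunCPM:
    def test_determinism_same_seed(self, null_cohort):
        X = null_cohort.edges["FACENAME"][:, :300]
        y = null_cohort.subjects["ravlt_ir"].to_numpy(float)
        cov = {"ffd": null_cohort.subjects["ffd_FACENAME"].to_numpy(),
               "age": null_cohort.subjects["age"].to_numpy()}
        cfg = CPMConfig(n_iterations=2, seed=42)
        a = run_cpm(X, y, cov, cfg)
        b = run_cpm(X, y, cov, cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.fold_assignment, rb.fold_assignment)
            assert np.array_equal(ra.predictions, rb.predictions)
            assert (ra.rho == rb.rho) or (np.isnan(ra.rho) and np.isnan(rb.rho))

    def test_each_subject_predicted_exactly_once_and_fold_sizes_balanced(self):
        rng = np.random.default_rng(6)
        for n, k in ((23, 5), (25, 5), (10, 3)):
            folds = make_folds(n, k, rng)
            sizes = np.bincount(folds, minlength=k)
            assert sizes.sum() == n
            assert sizes.max() - sizes.min() <= 1

    def test_null_cohort_rho_near_zero(self, null_cohort):
        X = null_cohort.edges["FACENAME"]
        y = null_cohort.subjects["ravlt_l"].to_numpy(float)
        cov = {"ffd": null_cohort.subjects["ffd_FACENAME"].to_numpy(),
               "age": null_cohort.subjects["age"].to_numpy()}
        runs = run_cpm(X, y, cov, CPMConfig(n_iterations=30, seed=8))
        rho = np.array([r.rho for r in runs])
        rho = rho[np.isfinite(rho)]
        se = rho.std(ddof=1) / np.sqrt(rho.size) + 1.0 / np.sqrt(len(y))
        assert abs(rho.mean()) < 3 * se + 0.1

    def test_planted_cohort_recovers_signal(self, planted_cohort):
        c = planted_cohort
        mask = c.sex_mask("F")
        X = c.edges["FACENAME"][mask]
        y = c.subjects.loc[mask, "ravlt_ir"].to_numpy(float)
        cov = {"ffd": c.subjects.loc[mask, "ffd_FACENAME"].to_numpy(),
               "age": c.subjects.loc[mask, "age"].to_numpy()}
        runs = run_cpm(X, y, cov, CPMConfig(n_iterations=20, seed=9))
        med = median_model(runs)
        assert med.rho > 0.3
        planted = {tuple(sorted(e[:2])) for e in
                   c.ground_truth["planted_edges"]["F"]}
        from memcpm.connectome import edge_pairs
        i, j = edge_pairs(c.atlas.n_nodes)
        pos_sel = np.concatenate([fm.selection.positive
                                  for fm in med.fold_models])
        hits = sum(1 for e in pos_sel if (int(i[e]), int(j[e])) in planted)
        assert hits / max(len(pos_sel), 1) > 0.5  # planted edges dominate

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            run_cpm(np.zeros((3, 5)), np.arange(3.0), None, CPMConfig(k_folds=5))


class TestMedianModel:
    def test_median_of_three(self):
        runs = _fake_runs([0.1, 0.5, 0.3])
        assert median_model(runs).rho == 0.3

    def test_single_iteration_is_itself(self):
        runs = _fake_runs([0.7])
        assert median_model(runs).index == 0

    def test_lower_median_for_even_count_with_tiebreak(self):
        runs = _fake_runs([0.4, 0.2, 0.4, 0.1])
        # sorted: 0.1, 0.2, 0.4(idx0), 0.4(idx2); rank ceil(4/2)=2 -> 0.2
        assert median_model(runs).rho == 0.2
        runs = _fake_runs([0.4, 0.4])
        assert median_model(runs).index == 0  # tie broken by lower index

    def test_large_ensemble_matches_sort_oracle(self):
        rng = np.random.default_rng(10)
        rho = rng.standard_normal(1000)
        runs = _fake_runs(rho.tolist())
        got = median_model(runs)
        order = sorted(range(1000), key=lambda k: (rho[k], k))
        assert got.index == order[499]  # rank 500 of 1000

    def test_nan_rho_excluded_from_ranking(self):
        runs = _fake_runs([0.5, float("nan"), 0.1, 0.9])
        assert median_model(runs).rho == 0.5


def _fake_runs(rhos):
    from memcpm.cpm import CPMIterationResult

    return [CPMIterationResult(index=k, fold_assignment=np.zeros(1, int),
                               fold_models=[], predictions=np.zeros(1),
                               rho=r, rmse=0.0)
            for k, r in enumerate(rhos)]


class TestTransfer:
    def test_disjoint_planted_sets_transfer_near_zero(self, planted_cohort):
        c = planted_cohort
        f, m = c.sex_mask("F"), c.sex_mask("M")
        y = c.subjects["ravlt_ir"].to_numpy(float)
        cov_f = {"ffd": c.subjects.loc[f, "ffd_FACENAME"].to_numpy(),
                 "age": c.subjects.loc[f, "age"].to_numpy()}
        cfg = CPMConfig(n_iterations=10, seed=11)
        tr = transfer_model(c.edges["FACENAME"][f], y[f], cov_f,
                            c.edges["FACENAME"][m], y[m], cfg)
        within = run_cpm(c.edges["FACENAME"][f], y[f], cov_f, cfg)
        assert abs(tr.rho_median) < 0.25
        assert median_model(within).rho > tr.rho_median

    def test_shared_core_transfer_positive_but_below_within(self, atlas60):
        from memcpm import GroundTruthSpec, generate_cohort
        from memcpm.cohort import within_network_pairs

        rng = np.random.default_rng(12)
        core = within_network_pairs(atlas60, "FP", 10, rng)
        extra_f = within_network_pairs(atlas60, "DMN", 10, rng)
        spec = GroundTruthSpec(
            n_female=120, n_male=120, scans=("FACENAME",), seed=31,
            score_noise_sd=0.0,
            planted_edges={"F": [(i, j, 0.5) for i, j in core + extra_f],
                           "M": [(i, j, 0.5) for i, j in core]})
        c = generate_cohort(spec, atlas60)
        f, m = c.sex_mask("F"), c.sex_mask("M")
        y = c.subjects["ravlt_l"].to_numpy(float)
        cfg = CPMConfig(n_iterations=10, seed=13, covariates=())
        tr = transfer_model(c.edges["FACENAME"][f], y[f], None,
                            c.edges["FACENAME"][m], y[m], cfg)
        within = median_model(run_cpm(c.edges["FACENAME"][f], y[f], None, cfg))
        assert tr.rho_median > 0.15          # shared core carries over
        assert within.rho > tr.rho_median    # but within-sex is stronger

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="empty target"):
            transfer_model(np.zeros((10, 4)), np.arange(10.0), None,
                           np.zeros((0, 4)), np.zeros(0), CPMConfig())
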