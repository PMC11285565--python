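import numpy as np
import pytest

from memcpm import (build_consensus, difference_map, intranetwork_heatmap,
                    summarize_internetwork)
from memcpm.consensus import internetwork_counts
from memcpm.cpm import CPMIterationResult, EdgeSelection, FoldModel


def make_run(selections, n_subjects=10):
    """Build CPM iteration results from explicit per-iteration, per-fold
    (positive, negative) edge-index lists."""
    runs = []
    for it, folds in enumerate(selections):
        models = [FoldModel(1.0, 0.0,
                            EdgeSelection(positive=pos, negative=neg),
                            False, f)
                  for f, (pos, neg) in enumerate(folds)]
        runs.append(CPMIterationResult(
            index=it, fold_assignment=np.zeros(n_subjects, int),
            fold_models=models, predictions=np.zeros(n_subjects),
            rho=0.0, rmse=0.0))
    return runs


class TestBuildConsensus:
    def test_two_folds_in_forty_percent_is_significant(self):
        # edge 0 positive in exactly 2 of 5 folds in 400 of 1000 iterations
        qualifying = [[([0], []), ([0], []), ([], []), ([], []), ([], [])]] * 400
        rest = [[([], []), ([], []), ([], []), ([], []), ([], [])]] * 600
        cons = build_consensus(make_run(qualifying + rest), n_edges_total=5)
        assert cons.significant_pos[0]
        assert not cons.significant_neg[0]
        assert cons.qualifying_pos[0] == 400
        assert cons.fold_count_pos[0] == 800

    def test_one_fold_every_iteration_never_qualifies(self):
        runs = make_run([[([3], []), ([], []), ([], []), ([], []), ([], [])]] * 50)
        cons = build_consensus(runs, n_edges_total=5)
        assert cons.qualifying_pos[3] == 0
        assert not cons.significant_pos[3]
        assert cons.fold_count_pos[3] == 50

    def test_just_below_forty_percent_not_significant(self):
        qualifying = [[([1], []), ([1], []), ([], [])]] * 3   # 3 of 10 iters
        rest = [[([], []), ([], []), ([], [])]] * 7
        cons = build_consensus(make_run(qualifying + rest), n_edges_total=3)
        assert not cons.significant_pos[1]
        cons2 = build_consensus(make_run(qualifying + qualifying[:1] + rest[:6]),
                                n_edges_total=3)
        assert cons2.significant_pos[1]  # 4 of 10 meets >= 0.40

    def test_randomized_run_matches_recount_oracle(self):
        rng = np.random.default_rng(18)
        k, iters, n_edges = 3, 10, 20
        selections = []
        for _ in range(iters):
            folds = []
            for _ in range(k):
                picks = rng.choice(n_edges, size=rng.integers(0, 6),
                                   replace=False)
                half = rng.random(picks.size) < 0.5
                folds.append((picks[half].tolist(), picks[~half].tolist()))
            selections.append(folds)
        cons = build_consensus(make_run(selections), n_edges_total=n_edges,
                               min_folds=2, iteration_fraction=0.4)
        # brute-force recount from the stored logs
        for e in range(n_edges):
            fp = sum(e in pos for folds in selections for pos, _ in folds)
            fn = sum(e in neg for folds in selections for _, neg in folds)
            qp = sum(sum(e in pos for pos, _ in folds) >= 2
                     for folds in selections)
            qn = sum(sum(e in neg for _, neg in folds) >= 2
                     for folds in selections)
            assert cons.fold_count_pos[e] == fp
            assert cons.fold_count_neg[e] == fn
            assert cons.qualifying_pos[e] == qp
            assert cons.qualifying_neg[e] == qn
            sig_p, sig_n = qp >= 0.4 * iters, qn >= 0.4 * iters
            if sig_p and sig_n:
                sig_p, sig_n = qp > qn, qn > qp
            assert cons.significant_pos[e] == sig_p
            assert cons.significant_neg[e] == sig_n

    def test_raising_fraction_never_adds_edges(self):
        rng = np.random.default_rng(19)
        selections = []
        for _ in range(20):
            folds = []
            for _ in range(5):
                picks = rng.choice(10, size=3, replace=False)
                folds.append((picks[:2].tolist(), picks[2:].tolist()))
            selections.append(folds)
        runs = make_run(selections)
        prev = None
        for frac in (0.2, 0.4, 0.6, 0.8):
            cons = build_consensus(runs, 10, iteration_fraction=frac)
            sig = set(np.flatnonzero(cons.significant_pos)) | \
                set(np.flatnonzero(cons.significant_neg))
            if prev is not None:
                assert sig <= prev
            prev = sig

    def test_both_sign_tie_excluded_and_logged(self):
        # edge 0 qualifies positively in 2 iterations and negatively in 2
        sel = ([[([0], []), ([0], []), ([], [])]] * 2 +
               [[([], [0]), ([], [0]), ([], [])]] * 2)
        cons = build_consensus(make_run(sel), 2, min_folds=2,
                               iteration_fraction=0.4)
        assert not cons.significant_pos[0] and not cons.significant_neg[0]
        assert cons.sign_ties == [0]

    def test_nondefault_k_fold_minimum_generalizes(self):
        # k = 8 -> ceil(0.4 * 8) = 4 folds required
        sel = [[([0], [])] * 3 + [([], [])] * 5] * 10
        cons = build_consensus(make_run(sel), 2)
        assert cons.min_folds == 4
        assert cons.qualifying_pos[0] == 0


class TestInternetwork:
    def test_three_ab_edges_normalized(self, toy_atlas):
        # A = nodes 0-2 (3 nodes), B = nodes 3-6 (4 nodes); 3 significant
        # A-B edges -> 3 / (3*4) = 0.25
        from memcpm.connectome import edge_index_of

        ab_edges = [edge_index_of(0, 3, 7), edge_index_of(1, 4, 7),
                    edge_index_of(2, 6, 7)]
        sel = [[(ab_edges, []), (ab_edges, []), ([], []), ([], []), ([], [])]] * 5
        cons = build_consensus(make_run(sel), n_edges_total=21)
        table = summarize_internetwork(cons, toy_atlas, "positive")
        assert table.loc["A", "B"] == pytest.approx(0.25)
        assert table.loc["B", "A"] == pytest.approx(0.25)
        assert table.loc["A", "A"] == 0.0

    def test_no_significant_edges_all_zero(self, toy_atlas):
        sel = [[([], [])] * 5] * 3
        cons = build_consensus(make_run(sel), n_edges_total=21)
        table = summarize_internetwork(cons, toy_atlas, "positive")
        assert (table.to_numpy() == 0).all()

    def test_random_consensus_matches_double_loop_oracle(self, toy_atlas):
        rng = np.random.default_rng(20)
        n_edges_total = 21
        flags = rng.random(n_edges_total) < 0.4
        sel_edges = np.flatnonzero(flags).tolist()
        sel = [[(sel_edges, []), (sel_edges, []), ([], []), ([], []), ([], [])]] * 5
        cons = build_consensus(make_run(sel), n_edges_total)
        table = summarize_internetwork(cons, toy_atlas, "positive")
        labels = toy_atlas.labels
        for a in ("A", "B"):
            for b in ("A", "B"):
                count = denom = 0
                for i in range(7):
                    for j in range(i + 1, 7):
                        pair = {labels[i], labels[j]}
                        if pair == ({a} | {b}):
                            from memcpm.connectome import edge_index_of
                            denom += 1
                            count += bool(flags[edge_index_of(i, j, 7)])
                assert table.loc[a, b] == pytest.approx(count / denom)

    def test_count_conservation(self, atlas60):
        rng = np.random.default_rng(22)
        E = 60 * 59 // 2
        sel_edges = np.flatnonzero(rng.random(E) < 0.05).tolist()
        sel = [[(sel_edges, []), (sel_edges, []), ([], []), ([], []), ([], [])]] * 5
        cons = build_consensus(make_run(sel), E)
        counts = internetwork_counts(cons, atlas60, "positive")
        total = int(cons.significant_pos.sum())
        upper = sum(counts.iloc[a, b] for a in range(10) for b in range(a, 10))
        assert upper == total


class TestDifferenceMap:
    def test_identical_summaries_zero(self, toy_atlas):
        import pandas as pd

        t = pd.DataFrame([[0.1, 0.2], [0.2, 0.3]], index=["A", "B"],
                         columns=["A", "B"])
        assert (difference_map(t, t).to_numpy() == 0).all()

    def test_all_zero_second_operand_is_identity(self, toy_atlas):
        import pandas as pd

        f = pd.DataFrame([[0.5, 0.1], [0.1, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        z = f * 0.0
        assert difference_map(f, z).equals(f)

    def test_cellwise_arithmetic(self):
        import pandas as pd

        a = pd.DataFrame([[1.0, 2.0], [2.0, 4.0]], index=["A", "B"],
                         columns=["A", "B"])
        b = pd.DataFrame([[0.5, 1.0], [1.0, 1.0]], index=["A", "B"],
                         columns=["A", "B"])
        d = difference_map(a, b)
        for i in ("A", "B"):
            for j in ("A", "B"):
                assert d.loc[i, j] == a.loc[i, j] - b.loc[i, j]

    def test_atlas_mismatch_rejected(self):
        import pandas as pd

        a = pd.DataFrame([[0.0]], index=["A"], columns=["A"])
        b = pd.DataFrame([[0.0]], index=["B"], columns=["B"])
        with pytest.raises(ValueError, match="atlas"):
            difference_map(a, b)


class TestIntranetwork:
    def test_always_selected_edge_hits_positive_bound(self, toy_atlas):
        from memcpm.connectome import edge_index_of

        e01 = edge_index_of(0, 1, 7)
        sel = [[([e01], [])] * 5] * 1000
        cons = build_consensus(make_run(sel), 21)
        h = intranetwork_heatmap(cons, toy_atlas, "A")
        assert h.bound == 5000
        assert h.matrix[0, 1] == 5000
        assert h.matrix[1, 0] == 5000

    def test_never_selected_edge_zero(self, toy_atlas):
        sel = [[([], [])] * 5] * 10
        cons = build_consensus(make_run(sel), 21)
        h = intranetwork_heatmap(cons, toy_atlas, "A")
        assert (h.matrix == 0).all()
        assert (h.summed_vector == 0).all()

    def test_summed_vector_is_half_row_sum(self, toy_atlas):
        from memcpm.connectome import edge_index_of

        e01, e02, e12 = (edge_index_of(a, b, 7) for a, b in
                         ((0, 1), (0, 2), (1, 2)))
        sel = [[([e01, e02], [e12])] * 3 + [([], [])] * 2] * 4
        cons = build_consensus(make_run(sel), 21)
        h = intranetwork_heatmap(cons, toy_atlas, "A")
        # each selected edge has fold count 3*4 = 12 with its sign
        expected = np.array([[0, 12, 12], [12, 0, -12], [12, -12, 0]])
        assert np.array_equal(h.matrix, expected)
        assert h.summed_vector == pytest.approx(expected.sum(axis=1) / 2)
        h2 = intranetwork_heatmap(cons, toy_atlas, "A", halve_sv=False)
        assert h2.summed_vector == pytest.approx(expected.sum(axis=1))

    def test_values_within_analytic_bounds(self, atlas60):
        rng = np.random.default_rng(23)
        E = 60 * 59 // 2
        sel = []
        for _ in range(7):
            folds = []
            for _ in range(5):
                picks = rng.choice(E, size=40, replace=False)
                folds.append((picks[:20].tolist(), picks[20:].tolist()))
            sel.append(folds)
        cons = build_consensus(make_run(sel), E)
        for nw in atlas60.networks:
            h = intranetwork_heatmap(cons, atlas60, nw)
            assert np.abs(h.matrix).max() <= h.bound == 35
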