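import itertools

import numpy as np
import pytest

from tdnd import DirectedNetwork, confusion, f_measure, roc


def net(genes, edges):
    n = DirectedNetwork(genes)
    for r, t in edges:
        n.add_edge(r, t)
    return n


def brute_force_confusion(pred_edges, truth_edges, genes):
    """Oracle: enumerate every ordered pair explicitly."""
    tp = tn = fp = fn = 0
    for a, b in itertools.permutations(genes, 2):
        p = (a, b) in pred_edges
        t = (a, b) in truth_edges
        tp += p and t
        fp += p and not t
        fn += t and not p
        tn += (not p) and (not t)
    return tp, tn, fp, fn


class TestConfusion:
    def test_perfect_prediction_all_metrics_one(self):
        genes = [f"g{k}" for k in range(5)]
        edges = [("g0", "g1"), ("g1", "g2"), ("g2", "g3"), ("g3", "g4"),
                 ("g4", "g0"), ("g0", "g2"), ("g1", "g3"), ("g2", "g4")]
        rep = confusion(net(genes, edges), net(genes, edges))
        assert rep.sensitivity == rep.precision == 1.0
        assert rep.f_measure == rep.specificity == 1.0

    def test_counts_match_exhaustive_enumeration(self, rng):
        genes = [f"g{k}" for k in range(6)]
        pairs = list(itertools.permutations(genes, 2))
        pred = {pairs[k] for k in rng.choice(30, size=9, replace=False)}
        truth = {pairs[k] for k in rng.choice(30, size=7, replace=False)}
        rep = confusion(net(genes, pred), net(genes, truth))
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == brute_force_confusion(
            pred, truth, genes
        )

    def test_count_conservation(self, rng):
        genes = [f"g{k}" for k in range(7)]
        pairs = list(itertools.permutations(genes, 2))
        for _ in range(10):
            pred = {pairs[k] for k in rng.choice(42, size=12, replace=False)}
            truth = {pairs[k] for k in rng.choice(42, size=10, replace=False)}
            rep = confusion(net(genes, pred), net(genes, truth))
            assert rep.tp + rep.tn + rep.fp + rep.fn == 7 * 6

    def test_swapping_pred_and_truth_swaps_fp_fn(self):
        genes = list("abcd")
        p = net(genes, [("a", "b"), ("b", "c")])
        t = net(genes, [("a", "b"), ("c", "d"), ("d", "a")])
        fwd = confusion(p, t)
        rev = confusion(t, p)
        assert (fwd.tp, fwd.tn) == (rev.tp, rev.tn)
        assert (fwd.fp, fwd.fn) == (rev.fn, rev.fp)

    def test_direction_matters_unless_undirected(self):
        genes = list("abc")
        p = net(genes, [("a", "b")])
        t = net(genes, [("b", "a")])
        assert confusion(p, t).tp == 0
        rep = confusion(p, t, undirected=True)
        assert rep.tp == 1 and rep.tp + rep.tn + rep.fp + rep.fn == 3

    def test_zero_division_conventions_flagged(self):
        genes = list("abc")
        rep = confusion(net(genes, []), net(genes, [("a", "b")]))
        assert rep.precision == 0.0 and rep.f_measure == 0.0
        assert any("precision" in f for f in rep.flags)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            confusion(net(list("abc"), []), net(list("abd"), []))

    def test_universe_argument_checks_membership(self):
        with pytest.raises(ValueError, match="outside"):
            confusion(net(list("abc"), []), net(list("ab"), []),
                      universe=["a", "b"])


class TestFMeasure:
    def test_consistency_with_reported_precision_recall_pair(self):
        # harmonic-mean identity on a representative benchmark operating point
        assert f_measure(0.2917, 0.8235) == pytest.approx(0.4308, abs=5e-5)

    def test_zero_convention(self):
        assert f_measure(0.0, 0.0) == 0.0


def rank_auc(scores_pos, scores_neg):
    """Oracle: Mann-Whitney statistic (ties counted half)."""
    wins = 0.0
    for p in scores_pos:
        for q in scores_neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(scores_pos) * len(scores_neg))


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        genes = list("abcd")
        truth = net(genes, [("a", "b"), ("c", "d")])
        s = np.zeros((4, 4))
        s[1, 0] = 1.0  # a -> b
        s[3, 2] = 1.0  # c -> d
        curve = roc(s, truth, genes)
        assert curve.auc == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_scores_give_half(self):
        genes = list("abcd")
        truth = net(genes, [("a", "b"), ("c", "d")])
        s = np.full((4, 4), 0.5)
        np.fill_diagonal(s, 0)
        assert roc(s, truth, genes).auc == pytest.approx(0.5, abs=1e-12)

    def test_matches_rank_statistic_oracle(self, rng):
        genes = list("abcd")
        truth = net(genes, [("a", "b"), ("b", "c"), ("d", "a")])
        # distinct weights on the 0.01 grid so the theta sweep resolves
        # every cut between consecutive scores
        s = np.zeros((4, 4))
        idx = {g: k for k, g in enumerate(genes)}
        weights = rng.choice(np.arange(1, 100), size=12, replace=False) / 100
        pos, neg = [], []
        k = 0
        for a, b in itertools.permutations(genes, 2):
            s[idx[b], idx[a]] = weights[k]
            (pos if (a, b) in truth.edges else neg).append(weights[k])
            k += 1
        curve = roc(s, truth, genes, grid_size=101)
        assert curve.auc == pytest.approx(rank_auc(pos, neg), abs=1e-9)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        genes = [f"g{k}" for k in range(5)]
        truth_edges = [("g0", "g1"), ("g1", "g2"), ("g2", "g0"), ("g3", "g4")]
        truth = net(genes, truth_edges)
        s = np.zeros((5, 5))
        idx = {g: k for k, g in enumerate(genes)}
        y, scores = [], []
        weights = rng.choice(np.arange(1, 200), size=20, replace=False) / 200
        for k, (a, b) in enumerate(itertools.permutations(genes, 2)):
            s[idx[b], idx[a]] = weights[k]
            y.append((a, b) in truth.edges)
            scores.append(weights[k])
        curve = roc(s, truth, genes, grid_size=201)
        assert curve.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-9)

    def test_curve_is_anchored_and_monotone(self, rng):
        genes = [f"g{k}" for k in range(5)]
        truth = net(genes, [("g0", "g1"), ("g2", "g3")])
        s = rng.uniform(0, 1, (5, 5))
        np.fill_diagonal(s, 0)
        curve = roc(s, truth, genes)
        pts = curve.points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all()

    def test_auc_invariant_under_monotone_rescaling(self, rng):
        genes = [f"g{k}" for k in range(5)]
        truth = net(genes, [("g0", "g1"), ("g2", "g3"), ("g1", "g4")])
        s = np.round(rng.uniform(0.05, 0.95, (5, 5)), 2)
        np.fill_diagonal(s, 0)
        a1 = roc(s, truth, genes, grid_size=1001).auc
        a2 = roc(s ** 2, truth, genes, grid_size=1001).auc
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_degenerate_truth_rejected(self):
        genes = list("abc")
        s = np.zeros((3, 3))
        with pytest.raises(ValueError, match="ROC undefined"):
            roc(s, net(genes, []), genes)
        full = [(a, b) for a, b in itertools.permutations(genes, 2)]
        with pytest.raises(ValueError, match="ROC undefined"):
            roc(s, net(genes, full), genes)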