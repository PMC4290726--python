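"""Scoring of predicted networks against a ground truth.

An edge's presence is the "positive" event; the candidate set is all
N(N−1) ordered gene pairs (self-loops excluded).  From the confusion
counts: sensitivity Se = TP/(TP+FN), precision Pr = TP/(TP+FP),
F-measure Fm = 2·Pr·Se/(Pr+Se), specificity Sp = TN/(TN+FP).  ROC curves
sweep the threshold θ over the weight matrix, plotting the true-positive
rate (Se) against the false-positive rate (1 − Sp); AUC is the trapezoidal
area after anchoring at (0,0) and (1,1).  Inferred delays are never scored
— only edge topology counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import DirectedNetwork

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "RocCurve", "confusion", "roc", "f_measure"]


def f_measure(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both are 0."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and derived metrics for one prediction."""

    tp: int
    tn: int
    fp: int
    fn: int
    flags: tuple[str, ...] = field(default=())

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f_measure(self) -> float:
        return f_measure(self.precision, self.sensitivity)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "specificity": self.specificity,
            "flags": list(self.flags),
        }


def _edge_pairs(net: DirectedNetwork, undirected: bool) -> set:
    pairs = {(r, t) for (r, t) in net.edges if r != t}
    if undirected:
        return {frozenset(p) for p in pairs}
    return pairs


def confusion(
    pred: DirectedNetwork,
    truth: DirectedNetwork,
    universe=None,
    undirected: bool = False,
) -> EvalReport:
    """Confusion counts of a predicted network against the truth.

    Both networks must share one gene universe (checked); self-loops are
    excluded, leaving N(N−1) candidate ordered pairs (N(N−1)/2 with
    ``undirected``, which collapses edge orientation).  Undefined ratios on
    degenerate counts follow the zero conventions documented on
    :class:`EvalReport` and are flagged.
    """
    if universe is not None:
        universe = set(map(str, universe))
        for name, net in (("pred", pred), ("truth", truth)):
            extra = set(net.genes) - universe
            if extra:
                raise ValueError(
                    f"{name} network uses genes outside the declared "
                    f"universe: {sorted(extra)}"
                )
    else:
        if set(pred.genes) != set(truth.genes):
            raise ValueError(
                "mismatched gene universes between prediction and truth"
            )
        universe = set(pred.genes)
    n = len(universe)
    n_pairs = n * (n - 1) // (2 if undirected else 1)
    p_edges = _edge_pairs(pred, undirected)
    t_edges = _edge_pairs(truth, undirected)
    tp = len(p_edges & t_edges)
    fp = len(p_edges - t_edges)
    fn = len(t_edges - p_edges)
    tn = n_pairs - tp - fp - fn
    flags = []
    if tp + fp == 0:
        flags.append("no predicted edges: precision defined as 0")
    if tp + fn == 0:
        flags.append("no true edges: sensitivity defined as 0")
    for f in flags:
        logger.warning(f)
    return EvalReport(tp, tn, fp, fn, tuple(flags))


@dataclass(frozen=True)
class RocCurve:
    """θ-sweep ROC curve: anchored (FPR, TPR) points and trapezoidal AUC."""

    points: np.ndarray  # (k, 2), FPR nondecreasing
    auc: float
    thetas: np.ndarray


def roc(
    s: np.ndarray,
    truth: DirectedNetwork,
    gene_names=None,
    grid_size: int = 101,
) -> RocCurve:
    """ROC curve of a weight matrix against a truth network.

    Thresholds ``grid_size`` evenly spaced θ values in [0, 1]; at each, the
    prediction is ``s[i, j] >= θ`` for the directed pair j → i.  Points are
    anchored at (0, 0) and (1, 1) and integrated by the trapezoid rule over
    FPR-sorted points.  Raises when the truth has no positive or no negative
    pairs, where a ROC curve is undefined.
    """
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    if s.ndim != 2 or s.shape[1] != n:
        raise ValueError("weight matrix must be square")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("weight matrix entries must lie in [0, 1]")
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    genes = list(gene_names) if gene_names is not None else [
        f"G{k + 1}" for k in range(n)
    ]
    if set(truth.genes) != set(genes):
        raise ValueError("truth network universe does not match weight matrix")
    idx = {g: k for k, g in enumerate(genes)}
    adj = np.zeros((n, n), dtype=bool)  # adj[i, j]: true edge j -> i
    for (r, t) in truth.edges:
        if r != t:
            adj[idx[t], idx[r]] = True
    offdiag = ~np.eye(n, dtype=bool)
    pos = adj & offdiag
    neg = ~adj & offdiag
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC undefined: truth network must contain at least one present "
            "and one absent edge"
        )
    thetas = np.linspace(0.0, 1.0, int(grid_size))
    pts = [(0.0, 0.0), (1.0, 1.0)]
    for th in thetas:
        pred = (s >= th) & offdiag
        tpr = float((pred & pos).sum()) / n_pos
        fpr = float((pred & neg).sum()) / n_neg
        pts.append((fpr, tpr))
    pts_arr = np.array(sorted(set(pts)))
    auc = float(np.trapezoid(pts_arr[:, 1], pts_arr[:, 0]))
    return RocCurve(pts_arr, auc, thetas)
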