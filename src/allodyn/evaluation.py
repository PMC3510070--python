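"""Scoring residue predictors against an experimental labeling.

Confusion counts, TPR/FPR, ROC curves over the CAST threshold sweep (or
over a generic per-residue score), AUC by trapezoidal integration of the
curve closed at (0,0) and (1,1), best-threshold selection by distance to
the top-left corner, and the weighted side-chain + backbone rank
combination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import cast as cast_mod

__all__ = [
    "ResidueLabels",
    "ConfusionCounts",
    "ROCCurve",
    "CombinedRanking",
    "label_residues",
    "confusion",
    "tpr_fpr",
    "roc_from_sweep",
    "roc_from_scores",
    "best_threshold",
    "combine_ranks",
    "read_labels",
    "write_labels",
]


@dataclass
class ResidueLabels:
    positives: set
    negatives: set
    excluded: set
    universe: set

    def without_alanines(self) -> "ResidueLabels":
        """Drop alanines from the labeling (they are conformationally
        invariant, hence carry zero MI by construction)."""
        def keep(s):
            return {r for r in s if not str(r).startswith("A")}
        return ResidueLabels(keep(self.positives), keep(self.negatives),
                             keep(self.excluded), keep(self.universe))


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class ROCCurve:
    #: (threshold, FPR, TPR); includes the corners (0,0) and (1,1) with
    #: thresholds +inf / -inf
    points: list[tuple[float, float, float]]
    auc: float
    best: tuple[float, float, float] | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class CombinedRanking:
    order: list
    score: dict        # residue → r = α·rank_sc + β·rank_bb
    rank_sidechain: dict
    rank_backbone: dict
    alpha: float
    beta: float


def label_residues(positives, excluded, universe) -> ResidueLabels:
    """Split the universe into positives / negatives / excluded."""
    positives, excluded, universe = set(positives), set(excluded), set(universe)
    if positives & excluded:
        raise ValueError("positives and excluded sets overlap: "
                         f"{sorted(positives & excluded)}")
    if not positives <= universe or not excluded <= universe:
        raise ValueError("positives and excluded must be subsets of universe")
    return ResidueLabels(positives=positives,
                         negatives=universe - positives - excluded,
                         excluded=excluded,
                         universe=universe)


def confusion(predicted, labels: ResidueLabels) -> ConfusionCounts:
    """Confusion counts over labeled residues only; excluded never counted."""
    predicted = set(predicted)
    outside = predicted - labels.universe
    if outside:
        warnings.warn(f"{len(outside)} predicted residues outside the "
                      "labeled universe were ignored")
    tp = len(predicted & labels.positives)
    fp = len(predicted & labels.negatives)
    return ConfusionCounts(tp=tp,
                           tn=len(labels.negatives) - fp,
                           fp=fp,
                           fn=len(labels.positives) - tp)


def tpr_fpr(c: ConfusionCounts) -> tuple[float, float]:
    """TPR = TP/(TP+FN); FPR = FP/(FP+TN)."""
    if c.tp + c.fn == 0:
        raise ValueError("no positives: TPR undefined")
    if c.fp + c.tn == 0:
        raise ValueError("no negatives: FPR undefined")
    return c.tp / (c.tp + c.fn), c.fp / (c.fp + c.tn)


def _close_and_integrate(points: list[tuple[float, float, float]]
                         ) -> tuple[list, float]:
    """Sort sweep points, close the curve at (0,0)/(1,1), trapezoid AUC."""
    pts = sorted(set((round(f, 12), round(t, 12)) for _, f, t in points))
    xs = [0.0] + [p[0] for p in pts] + [1.0]
    ys = [0.0] + [p[1] for p in pts] + [1.0]
    auc = float(np.trapezoid(ys, xs))
    closed = ([(math.inf, 0.0, 0.0)]
              + sorted(points, key=lambda p: (p[1], p[2]))
              + [(-math.inf, 1.0, 1.0)])
    return closed, auc


def roc_from_sweep(dmi_abs: np.ndarray, residue_ids, labels: ResidueLabels,
                   t_grid) -> ROCCurve:
    """ROC over the CAST threshold sweep.

    At each threshold the informative group (restricted to the labeled
    universe) is scored against the labeling; each threshold contributes
    one operating point.
    """
    points = []
    for t in t_grid:
        group = cast_mod.cast_cluster(dmi_abs, t,
                                      residue_ids=residue_ids).informative_group
        c = confusion(group & labels.universe, labels)
        tpr, fpr = tpr_fpr(c)
        points.append((float(t), fpr, tpr))
    closed, auc = _close_and_integrate(points)
    curve = ROCCurve(points=closed, auc=auc,
                     meta={"t_grid": [float(t) for t in t_grid],
                           "kind": "cast_sweep"})
    curve.best = best_threshold(curve)
    return curve


def roc_from_scores(scores: dict, labels: ResidueLabels) -> ROCCurve:
    """ROC from a per-residue score (higher = more confidently positive).

    The threshold sweep runs over the distinct score values; residues
    missing from ``scores`` get the minimum score.
    """
    labeled = sorted(labels.positives | labels.negatives, key=str)
    if not labeled:
        raise ValueError("empty labeling")
    floor = min(scores.values()) if scores else 0.0
    s = {r: scores.get(r, floor) for r in labeled}
    points = []
    for t in sorted(set(s.values()), reverse=True):
        pred = {r for r in labeled if s[r] >= t}
        tpr, fpr = tpr_fpr(confusion(pred, labels))
        points.append((float(t), fpr, tpr))
    closed, auc = _close_and_integrate(points)
    curve = ROCCurve(points=closed, auc=auc, meta={"kind": "score_sweep"})
    curve.best = best_threshold(curve)
    return curve


def best_threshold(roc: ROCCurve) -> tuple[float, float, float]:
    """Sweep point closest (Euclidean) to the top-left corner (0,1).

    Ties go to the larger threshold. The synthetic closure corners are not
    eligible.
    """
    interior = [p for p in roc.points if math.isfinite(p[0])]
    if not interior:
        raise ValueError("ROC curve has no interior points")
    return min(interior,
               key=lambda p: (math.hypot(p[1], 1.0 - p[2]), -p[0]))


def combine_ranks(rank_sc: dict, rank_bb: dict, alpha: float = 1.5,
                  beta: float = 1.0, seed: int = 0) -> CombinedRanking:
    """Weighted rank combination r_i = α·rank_sc(i) + β·rank_bb(i).

    Ranks are 1-based positions; the final order is ascending in r with
    ties broken uniformly at random under the seed. The defaults give the
    side-chain ranking 50% more weight than the backbone one.
    """
    if set(rank_sc) != set(rank_bb):
        raise ValueError("side-chain and backbone rankings cover "
                         "different residues")
    rng = np.random.default_rng(seed)
    residues = sorted(rank_sc, key=str)
    score = {r: alpha * rank_sc[r] + beta * rank_bb[r] for r in residues}
    tiebreak = {r: rng.random() for r in residues}
    order = sorted(residues, key=lambda r: (score[r], tiebreak[r]))
    return CombinedRanking(order=order, score=score,
                           rank_sidechain=dict(rank_sc),
                           rank_backbone=dict(rank_bb),
                           alpha=alpha, beta=beta)


def read_labels(path) -> ResidueLabels:
    """Read a labeling TSV: residue_id <tab> label ∈ {P, N, X}."""
    pos, neg, exc = set(), set(), set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith(
                    "residue"):
                continue
            rid, lab = line.split("\t")[:2]
            {"P": pos, "N": neg, "X": exc}[lab.strip().upper()].add(rid)
    return ResidueLabels(positives=pos, negatives=neg, excluded=exc,
                         universe=pos | neg | exc)


def write_labels(labels: ResidueLabels, path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tlabel\n")
        for r in sorted(labels.universe, key=str):
            lab = ("P" if r in labels.positives
                   else "X" if r in labels.excluded else "N")
            fh.write(f"{r}\t{lab}\n")
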