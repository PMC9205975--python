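"""Gold-standard evaluation: ROC/PR threshold sweeps and confusion metrics.

Predictions are scored as a ranking of directed gene pairs; the gold
standard labels each pair 0/1 (DREAM3-style edge lists). AUROC comes from
the trapezoidal integral of the ROC sweep with tied scores grouped into
single threshold steps (equivalent to the rank statistic with half credit
for ties); AUPRC is the trapezoidal integral over the same sweep's
precision–recall points. Self-pairs are excluded from the evaluation
universe throughout. Gold pairs the predictor never scored are ranked last
(score −inf) and reported in a coverage warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from tegrn.screening_network import EdgeList, TEMatrix

__all__ = [
    "GoldStandard",
    "BenchmarkMetrics",
    "read_gold_standard",
    "roc_pr_curves",
    "confusion_at_threshold",
]


@dataclass(frozen=True)
class GoldStandard:
    """Directed reference edges plus (optionally) the gene universe.

    With a universe, every ordered non-self pair not listed as positive is a
    negative; without one, only explicitly labeled pairs are used.
    """

    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]
    universe: frozenset[str] | None = None

    def label_of(self, source: str, target: str) -> int | None:
        pair = (source, target)
        if pair in self.positives:
            return 1
        if pair in self.negatives:
            return 0
        if self.universe is not None and source in self.universe and target in self.universe:
            return 0
        return None

    def all_pairs(self) -> list[tuple[str, str, int]]:
        if self.universe is not None:
            genes = sorted(self.universe)
            return [
                (a, b, 1 if (a, b) in self.positives else 0)
                for a in genes
                for b in genes
                if a != b
            ]
        labeled = [(s, t, 1) for s, t in sorted(self.positives)]
        labeled += [(s, t, 0) for s, t in sorted(self.negatives)]
        return labeled


@dataclass(frozen=True)
class BenchmarkMetrics:
    auroc: float | None = None
    auprc: float | None = None
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None
    tn: int | None = None
    ppv: float | None = None
    sensitivity: float | None = None


def read_gold_standard(path: str | Path, universe=None) -> GoldStandard:
    """Parse a DREAM3-style TSV: regulator TAB target TAB {0,1}."""
    positives, negatives = set(), set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in ("0", "1"):
                raise ValueError(f"{path}: malformed gold-standard line {lineno}: {line!r}")
            src, tgt, label = parts
            if src == tgt:
                raise ValueError(f"{path}: self-loop on line {lineno}")
            (positives if label == "1" else negatives).add((src, tgt))
    return GoldStandard(
        positives=frozenset(positives),
        negatives=frozenset(negatives - positives),
        universe=frozenset(universe) if universe is not None else None,
    )


def _scores_and_labels(scores, gold: GoldStandard) -> tuple[np.ndarray, np.ndarray]:
    """Align predictor scores with gold labels over the evaluation universe."""
    if isinstance(scores, TEMatrix):
        scores = scores.to_edge_list()
    if isinstance(scores, EdgeList):
        score_map = {
            (r.source, r.target): r.te for r in scores.edges.itertuples(index=False)
        }
    else:
        score_map = dict(scores)
    pairs = gold.all_pairs()
    if not pairs:
        raise ValueError("gold standard labels no pairs")
    y, s, missing = [], [], 0
    for src, tgt, label in pairs:
        y.append(label)
        if (src, tgt) in score_map:
            s.append(score_map[(src, tgt)])
        else:
            s.append(-math.inf)
            missing += 1
    if missing:
        warnings.warn(
            f"{missing} gold pairs not scored by the predictor; ranked last",
            UserWarning,
            stacklevel=3,
        )
    y_arr = np.asarray(y)
    if y_arr.sum() == 0 or y_arr.sum() == y_arr.size:
        raise ValueError("gold standard needs both positive and negative pairs")
    return np.asarray(s, dtype=float), y_arr


def roc_pr_curves(scores, gold: GoldStandard):
    """AUROC/AUPRC from a threshold sweep, plus the curve points.

    Returns (BenchmarkMetrics, curve DataFrame). The curve table has one row
    per threshold step with TPR, FPR, precision and recall.
    """
    s, y = _scores_and_labels(scores, gold)
    finite_min = np.min(s[np.isfinite(s)]) if np.isfinite(s).any() else 0.0
    s_plot = np.where(np.isneginf(s), finite_min - 1.0, s)
    fpr, tpr, roc_thr = roc_curve(y, s_plot)
    auroc = float(auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(y, s_plot)
    # walk the sweep from high to low threshold (recall increasing); where a
    # threshold step leaves recall unchanged keep the higher-threshold point
    rec_sweep, prec_sweep = recall[::-1].copy(), precision[::-1].copy()
    keep = np.concatenate(([True], np.diff(rec_sweep) > 0))
    rec_sweep, prec_sweep = rec_sweep[keep], prec_sweep[keep]
    if len(prec_sweep) > 1 and rec_sweep[0] == 0.0:
        # extend the first achieved precision back to recall 0 instead of
        # the conventional (0, 1) anchor, which has no observed support
        prec_sweep[0] = prec_sweep[1]
    auprc = float(np.trapezoid(prec_sweep, rec_sweep))
    order = np.argsort(recall, kind="mergesort")
    n_steps = len(fpr)
    curve = pd.DataFrame(
        {
            "threshold": roc_thr,
            "tpr": tpr,
            "fpr": fpr,
            "precision": np.interp(tpr, recall[order], precision[order]),
            "recall": tpr,
        }
    )
    metrics = BenchmarkMetrics(auroc=auroc, auprc=auprc)
    return metrics, curve


def confusion_at_threshold(scores, gold: GoldStandard, threshold: float) -> BenchmarkMetrics:
    """TP/FP/FN/TN, PPV and sensitivity at a fixed score threshold.

    A pair is predicted positive when its score >= threshold. PPV = TP/(TP+FP)
    and Se = TP/(TP+FN); either is None (flagged undefined) when its
    denominator is zero.
    """
    s, y = _scores_and_labels(scores, gold)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    se = tp / (tp + fn) if (tp + fn) > 0 else None
    return BenchmarkMetrics(tp=tp, fp=fp, fn=fn, tn=tn, ppv=ppv, sensitivity=se)
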