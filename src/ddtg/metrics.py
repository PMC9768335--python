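"""Evaluation of predicted directed networks against a gold standard.

All counts are over the n(n-1) ordered non-self gene pairs and are
direction-sensitive: predicting v -> u for a true u -> v costs both a false
positive and a false negative. Five scalar summaries are reported —

    TPR = TP/(TP+FN)    FPR = FP/(FP+TN)    PPV = TP/(TP+FP)
    ACC = (TP+TN)/(TP+FP+TN+FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

— together with the ROC curve of a full edge ranking and its trapezoidal
AUC (equivalently the tie-corrected Mann-Whitney statistic).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .dream_io import GoldStandard

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "confusion", "scalar_metrics", "roc_auc", "evaluate"]


def confusion(
    pred: Iterable[tuple[str, str]], gold: GoldStandard
) -> tuple[int, int, int, int]:
    """Confusion counts (TP, FP, TN, FN) of a predicted edge set."""
    known = set(gold.gene_names)
    pred_set: set[tuple[str, str]] = set()
    for u, v in pred:
        if u not in known or v not in known:
            raise ValueError(f"predicted edge {u}->{v} names a gene outside the gold universe")
        if u == v:
            raise ValueError(f"self-edge {u}->{v} in predictions")
        pred_set.add((u, v))
    tp = len(pred_set & gold.positives)
    fp = len(pred_set) - tp
    fn = gold.n_positive - tp
    tn = gold.n_negative - fp
    return tp, fp, tn, fn


def scalar_metrics(
    tp: int, fp: int, tn: int, fn: int
) -> dict[str, float]:
    """The five scalar metrics; zero denominators yield 0 with a warning."""
    counts = dict(TP=tp, FP=fp, TN=tn, FN=fn)
    for name, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count {name}={c}")
    if tp + fp + tn + fn == 0:
        raise ValueError("all confusion counts are zero")

    degenerate: list[str] = []

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            degenerate.append(name)
            logger.warning("%s denominator is zero; reporting 0", name)
            return 0.0
        return num / den

    tpr = ratio("TPR", tp, tp + fn)
    fpr = ratio("FPR", fp, fp + tn)
    ppv = ratio("PPV", tp, tp + fp)
    acc = (tp + tn) / (tp + fp + tn + fn)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ratio("MCC", tp * tn - fp * fn, mcc_den)
    return {
        "TPR": tpr,
        "FPR": fpr,
        "PPV": ppv,
        "ACC": acc,
        "MCC": mcc,
        "degenerate": degenerate,
    }


def roc_auc(
    ranked: Sequence[tuple[str, str, float]], gold: GoldStandard
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC of a complete ordered-pair ranking.

    The ranking must cover every ordered non-self pair exactly once. Tied
    scores form a single ROC step (the trapezoid across the tie block), so
    the AUC equals the tie-corrected Mann-Whitney statistic.
    """
    pairs = [(u, v) for u, v, _ in ranked]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate ordered pair in ranking")
    universe = set(gold.universe())
    if set(pairs) != universe:
        missing = len(universe - set(pairs))
        raise ValueError(
            f"ranking does not cover the ordered-pair universe ({missing} pairs missing)"
        )
    if gold.n_positive == 0 or gold.n_negative == 0:
        raise ValueError("gold standard needs at least one positive and one negative")
    y_true = np.array([gold.label(u, v) for u, v, _ in ranked])
    y_score = np.array([s for _, _, s in ranked], dtype=float)
    fpr, tpr, _ = roc_curve(y_true, y_score, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack((fpr, tpr)), auc


@dataclass
class EvalReport:
    """Full evaluation of one prediction against one gold standard."""

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    ppv: float
    acc: float
    mcc: float
    roc: np.ndarray
    auc: float
    degenerate: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "TPR": self.tpr,
            "FPR": self.fpr,
            "PPV": self.ppv,
            "ACC": self.acc,
            "MCC": self.mcc,
            "AUC": self.auc,
            "roc": [[float(a), float(b)] for a, b in self.roc],
            "degenerate_metrics": list(self.degenerate),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def summary(self) -> str:
        return (
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}\n"
            f"TPR={self.tpr:.4f} FPR={self.fpr:.4f} PPV={self.ppv:.4f} "
            f"ACC={self.acc:.4f} MCC={self.mcc:.4f} AUC={self.auc:.4f}"
        )


def evaluate(
    pred_edges: Iterable[tuple[str, str]],
    ranked: Sequence[tuple[str, str, float]],
    gold: GoldStandard,
) -> EvalReport:
    """Confusion metrics of the emitted edges plus ROC/AUC of the ranking."""
    tp, fp, tn, fn = confusion(pred_edges, gold)
    scalars = scalar_metrics(tp, fp, tn, fn)
    roc, auc = roc_auc(ranked, gold)
    return EvalReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        tpr=scalars["TPR"],
        fpr=scalars["FPR"],
        ppv=scalars["PPV"],
        acc=scalars["ACC"],
        mcc=scalars["MCC"],
        roc=roc,
        auc=auc,
        degenerate=tuple(scalars["degenerate"]),
    )
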