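"""Evaluation statistics for binary and multi-class decoding.

All rate metrics derive from the 2x2 confusion table (TP/FP/TN/FN); the
agreement statistics (Cohen's kappa with its large-sample standard error)
work on a general CxC confusion matrix.  A metric whose denominator is zero
raises :class:`UndefinedMetricError` with a reason code — it is never
silently reported as 0.

Conventions: rates (accuracy, sensitivity, ...) are fractions in [0, 1];
balanced accuracy (BACC) is reported as a percentage, so BACC = 100 * AUC
identically; MCC and kappa live in [-1, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import UndefinedMetricError


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/TN/FN counts — the substrate of every binary metric.

    Positive = movement (stage 1) or left (stage 2); negative = rest / right.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"ConfusionTable.{name} must be a non-negative count, got {v}")
        if self.total < 1:
            raise ValueError("ConfusionTable must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.tp + other.tp, self.fp + other.fp,
                              self.tn + other.tn, self.fn + other.fn)

    def as_matrix(self) -> np.ndarray:
        """2x2 agreement matrix, rows = truth (pos, neg), cols = prediction."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


def confusion_from_labels(y_true, y_pred, positive) -> ConfusionTable:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    tp = int(np.sum((yt == positive) & (yp == positive)))
    fn = int(np.sum((yt == positive) & (yp != positive)))
    fp = int(np.sum((yt != positive) & (yp == positive)))
    tn = int(np.sum((yt != positive) & (yp != positive)))
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# basic rates
# ---------------------------------------------------------------------------


def accuracy(ct: ConfusionTable) -> float:
    return (ct.tp + ct.tn) / ct.total


def sensitivity(ct: ConfusionTable) -> float:
    """Detection rate / TPR: TP / (TP + FN)."""
    if ct.tp + ct.fn == 0:
        raise UndefinedMetricError("sensitivity", "no positive-class observations (TP+FN=0)")
    return ct.tp / (ct.tp + ct.fn)


def specificity(ct: ConfusionTable) -> float:
    """TNR: TN / (TN + FP)."""
    if ct.tn + ct.fp == 0:
        raise UndefinedMetricError("specificity", "no negative-class observations (TN+FP=0)")
    return ct.tn / (ct.tn + ct.fp)


def precision(ct: ConfusionTable) -> float:
    if ct.tp + ct.fp == 0:
        raise UndefinedMetricError("precision", "no positive predictions (TP+FP=0)")
    return ct.tp / (ct.tp + ct.fp)


def oer(ct: ConfusionTable) -> float:
    """Overall error rate = 1 - accuracy."""
    return (ct.fp + ct.fn) / ct.total


def fpr(ct: ConfusionTable) -> float:
    if ct.tn + ct.fp == 0:
        raise UndefinedMetricError("fpr", "no negative-class observations (TN+FP=0)")
    return ct.fp / (ct.fp + ct.tn)


def fnr(ct: ConfusionTable) -> float:
    if ct.tp + ct.fn == 0:
        raise UndefinedMetricError("fnr", "no positive-class observations (TP+FN=0)")
    return ct.fn / (ct.fn + ct.tp)


def basic_rates(ct: ConfusionTable) -> dict:
    """Accuracy, sensitivity, specificity, OER, FPR, FNR, precision."""
    return {
        "accuracy": accuracy(ct),
        "sensitivity": sensitivity(ct),
        "specificity": specificity(ct),
        "oer": oer(ct),
        "fpr": fpr(ct),
        "fnr": fnr(ct),
        "precision": precision(ct),
    }


# ---------------------------------------------------------------------------
# composite measures
# ---------------------------------------------------------------------------


def f_measure(ct: ConfusionTable) -> float:
    p, s = precision(ct), sensitivity(ct)
    if p + s == 0:
        raise UndefinedMetricError("f_measure", "precision + sensitivity = 0")
    return 2.0 * p * s / (p + s)


def gmean1(ct: ConfusionTable) -> float:
    """sqrt(sensitivity * precision)."""
    return math.sqrt(sensitivity(ct) * precision(ct))


def gmean2(ct: ConfusionTable) -> float:
    """sqrt(sensitivity * specificity)."""
    return math.sqrt(sensitivity(ct) * specificity(ct))


def f_and_gmeans(ct: ConfusionTable) -> dict:
    return {"f_measure": f_measure(ct), "gmean1": gmean1(ct), "gmean2": gmean2(ct)}


def mcc(ct: ConfusionTable) -> float:
    """Matthews correlation coefficient between truth and prediction."""
    margins = [ct.tp + ct.fp, ct.tp + ct.fn, ct.tn + ct.fp, ct.tn + ct.fn]
    if any(m == 0 for m in margins):
        raise UndefinedMetricError("mcc", "a confusion-table marginal is zero")
    num = ct.tp * ct.tn - ct.fp * ct.fn
    den = math.sqrt(math.prod(float(m) for m in margins))
    return num / den


def auc_formula(ct: ConfusionTable) -> float:
    """Closed-form AUC of the single-threshold classifier: (TPR + TNR) / 2."""
    return 0.5 * (sensitivity(ct) + specificity(ct))


def bacc(ct: ConfusionTable) -> float:
    """Balanced accuracy in percent; identically 100 * auc_formula."""
    return 100.0 * auc_formula(ct)


# ---------------------------------------------------------------------------
# Cohen's kappa with standard error
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    above_chance: bool
    n: int


def kappa_with_se(confusion_matrix) -> KappaResult:
    """Cohen's kappa, its large-sample SE, 95% CI and the above-chance flag.

    ``confusion_matrix`` is a CxC count matrix (rows = truth, cols =
    prediction).  kappa = (p0 - pe) / (1 - pe) with p0 the observed and pe
    the chance agreement; the SE is the large-sample form
    sqrt(pe + pe^2 - sum_i p_i+ p_+i (p_i+ + p_+i)) / ((1 - pe) sqrt(N))
    with proportion marginals p_i+ (row) and p_+i (column).
    """
    M = np.asarray(confusion_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("kappa_with_se needs a square confusion matrix")
    if np.any(M < 0):
        raise ValueError("confusion matrix counts must be >= 0")
    n = M.sum()
    if n < 1:
        raise UndefinedMetricError("kappa", "empty confusion matrix")
    P = M / n
    p0 = np.trace(P)
    row, col = P.sum(axis=1), P.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        raise UndefinedMetricError("kappa", "chance agreement pe = 1")
    kappa = (p0 - pe) / (1.0 - pe)
    inner = pe + pe**2 - float(np.sum(row * col * (row + col)))
    se = math.sqrt(max(inner, 0.0)) / ((1.0 - pe) * math.sqrt(n))
    lo, hi = kappa - 1.96 * se, kappa + 1.96 * se
    return KappaResult(kappa=float(kappa), se=float(se), ci95=(float(lo), float(hi)),
                       above_chance=bool(lo > 0.0), n=int(n))


# ---------------------------------------------------------------------------
# desirability
# ---------------------------------------------------------------------------

_D1_KEYS = ("precision", "sensitivity", "specificity")
_D2_KEYS = ("gmean1", "gmean2", "f_measure")


@dataclass(frozen=True)
class DesirabilityInput:
    """Per-subject vectors of the six performance measures."""

    precision: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    gmean1: np.ndarray
    gmean2: np.ndarray
    f_measure: np.ndarray

    def vector(self, key: str) -> np.ndarray:
        v = np.asarray(getattr(self, key), dtype=float)
        if len(v) < 2:
            raise UndefinedMetricError("desirability", f"{key}: need >= 2 values for a std")
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"desirability input {key} must lie in [0, 1]")
        return v


def desirability(inp: DesirabilityInput) -> tuple[float, float, float]:
    """(D1, D2, D): products of mean/std ratios and their sixth-root composite."""

    def ratio(key: str) -> float:
        v = inp.vector(key)
        sd = v.std(ddof=0)
        if sd == 0:
            raise UndefinedMetricError("desirability", f"{key} has zero spread")
        return float(v.mean() / sd)

    d1 = math.prod(ratio(k) for k in _D1_KEYS)
    d2 = math.prod(ratio(k) for k in _D2_KEYS)
    return d1, d2, (d1 * d2) ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_REPORT_FUNS = {
    "accuracy": accuracy,
    "sensitivity": sensitivity,
    "specificity": specificity,
    "oer": oer,
    "fpr": fpr,
    "fnr": fnr,
    "precision": precision,
    "f_measure": f_measure,
    "gmean1": gmean1,
    "gmean2": gmean2,
    "mcc": mcc,
    "auc": auc_formula,
    "bacc": bacc,
}


@dataclass
class MetricsReport:
    """All scalar metrics for one binary evaluation.

    Undefined metrics are stored as None with the reason in ``undefined``.
    """

    values: dict = field(default_factory=dict)
    undefined: dict = field(default_factory=dict)
    kappa: float | None = None
    kappa_se: float | None = None
    kappa_ci95: tuple[float, float] | None = None
    kappa_above_chance: bool | None = None
    n: int = 0

    @classmethod
    def from_confusion(cls, ct: ConfusionTable) -> "MetricsReport":
        rep = cls(n=ct.total)
        for name, fun in _REPORT_FUNS.items():
            try:
                rep.values[name] = float(fun(ct))
            except UndefinedMetricError as e:
                rep.values[name] = None
                rep.undefined[name] = e.reason
        try:
            kr = kappa_with_se(ct.as_matrix())
            rep.kappa, rep.kappa_se = kr.kappa, kr.se
            rep.kappa_ci95, rep.kappa_above_chance = kr.ci95, kr.above_chance
        except UndefinedMetricError as e:
            rep.undefined["kappa"] = e.reason
        return rep

    def __getitem__(self, key: str):
        return self.values[key]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            **self.values,
            "kappa": self.kappa,
            "kappa_se": self.kappa_se,
            "kappa_ci95": list(self.kappa_ci95) if self.kappa_ci95 else None,
            "kappa_above_chance": self.kappa_above_chance,
            "undefined": self.undefined,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def format_report_table(reports: dict, columns=("f_measure", "mcc", "auc", "kappa", "bacc", "fpr")) -> str:
    """Human-readable comparison table, one row per classifier."""
    widths = [max(10, len(c) + 2) for c in columns]
    head = f"{'classifier':<12}" + "".join(f"{c:>{w}}" for c, w in zip(columns, widths))
    lines = [head, "-" * len(head)]
    for name, rep in reports.items():
        cells = []
        for c, w in zip(columns, widths):
            v = rep.kappa if c == "kappa" else rep.values.get(c)
            cells.append(f"{'n/a':>{w}}" if v is None else f"{v:>{w}.4f}")
        lines.append(f"{name:<12}" + "".join(cells))
    return "\n".join(lines)
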