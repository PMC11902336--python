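"""Evaluation metrics for event detection and AHI regression.

Classification: accuracy, macro F1 (unweighted mean of per-class F1 over
classes present in either vector), Cohen's kappa with marginal-product
chance agreement, and recall / precision / specificity (positive class for
binary tasks, macro-averaged for multiclass).

Regression: MAE, RMSE, the coefficient of determination in both the
regression-sum-of-squares form (``r2_paper`` = SSreg/SStot, which can
exceed 1 when predictions overshoot) and the conventional
``1 - SSres/SStot``, and the intraclass correlation ICC(2,1) of the
two-way random-effects absolute-agreement model with two raters
(label sequence and prediction sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "classification_metrics",
    "regression_metrics",
    "icc21",
    "bland_altman_summary",
    "EvalReport",
]


class MetricError(ValueError):
    pass


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def classification_metrics(y_true, y_pred) -> dict:
    """ACC / MF1 / kappa / recall / precision / specificity + confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise MetricError("label vectors must be non-empty and equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    cm = _confusion(y_true, y_pred, classes)
    n = cm.sum()
    acc = np.trace(cm) / n

    # per-class precision/recall/F1 (0 where undefined)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    mf1 = float(f1.mean())

    po = acc
    pe = float((cm.sum(axis=0) / n * cm.sum(axis=1) / n).sum())
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0

    binary = set(classes.tolist()) <= {0, 1}
    if binary and len(classes) == 2:
        i1 = int(np.where(classes == 1)[0][0])
        i0 = 1 - i1
        recall = rec[i1]
        precision = prec[i1]
        denom = cm[i0].sum()
        specificity = cm[i0, i0] / denom if denom > 0 else 0.0
    else:
        recall = float(rec.mean())
        precision = float(prec.mean())
        spec = []
        for i in range(len(classes)):
            tn = n - cm[i].sum() - cm[:, i].sum() + cm[i, i]
            neg = n - cm[i].sum()
            spec.append(tn / neg if neg > 0 else 0.0)
        specificity = float(np.mean(spec))

    return {
        "acc": float(acc), "mf1": mf1, "kappa": float(kappa),
        "recall": float(recall), "precision": float(precision),
        "specificity": float(specificity),
        "confusion": cm, "classes": classes, "n": int(n),
    }


def icc21(y_true, y_pred) -> float:
    """ICC(2,1): two-way random effects, single rater, absolute agreement."""
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    n = len(a)
    if n < 2 or len(b) != n:
        raise MetricError("need two equal-length sequences with n >= 2")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def regression_metrics(y_true, y_pred) -> dict:
    """MAE, RMSE, both R^2 variants and ICC(2,1)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 2 or len(y_true) != len(y_pred):
        raise MetricError("need two equal-length sequences with n >= 2")
    err = y_true - y_pred
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise MetricError("zero variance in y_true: R^2 and ICC undefined")
    r2_paper = float(np.sum((y_pred - y_true.mean()) ** 2) / sst)
    r2 = float(1.0 - np.sum(err**2) / sst)
    return {
        "mae": mae, "rmse": rmse, "r2_paper": r2_paper, "r2": r2,
        "icc": icc21(y_true, y_pred), "n": int(len(y_true)),
    }


def bland_altman_summary(y_true, y_pred) -> tuple[float, float, float]:
    """(mean difference, lower, upper) limits at +-1.96 sample SD."""
    d = np.asarray(y_pred, dtype=float) - np.asarray(y_true, dtype=float)
    if len(d) < 2:
        raise MetricError("need n >= 2")
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return m, m - 1.96 * sd, m + 1.96 * sd


@dataclass
class EvalReport:
    """Per-task metric tables for one pipeline run."""

    sas_detection: dict = field(default_factory=dict)
    ahi_regression: dict = field(default_factory=dict)
    severity: dict = field(default_factory=dict)
    binary: dict = field(default_factory=dict)   # cut-off -> metrics
    n_subjects: int = 0
    n_samples: int = 0

    def to_text(self) -> str:
        def fmt(d, keys):
            return "  ".join(f"{k}={d[k]:.4f}" for k in keys if k in d)

        lines = [
            f"subjects={self.n_subjects}  samples={self.n_samples}",
            "SAS detection   " + fmt(self.sas_detection,
                                     ["acc", "mf1", "kappa", "recall", "precision"]),
            "AHI regression  " + fmt(self.ahi_regression,
                                     ["icc", "r2", "mae", "rmse"]),
            "SAS severity    " + fmt(self.severity,
                                     ["acc", "mf1", "kappa", "recall", "specificity"]),
        ]
        for cut, d in sorted(self.binary.items()):
            lines.append(f"binary @ {cut:<4} " + fmt(d, ["acc", "mf1", "kappa",
                                                         "recall", "specificity"]))
        return "\n".join(lines)

    def flat(self) -> dict:
        out = {}
        for prefix, d in [("sas", self.sas_detection), ("ahi", self.ahi_regression),
                          ("sev", self.severity)]:
            for k, v in d.items():
                if isinstance(v, (int, float)):
                    out[f"{prefix}_{k}"] = float(v)
        for cut, d in self.binary.items():
            for k, v in d.items():
                if isinstance(v, (int, float)):
                    out[f"bin{cut}_{k}"] = float(v)
        return out
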