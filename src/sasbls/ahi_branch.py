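"""AHI-prediction branch and severity grading.

Two BLS regression units operate on the overnight global features.  The
first produces the global AHI estimate fed to the SDFFU; the second fuses
the AHI counted from the final event detections (predicted event runs per
hour of sleep) as an incremental feature.  Both are trained on
log-transformed labels and inverse-transformed, floored at zero.

Severity follows the clinical AHI bins: none < 5 <= mild < 15 <= moderate
< 30 <= severe (left-closed, boundary to the higher class), with the three
companion binary tasks at cut-offs 5, 15 and 30.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bls
from .sdffu import LOG_AHI_CAP, ahi_inverse, ahi_transform

__all__ = [
    "SEVERITY_CLASSES",
    "SubjectPrediction",
    "predict_ahig",
    "predict_final_ahi",
    "severity_from_ahi",
    "ahi_from_detections",
]

SEVERITY_CLASSES = ("none", "mild", "moderate", "severe")
SEVERITY_THRESHOLDS = (5.0, 15.0, 30.0)


@dataclass
class SubjectPrediction:
    subject_id: str
    ahi_hat: float
    ahi_g: float
    sas_final_labels: np.ndarray
    severity_class: str


def predict_ahig(global_features: np.ndarray, regressor: bls.BLSModel) -> np.ndarray:
    """Global-feature AHI estimate (first regression unit)."""
    raw = bls.predict(regressor, np.atleast_2d(global_features))[:, 0]
    return np.maximum(ahi_inverse(np.minimum(raw, LOG_AHI_CAP)), 0.0)


def ahi_from_detections(final_labels: np.ndarray, tst_min: float) -> float:
    """Counted AHI: number of predicted event runs per hour of sleep."""
    y = np.asarray(final_labels).astype(bool)
    n_runs = int(np.sum(y[1:] & ~y[:-1]) + (1 if len(y) and y[0] else 0))
    hours = tst_min / 60.0
    return n_runs / hours if hours > 0 else 0.0


def fit_final_ahi(
    G_train: np.ndarray,
    ahi_det_train: np.ndarray,
    ahi_labels_train: np.ndarray,
    config: bls.BLSConfig,
) -> bls.BLSModel:
    """Fit the second regression unit on [global | detection AHI]."""
    base = bls.fit(G_train, ahi_transform(np.asarray(ahi_labels_train)), config)
    return bls.fit_incremental(
        base, G_train, np.asarray(ahi_det_train, dtype=float).reshape(-1, 1),
        ahi_transform(np.asarray(ahi_labels_train)),
    )


def predict_final_ahi(
    global_features: np.ndarray,
    ahi_from_final_detections: np.ndarray,
    regressor2: bls.BLSModel,
) -> np.ndarray:
    """Fused AHI output: inverse-transformed, floored at 0."""
    G = np.atleast_2d(global_features)
    inc = np.asarray(ahi_from_final_detections, dtype=float).reshape(-1, 1)
    if len(G) != len(inc):
        raise bls.BLSError("global features and incremental AHI are misaligned")
    raw = bls.predict(regressor2, G, inc)[:, 0]
    return np.maximum(ahi_inverse(np.minimum(raw, LOG_AHI_CAP)), 0.0)


def severity_from_ahi(ahi: float) -> tuple[str, tuple[int, int, int]]:
    """Severity class plus the three binary tasks at cut-offs 5/15/30."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    t5, t15, t30 = SEVERITY_THRESHOLDS
    if ahi < t5:
        cls = "none"
    elif ahi < t15:
        cls = "mild"
    elif ahi < t30:
        cls = "moderate"
    else:
        cls = "severe"
    return cls, (int(ahi >= t5), int(ahi >= t15), int(ahi >= t30))


def severity_codes(ahi: np.ndarray) -> np.ndarray:
    """Vectorized 0..3 class codes for an AHI array."""
    a = np.asarray(ahi, dtype=float)
    if np.any(a < 0):
        raise ValueError("AHI must be non-negative")
    return np.digitize(a, SEVERITY_THRESHOLDS)
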