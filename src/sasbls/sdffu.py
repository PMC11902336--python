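"""Global-segment feature fusing unit (SDFFU).

The unit reconciles two independent AHI estimates for a subject: one
regressed from the overnight global features (``ahig``) and one regressed
from statistics of the segment-level detection probabilities (``ahis``).
When the two disagree by more than 10 events/h the detection probability
sequence is nudged toward the global estimate: the samples just below the
top decile of the probability ordering are scaled up (global AHI higher)
or down (lower) by a position-dependent coefficient

    v = 0.5 * Evend * (60 / T) * (i / N)

with ``Evend = round(|ahig - ahis| * 60)`` (the printed event-count form;
``evend_mode='hours'`` selects the dimensionally coherent
``|ahig - ahis| * T / 60``), ``T`` the sleep duration in minutes, ``i`` the
sample's temporal position and ``N`` the subject's original sample count.
Corrected probabilities are clipped to [0, 1].

AHI targets are fit on the log scale ``Y' = ln(Y + 1)`` and predictions are
inverse-transformed with ``Y = exp(Y') - 1`` and floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import bls

__all__ = [
    "EventStatFeatures",
    "CorrectionRecord",
    "ahi_transform",
    "ahi_inverse",
    "event_stat_features",
    "EVENT_STAT_FEATURES",
    "predict_ahis",
    "correct_probabilities",
]


class SDFFUError(ValueError):
    pass


def ahi_transform(y: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing label transform Y' = ln(Y + 1)."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise SDFFUError("AHI values must be non-negative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(y) else out


def ahi_inverse(yp: np.ndarray | float) -> np.ndarray | float:
    """Inverse transform Y = exp(Y') - 1 (exact round-trip)."""
    arr = np.asarray(yp, dtype=float)
    out = np.expm1(arr)
    return float(out) if np.isscalar(yp) else out


EVENT_STAT_FEATURES = [
    "event_time_fraction", "event_len_mean", "event_len_sd",
    "frac_p_gt_05", "frac_p_lt_03", "mean_p_on_events", "mean_p_on_runs",
]


@dataclass
class EventStatFeatures:
    event_time_fraction: float
    event_len_mean: float
    event_len_sd: float
    frac_p_gt_05: float
    frac_p_lt_03: float
    mean_p_on_events: float
    mean_p_on_runs: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in EVENT_STAT_FEATURES])


def _runs_of_ones(y: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i, n = 0, len(y)
    while i < n:
        if y[i]:
            j = i
            while j < n and y[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def event_stat_features(
    p0: np.ndarray, y0: np.ndarray, window_s: float, sleep_s: float
) -> EventStatFeatures:
    """Subject-level statistics of the predicted event sequence.

    Runs of consecutive positive windows form predicted events; lengths are
    in seconds.  Subjects with no predicted events get zeros (by convention
    ``mean_p_on_events = 0``).
    """
    p0 = np.asarray(p0, dtype=float)
    y0 = np.asarray(y0).astype(bool)
    runs = _runs_of_ones(y0)
    lengths = np.array([(j - i) * window_s for i, j in runs])
    n_pos = int(y0.sum())
    if len(lengths):
        len_mean = float(lengths.mean())
        len_sd = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    else:
        len_mean = len_sd = 0.0
    long_runs = [r for r in runs if r[1] - r[0] >= 2]
    if long_runs:
        idx = np.concatenate([np.arange(i, j) for i, j in long_runs])
        mean_runs = float(p0[idx].mean())
    else:
        mean_runs = 0.0
    return EventStatFeatures(
        event_time_fraction=n_pos * window_s / sleep_s if sleep_s > 0 else 0.0,
        event_len_mean=len_mean,
        event_len_sd=len_sd,
        frac_p_gt_05=float(np.mean(p0 > 0.5)) if len(p0) else 0.0,
        frac_p_lt_03=float(np.mean(p0 < 0.3)) if len(p0) else 0.0,
        mean_p_on_events=float(p0[y0].mean()) if n_pos else 0.0,
        mean_p_on_runs=mean_runs,
    )


# regressed log-AHI is capped at ln(1+300) before the inverse transform:
# extrapolation far past any physiologic AHI would otherwise overflow
LOG_AHI_CAP = float(np.log1p(300.0))


def predict_ahis(features: np.ndarray, regressor: bls.BLSModel) -> np.ndarray:
    """Detection-statistics AHI estimate, inverse-transformed, floored at 0."""
    raw = bls.predict(regressor, np.atleast_2d(features))[:, 0]
    return np.maximum(ahi_inverse(np.minimum(raw, LOG_AHI_CAP)), 0.0)


@dataclass
class CorrectionRecord:
    subject_id: str
    ahig: float
    ahis: float
    triggered: bool
    evend: int = 0
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    v: np.ndarray = field(default_factory=lambda: np.empty(0))
    truncated: bool = False


def correct_probabilities(
    p0: np.ndarray,
    ahig: float,
    ahis: float,
    t_min: float,
    n_total: int,
    positions: np.ndarray | None = None,
    subject_id: str = "",
    trigger: float = 10.0,
    top_fraction: float = 0.1,
    evend_mode: str = "verbatim",
) -> tuple[np.ndarray, CorrectionRecord]:
    """Correct a subject's probability sequence toward the global AHI.

    Identity when ``|ahig - ahis| <= trigger``.  Otherwise the most
    confident ``ceil(top_fraction * n)`` samples are skipped and the next
    ``Evend`` samples in descending probability order are scaled by
    ``(1 + v)`` if the global estimate is higher, ``(1 - v)`` if lower,
    clipping into [0, 1].  ``positions`` are the 1-based temporal indices
    used as ``i``; ``n_total`` is the original segment count ``N``.
    """
    if t_min <= 0:
        raise SDFFUError("t_min must be positive")
    if n_total < 1:
        raise SDFFUError("n_total must be >= 1")
    p0 = np.asarray(p0, dtype=float)
    n = len(p0)
    if positions is None:
        positions = np.arange(1, n + 1)
    delta = ahig - ahis
    rec = CorrectionRecord(subject_id=subject_id, ahig=float(ahig),
                           ahis=float(ahis), triggered=abs(delta) > trigger)
    if not rec.triggered or n == 0:
        return p0.copy(), rec

    if evend_mode == "verbatim":
        evend = int(math.floor(abs(delta) * 60.0 + 0.5))
    elif evend_mode == "hours":
        evend = int(math.floor(abs(delta) * t_min / 60.0 + 0.5))
    else:
        raise SDFFUError(f"unknown evend_mode {evend_mode!r}")
    rec.evend = evend

    order = np.argsort(-p0, kind="stable")
    skip = math.ceil(top_fraction * n)
    selected = order[skip : skip + evend]
    if evend > n - skip:
        rec.truncated = True
    i_pos = np.asarray(positions, dtype=float)[selected]
    v = 0.5 * evend * (60.0 / t_min) * (i_pos / n_total)
    out = p0.copy()
    factor = (1.0 + v) if delta > 0 else (1.0 - v)
    out[selected] = np.clip(out[selected] * factor, 0.0, 1.0)
    rec.indices = selected
    rec.v = v
    return out, rec
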