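"""SpO2 feature extraction: per-window vectors and the overnight registry.

Two feature families are produced:

* **Sample features** — 14 time-domain / nonlinear descriptors of a single
  fixed-length window (minimum, spread, saturation-threshold fractions,
  sample and permutation entropy, first-derivative statistics and the
  fraction of the window spent in an in-sample desaturation, i.e. at least
  10 consecutive seconds more than 3 % below the overnight mean).

* **Global features** — the overnight registry: time-domain summaries,
  Welch power in the 0.03-0.17 Hz ventilatory band, nonlinear complexity
  (ApEn, SampEn, permutation entropy, LZ76, DFA, CTM), phase-rectified
  signal averaging morphology, desaturation-event statistics relative to a
  running 120 s baseline, hypoxic-burden indices, and demographics.

Entropy and complexity primitives are implemented here directly; they are
small, deterministic, and unit-tested against brute-force references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import SampleSet
from .synth import Recording

__all__ = [
    "SAMPLE_FEATURES",
    "GLOBAL_FEATURES",
    "sample_features",
    "sample_feature_matrix",
    "global_features",
    "detect_desaturations",
    "sample_entropy",
    "approx_entropy",
    "perm_entropy",
    "lz76_complexity",
    "dfa_alpha",
    "ctm",
]


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# nonlinear primitives
# ---------------------------------------------------------------------------

def _phi_counts(x: np.ndarray, m: int, r: float, self_match: bool) -> np.ndarray:
    """Per-template counts of Chebyshev-matching templates of length m."""
    n = len(x)
    nt = n - m + 1
    tpl = np.lib.stride_tricks.sliding_window_view(x, m)
    d = np.abs(tpl[:, None, :] - tpl[None, :, :]).max(axis=2)
    match = d <= r
    if not self_match:
        np.fill_diagonal(match, False)
    return match.sum(axis=1)


def _m1_match(x: np.ndarray, r: float) -> np.ndarray:
    """Pairwise match matrix |x_i - x_j| <= r (shared by the m=1 fast paths)."""
    return np.abs(x[:, None] - x[None, :]) <= r


def _sampen_m1(match: np.ndarray, n: int) -> float:
    b = int(match[:-1, :-1].sum()) - (n - 1)
    a = int((match[:-1, :-1] & match[1:, 1:]).sum()) - (n - 1)
    if b == 0:
        return 0.0
    if a == 0:
        return -math.log(2.0 / ((n - 2) * (n - 1)))
    return -math.log(a / b)


def _apen_m1(match: np.ndarray, n: int) -> float:
    c1 = match.sum(axis=1) / n
    m2 = match[:-1, :-1] & match[1:, 1:]
    c2 = m2.sum(axis=1) / (n - 1)
    return float(np.mean(np.log(c1)) - np.mean(np.log(c2)))


def sample_entropy(x: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """Sample entropy with Chebyshev distance, tolerance ``r`` (default 0.25*SD).

    Returns 0 for a constant series; when no (m+1)-length matches exist the
    maximum resolvable value ``-log(2 / ((n-m-1)(n-m)))`` is returned.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return 0.0
    sd = x.std()
    if r is None:
        r = 0.25 * sd
    if sd == 0:
        return 0.0
    if m == 1:
        return _sampen_m1(_m1_match(x, r), n)
    # exclude the last template of length m so both counts use n-m templates
    b = _phi_counts(x[:-1], m, r, self_match=False).sum()
    a = _phi_counts(x, m + 1, r, self_match=False).sum()
    if b == 0:
        return 0.0
    if a == 0:
        return -math.log(2.0 / ((n - m - 1) * (n - m)))
    return -math.log(a / b)


def approx_entropy(x: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """Approximate entropy (Pincus), self-matches included."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return 0.0
    sd = x.std()
    if r is None:
        r = 0.25 * sd
    if sd == 0:
        return 0.0
    if m == 1:
        return _apen_m1(_m1_match(x, r), n)

    def phi(mm: int) -> float:
        c = _phi_counts(x, mm, r, self_match=True) / (n - mm + 1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def perm_entropy(x: np.ndarray, order: int = 3, delay: int = 1,
                 normalize: bool = True) -> float:
    """Permutation entropy of ordinal patterns (stable argsort tie-break)."""
    x = np.asarray(x, dtype=float)
    n = len(x) - (order - 1) * delay
    if n <= 0:
        return 0.0
    emb = np.empty((n, order))
    for k in range(order):
        emb[:, k] = x[k * delay : k * delay + n]
    patterns = np.argsort(emb, axis=1, kind="stable")
    base = order ** np.arange(order)
    codes = patterns @ base
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if normalize:
        h /= math.log(math.factorial(order))
    return h


def lz76_complexity(bits: np.ndarray) -> int:
    """Lempel-Ziv 1976 complexity (number of phrases) of a binary sequence."""
    s = "".join("1" if b else "0" for b in np.asarray(bits).astype(bool))
    n = len(s)
    c = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n and s[i : i + length] in s[: i + length - 1]:
            length += 1
        c += 1
        i += length
    return c


def lz_signal_complexity(x: np.ndarray) -> int:
    """LZ76 complexity of the signal binarized around its median."""
    x = np.asarray(x, dtype=float)
    return lz76_complexity(x > np.median(x))


def dfa_alpha(x: np.ndarray, scales: np.ndarray | None = None) -> float:
    """Detrended fluctuation exponent over scales of 10-300 samples."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if scales is None:
        hi = min(300, n // 4)
        if hi < 12:
            return 0.0
        scales = np.unique(np.geomspace(10, hi, 12).astype(int))
    y = np.cumsum(x - x.mean())
    fl = []
    used = []
    for s in scales:
        nseg = n // s
        if nseg < 2:
            continue
        seg = y[: nseg * s].reshape(nseg, s)
        t = np.arange(s)
        # linear detrend per segment
        tm = t - t.mean()
        beta = seg @ tm / (tm @ tm)
        resid = seg - seg.mean(axis=1, keepdims=True) - beta[:, None] * tm
        fl.append(math.sqrt(float(np.mean(resid**2))))
        used.append(s)
    if len(used) < 2 or min(fl) == 0:
        return 0.0
    alpha = np.polyfit(np.log(used), np.log(fl), 1)[0]
    return float(alpha)


def ctm(x: np.ndarray, rho: float = 1.0) -> float:
    """Central tendency measure on second-order differences.

    Fraction of successive second-difference pairs inside a circle of
    radius ``rho``.
    """
    z = np.diff(np.asarray(x, dtype=float), n=2)
    if len(z) < 2:
        return 1.0
    rad = np.hypot(z[:-1], z[1:])
    return float(np.mean(rad < rho))


# ---------------------------------------------------------------------------
# sample features
# ---------------------------------------------------------------------------

SAMPLE_FEATURES = [
    "min", "mean", "std", "range", "min_minus_overnight_mean",
    "p_lt95", "p_lt90", "p_lt80", "sampen", "permen",
    "d1_max", "d1_mean", "d1_gt3_frac", "desat_frac",
]


def _in_sample_desat_frac(seg: np.ndarray, overnight_mean: float,
                          drop: float = 3.0, min_dur: int = 10) -> float:
    below = seg < (overnight_mean - drop)
    frac = 0.0
    i, n = 0, len(below)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_dur:
                frac += (j - i) / n
            i = j
        else:
            i += 1
    return frac


def sample_features(segment: np.ndarray, overnight_mean: float) -> np.ndarray:
    """14-element feature vector of one 1 Hz window (order: SAMPLE_FEATURES)."""
    seg = np.asarray(segment, dtype=float)
    if not np.all(np.isfinite(seg)):
        raise FeatureError("segment contains non-finite values")
    n = len(seg)
    if n < 10:
        raise FeatureError("segment shorter than 10 s")
    d1 = np.abs(np.diff(seg))
    return np.array([
        seg.min(),
        seg.mean(),
        seg.std(),
        seg.max() - seg.min(),
        seg.min() - overnight_mean,
        float(np.mean(seg < 95.0)),
        float(np.mean(seg < 90.0)),
        float(np.mean(seg < 80.0)),
        sample_entropy(seg, m=1),
        perm_entropy(seg, order=3, delay=1, normalize=True),
        d1.max() if len(d1) else 0.0,
        d1.mean() if len(d1) else 0.0,
        float(np.sum(d1 > 3.0)) / n,
        _in_sample_desat_frac(seg, overnight_mean),
    ])


def sample_feature_matrix(samples: SampleSet) -> pd.DataFrame:
    """Feature rows for every window of a subject, columns = SAMPLE_FEATURES."""
    rows = [sample_features(seg, samples.overnight_mean) for seg in samples.segments]
    return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(SAMPLE_FEATURES))),
                        columns=SAMPLE_FEATURES)


# ---------------------------------------------------------------------------
# desaturation detection
# ---------------------------------------------------------------------------

@dataclass
class Desaturation:
    start_s: int
    length_s: int
    depth: float       # baseline - nadir, percent
    slope: float       # depth / fall time to nadir, %/s
    area: float        # sum of (baseline - value) over the event, %*s


def detect_desaturations(
    signal: np.ndarray,
    drop_pct: float = 3.0,
    min_dur_s: int = 10,
    baseline_win_s: int = 120,
) -> list[Desaturation]:
    """Baseline-relative desaturation events on a 1 Hz signal.

    The baseline at each second is the running maximum of the preceding
    ``baseline_win_s`` seconds (inclusive); an event is a maximal run of at
    least ``min_dur_s`` seconds with ``baseline - value >= drop_pct``.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) == 0:
        return []
    baseline = (
        pd.Series(x).rolling(baseline_win_s + 1, min_periods=1).max().to_numpy()
    )
    dev = baseline - x
    below = dev >= drop_pct
    out: list[Desaturation] = []
    i, n = 0, len(x)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_dur_s:
                seg_dev = dev[i:j]
                nadir = int(np.argmax(seg_dev))
                depth = float(seg_dev[nadir])
                fall = max(nadir, 1)
                out.append(Desaturation(
                    start_s=i, length_s=j - i, depth=depth,
                    slope=depth / fall, area=float(seg_dev.sum()),
                ))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# global features
# ---------------------------------------------------------------------------

GLOBAL_FEATURES = [
    # time domain
    "mean", "median", "min", "std", "spo2_range",
    "p95", "p90", "p85", "m95", "m90", "m85", "zc", "delta_index",
    # frequency domain
    "psd_total", "psd_band", "psd_ratio", "psd_peak",
    # nonlinear
    "apen", "sampen", "peen", "lz", "dfa", "ctm",
    # morphology (PRSA)
    "prsa_c", "prsa_ad", "prsa_s", "prsa_sb", "prsa_sa",
    # desaturation events
    "odi3", "dl_mean", "dl_sd", "dd_mean", "dd_sd",
    "ds_mean", "ds_sd", "da_mean", "da_sd", "td_mean", "td_sd",
    # hypoxic burden
    "pod", "aod", "ct90", "ca90",
    # demographics
    "age", "bmi", "sex", "smoking",
]

_ENTROPY_WIN_S = 600


def _windowed(fn, x: np.ndarray, win: int = _ENTROPY_WIN_S) -> float:
    """Mean of ``fn`` over consecutive windows (entropies are quadratic)."""
    n = len(x)
    if n <= win:
        return float(fn(x))
    vals = [fn(x[i : i + win]) for i in range(0, n - win + 1, win)]
    return float(np.mean(vals))


def _entropies_windowed(x: np.ndarray, win: int = _ENTROPY_WIN_S) -> tuple[float, float]:
    """(ApEn, SampEn) averaged over windows, sharing the match matrix."""
    n = len(x)
    starts = [0] if n <= win else range(0, n - win + 1, win)
    ap, se = [], []
    for i in starts:
        seg = x[i : i + min(win, n)]
        sd = seg.std()
        if sd == 0:
            ap.append(0.0)
            se.append(0.0)
            continue
        match = _m1_match(seg, 0.25 * sd)
        ap.append(_apen_m1(match, len(seg)))
        se.append(_sampen_m1(match, len(seg)))
    return float(np.mean(ap)), float(np.mean(se))


def _prsa(x: np.ndarray, T: int = 10) -> dict[str, float]:
    """Phase-rectified signal averaging anchored on decreases."""
    anchors = np.flatnonzero(x[1:] < x[:-1]) + 1
    anchors = anchors[(anchors >= T) & (anchors < len(x) - T)]
    if len(anchors) == 0:
        return {k: 0.0 for k in ("prsa_c", "prsa_ad", "prsa_s", "prsa_sb", "prsa_sa")}
    idx = anchors[:, None] + np.arange(-T, T)[None, :]
    w = x[idx].mean(axis=0)
    # capacity: quarter-sum around the anchor (standard AC/DC estimator)
    c = (w[T] + w[T + 1] - w[T - 1] - w[T - 2]) / 4.0
    before, after = w[:T], w[T:]
    k = np.arange(T)
    km = k - k.mean()

    def slope(seg):
        return float(seg @ km / (km @ km))

    return {
        "prsa_c": float(c),
        "prsa_ad": float(after.mean() - before.mean()),
        "prsa_s": float(np.polyfit(np.arange(2 * T), w, 1)[0]),
        "prsa_sb": slope(before),
        "prsa_sa": slope(after),
    }


def global_features(
    rec: Recording, demographics: tuple[float, float, int, int] | None = None
) -> pd.Series:
    """Overnight feature vector (order: GLOBAL_FEATURES) of a cleaned recording.

    Requires at least 5 minutes of 1 Hz signal; the canonical use is on the
    full clipped night.
    """
    x = np.asarray(rec.spo2, dtype=float)
    if len(x) < 300:
        raise FeatureError("overnight signal shorter than 5 minutes")
    demo = demographics if demographics is not None else rec.demographics
    hours = len(x) / 3600.0
    out: dict[str, float] = {}

    # time domain
    out["mean"] = float(x.mean())
    out["median"] = float(np.median(x))
    out["min"] = float(x.min())
    out["std"] = float(x.std())
    out["spo2_range"] = float(x.max() - x.min())
    for thr in (95, 90, 85):
        below = x < thr
        out[f"p{thr}"] = float(below.mean())
        out[f"m{thr}"] = float(x[below].mean()) if below.any() else float(thr)
    centered = x - x.mean()
    out["zc"] = float(np.sum(np.sign(centered[:-1]) * np.sign(centered[1:]) < 0))
    # delta index: mean |difference| of consecutive 12 s interval means
    n12 = len(x) // 12
    means12 = x[: n12 * 12].reshape(n12, 12).mean(axis=1)
    out["delta_index"] = float(np.abs(np.diff(means12)).mean()) if n12 > 1 else 0.0

    # frequency domain (Welch, 512 s segments, 50 % overlap)
    nper = min(512, len(x))
    f, pxx = sps.welch(x, fs=1.0, nperseg=nper, noverlap=nper // 2)
    df = f[1] - f[0] if len(f) > 1 else 1.0
    band = (f >= 0.03) & (f <= 0.17)
    out["psd_total"] = float(pxx.sum() * df)
    out["psd_band"] = float(pxx[band].sum() * df)
    out["psd_ratio"] = out["psd_band"] / out["psd_total"] if out["psd_total"] > 0 else 0.0
    out["psd_peak"] = float(pxx[band].max()) if band.any() else 0.0

    # nonlinear
    out["apen"], out["sampen"] = _entropies_windowed(x)
    out["peen"] = perm_entropy(x, order=3, delay=1, normalize=True)
    out["lz"] = float(lz_signal_complexity(x))
    out["dfa"] = dfa_alpha(x)
    out["ctm"] = ctm(x, rho=1.0)

    # morphology
    out.update(_prsa(x, T=10))

    # desaturation statistics
    desats = detect_desaturations(x, drop_pct=3.0, min_dur_s=10)
    out["odi3"] = len(desats) / hours
    lengths = [d.length_s for d in desats]
    depths = [d.depth for d in desats]
    slopes = [d.slope for d in desats]
    areas = [d.area for d in desats]
    starts = [d.start_s for d in desats]
    gaps = list(np.diff(starts)) if len(starts) > 1 else []
    for name, vals in (("dl", lengths), ("dd", depths), ("ds", slopes),
                       ("da", areas), ("td", gaps)):
        arr = np.asarray(vals, dtype=float)
        out[f"{name}_mean"] = float(arr.mean()) if len(arr) else 0.0
        out[f"{name}_sd"] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0

    # hypoxic burden
    out["pod"] = float(sum(lengths)) / len(x)
    out["aod"] = float(sum(areas)) / hours
    out["ct90"] = float(np.mean(x < 90.0))
    out["ca90"] = float(np.sum(np.clip(90.0 - x, 0.0, None))) / hours

    out["age"], out["bmi"], out["sex"], out["smoking"] = [float(v) for v in demo]
    ser = pd.Series(out, dtype=float).reindex(GLOBAL_FEATURES)
    if ser.isna().any():
        raise FeatureError(f"missing features: {list(ser.index[ser.isna()])}")
    return ser


def global_feature_matrix(records: list[Recording]) -> pd.DataFrame:
    """Stack per-subject overnight vectors into a DataFrame."""
    rows = {r.subject_id: global_features(r) for r in records}
    return pd.DataFrame(rows).T
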