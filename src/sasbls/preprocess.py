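"""Subject screening, SpO2 cleaning and fixed-window segmentation.

The cleaning chain mirrors standard oximetry practice: trim the wake edges
of the record, resample to 1 Hz, flag physiologically implausible samples
(value outside [60, 100] or a step change above 4 %/s), interpolate short
qualifying artifact runs with a delta filter, cut the night into
non-overlapping windows, and label a window positive when more than 5 s of
an annotated respiratory event falls inside it.

Boundary conventions follow the wording of the screening rules strictly:
a subject is excluded when the outlier fraction exceeds 1/5, fewer than
three sleep stages appear, sleep efficiency is below 50 % or total sleep
time is below five hours; ties pass screening.  Artifact runs are
interpolated only when strictly shorter than 3 s and their enclosing window
carries at most 10 % flagged samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

from .synth import Recording, EPOCH_S

__all__ = [
    "ScreeningReport",
    "SampleSet",
    "screen_subject",
    "clip_wake_edges",
    "resample_1hz",
    "flag_outliers",
    "delta_filter",
    "segment_and_label",
    "sample_exclude",
    "preprocess_recording",
]

ALLOWED_WINDOWS = (10, 30, 60, 90, 120, 180, 300)


class PreprocessError(ValueError):
    pass


@dataclass
class ScreeningReport:
    subject_id: str
    excluded: bool
    reasons: set[str]
    outlier_fraction: float
    n_stages: int
    sleep_efficiency: float
    tst_min: float


@dataclass
class SampleSet:
    """Fixed-length 1 Hz SpO2 windows with binary event labels.

    ``positions`` keeps the original window index i (1-based) within the
    original count ``n_total`` so that position-dependent downstream logic
    survives sample exclusion.  ``residual_mask`` flags seconds whose
    artifacts could not be interpolated.
    """

    segments: np.ndarray          # (n, window_s)
    labels: np.ndarray            # (n,) in {0, 1}
    positions: np.ndarray         # (n,) 1-based original indices
    n_total: int
    overnight_mean: float
    subject_id: str
    window_s: int
    tst_min: float
    residual_mask: np.ndarray | None = None   # (n, window_s) bool
    flagged_mask: np.ndarray | None = None    # (n, window_s) bool


# --- screening -------------------------------------------------------------

def screen_subject(rec: Recording) -> ScreeningReport:
    """Apply the subject-level exclusion rules.

    Exclusion triggers on any of: flagged-outlier fraction > 1/5, fewer than
    3 distinct sleep stages, sleep efficiency < 50 %, or TST < 300 min.
    """
    if not rec.hypnogram:
        raise PreprocessError("screening requires a hypnogram")
    sig1 = resample_1hz(rec.spo2, rec.fs)
    mask = flag_outliers(sig1)
    outlier_fraction = float(mask.mean()) if len(mask) else 0.0
    stages = {s for s in rec.hypnogram if s != "W"}
    n_stages = len(stages)
    tst_min = rec.tst_min()
    tib_min = len(rec.hypnogram) * EPOCH_S / 60.0
    sleep_efficiency = tst_min / tib_min if tib_min > 0 else 0.0

    reasons: set[str] = set()
    if outlier_fraction > 1.0 / 5.0:
        reasons.add("outlier_fraction")
    if n_stages < 3:
        reasons.add("stage_count")
    if sleep_efficiency < 0.5:
        reasons.add("sleep_efficiency")
    if tst_min < 300.0:
        reasons.add("total_sleep_time")
    return ScreeningReport(
        subject_id=rec.subject_id,
        excluded=bool(reasons),
        reasons=reasons,
        outlier_fraction=outlier_fraction,
        n_stages=n_stages,
        sleep_efficiency=sleep_efficiency,
        tst_min=tst_min,
    )


# --- cleaning --------------------------------------------------------------

def clip_wake_edges(rec: Recording) -> Recording:
    """Remove the leading/trailing maximal wake runs; shift event times."""
    hyp = rec.hypnogram
    first = 0
    while first < len(hyp) and hyp[first] == "W":
        first += 1
    if first == len(hyp):
        raise PreprocessError("record is entirely wake")
    last = len(hyp)
    while last > first and hyp[last - 1] == "W":
        last -= 1

    start_s = first * EPOCH_S
    end_s = last * EPOCH_S
    i0 = int(start_s * rec.fs)
    i1 = int(end_s * rec.fs)
    events = []
    for s, dur, kind in rec.events:
        a = max(s, start_s)
        b = min(s + dur, end_s)
        if b > a:
            events.append((a - start_s, b - a, kind))
    return Recording(
        spo2=rec.spo2[i0:i1].copy(),
        fs=rec.fs,
        hypnogram=hyp[first:last],
        events=events,
        demographics=rec.demographics,
        ahi_label=rec.ahi_label,
        subject_id=rec.subject_id,
    )


def resample_1hz(signal: np.ndarray, fs: float) -> np.ndarray:
    """Mean-decimate to 1 Hz; output length floor(len/fs)."""
    if fs < 1:
        raise PreprocessError("sampling rates below 1 Hz are unsupported")
    if fs == 1:
        return np.asarray(signal, dtype=float)
    step = int(round(fs))
    n = len(signal) // step
    return np.asarray(signal[: n * step], dtype=float).reshape(n, step).mean(axis=1)


def flag_outliers(signal: np.ndarray) -> np.ndarray:
    """Oximetry artifact screen on the 1 Hz signal.

    A sample is flagged when its value lies outside [60, 100] or either of
    its adjacent first differences exceeds 4 %/s in magnitude.
    """
    x = np.asarray(signal, dtype=float)
    mask = (x < 60.0) | (x > 100.0)
    if len(x) > 1:
        big = np.abs(np.diff(x)) > 4.0
        mask[:-1] |= big
        mask[1:] |= big
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) half-open index pairs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def delta_filter(
    signal: np.ndarray, mask: np.ndarray, window_s: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate qualifying artifact runs; return (signal, residual mask).

    A run qualifies when its outlier duration is under 3 s and the flagged
    fraction of every ``window_s`` window it touches is at most 10 %.
    Because a range-violating sample also flags its delta-violating
    neighbours, the outlier duration of a run is counted over its
    range-violating core (falling back to the full run length for pure
    delta glitches); otherwise a lone dropout second could never qualify.
    Non-qualifying runs are left in the residual mask for sample-wise
    exclusion.
    """
    x = np.asarray(signal, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise PreprocessError("signal is entirely flagged; nothing to anchor on")
    residual = np.zeros_like(mask)
    n = len(x)
    # per-window flagged fraction on the fixed segmentation grid
    n_win = max(1, n // window_s)
    frac = np.zeros(n_win + 1)
    for w in range(n_win + 1):
        seg = mask[w * window_s : (w + 1) * window_s]
        frac[w] = seg.mean() if len(seg) else 0.0
    valid_idx = np.flatnonzero(~mask)
    for i, j in _runs(mask):
        touched = range(i // window_s, min((j - 1) // window_s, n_win) + 1)
        ok_frac = all(frac[w] <= 0.10 for w in touched)
        core = int(np.sum((x[i:j] < 60.0) | (x[i:j] > 100.0)))
        duration = core if core > 0 else (j - i)
        if duration < 3 and ok_frac:
            x[i:j] = np.interp(np.arange(i, j), valid_idx, x[valid_idx])
        else:
            residual[i:j] = True
    return x, residual


def segment_and_label(
    rec: Recording,
    window_s: int = 30,
    min_overlap_s: float = 5.0,
    residual_mask: np.ndarray | None = None,
    flagged_mask: np.ndarray | None = None,
) -> SampleSet:
    """Cut the cleaned 1 Hz signal into windows and label them.

    Windows are half-open [k*w, (k+1)*w); the trailing partial window is
    dropped.  A window is positive iff the annotated event time inside it
    strictly exceeds ``min_overlap_s``.
    """
    sig = np.asarray(rec.spo2, dtype=float)
    n = len(sig)
    n_win = n // window_s
    if n_win == 0:
        raise PreprocessError("signal shorter than one window")
    segs = sig[: n_win * window_s].reshape(n_win, window_s)

    overlap = np.zeros(n_win)
    for s, dur, _kind in rec.events:
        for k in range(max(0, int(s // window_s)), min(n_win, int((s + dur) // window_s) + 1)):
            a = max(s, k * window_s)
            b = min(s + dur, (k + 1) * window_s)
            if b > a:
                overlap[k] += b - a
    labels = (overlap > min_overlap_s).astype(int)

    def _reshape(m):
        if m is None:
            return None
        return np.asarray(m, dtype=bool)[: n_win * window_s].reshape(n_win, window_s)

    return SampleSet(
        segments=segs,
        labels=labels,
        positions=np.arange(1, n_win + 1),
        n_total=n_win,
        overnight_mean=float(sig.mean()),
        subject_id=rec.subject_id,
        window_s=window_s,
        tst_min=rec.tst_min(),
        residual_mask=_reshape(residual_mask),
        flagged_mask=_reshape(flagged_mask),
    )


def sample_exclude(samples: SampleSet) -> SampleSet:
    """Drop windows whose artifacts disqualify them.

    A window is removed when it contains residual (uninterpolated) artifact
    seconds, or when it was flagged at all and carries no event label.
    Positions of the survivors keep their original 1-based index.
    """
    if samples.residual_mask is None and samples.flagged_mask is None:
        return samples
    n = len(samples.labels)
    residual = (
        samples.residual_mask.any(axis=1)
        if samples.residual_mask is not None
        else np.zeros(n, dtype=bool)
    )
    flagged = (
        samples.flagged_mask.any(axis=1)
        if samples.flagged_mask is not None
        else np.zeros(n, dtype=bool)
    )
    drop = residual | (flagged & (samples.labels == 0))
    keep = ~drop
    return replace(
        samples,
        segments=samples.segments[keep],
        labels=samples.labels[keep],
        positions=samples.positions[keep],
        residual_mask=None if samples.residual_mask is None else samples.residual_mask[keep],
        flagged_mask=None if samples.flagged_mask is None else samples.flagged_mask[keep],
    )


def read_edf_spo2(path, channel: str = "SaO2") -> tuple[np.ndarray, float]:
    """Read one SpO2 channel from an EDF file (optional; needs mne).

    Returns (signal, sampling_rate).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise PreprocessError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise PreprocessError(f"channel {channel!r} not present in {path}")
    return raw.get_data(picks=[channel])[0], float(raw.info["sfreq"])


def read_event_xml(path) -> list[tuple[float, float, str]]:
    """Minimal NSRR-style scored-event reader: (start_s, duration_s, type).

    Keeps only apnea/hypopnea events, matched case-insensitively on the
    event concept name.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    events: list[tuple[float, float, str]] = []
    for ev in root.iter("ScoredEvent"):
        concept = (ev.findtext("EventConcept") or "").lower()
        if "apnea" in concept or "hypopnea" in concept:
            kind = "hypopnea" if "hypopnea" in concept else "apnea"
            events.append((float(ev.findtext("Start", "0")),
                           float(ev.findtext("Duration", "0")), kind))
    return sorted(events)


def preprocess_recording(
    rec: Recording, window_s: int = 30, min_overlap_s: float = 5.0
) -> tuple[SampleSet, Recording]:
    """Full cleaning chain: clip -> resample -> delta filter -> segment -> exclude.

    Returns the surviving sample set and the cleaned 1 Hz recording (used by
    overnight feature extraction).
    """
    clipped = clip_wake_edges(rec)
    sig = resample_1hz(clipped.spo2, clipped.fs)
    mask = flag_outliers(sig)
    cleaned, residual = delta_filter(sig, mask, window_s=window_s)
    # overnight summary features must not see residual artifact runs: bridge
    # them by interpolation in the overnight view; the affected windows are
    # still dropped sample-wise below
    overnight = cleaned
    if residual.any() and not residual.all():
        overnight = cleaned.copy()
        valid = np.flatnonzero(~residual)
        overnight[residual] = np.interp(np.flatnonzero(residual), valid,
                                        cleaned[valid])
    clean_rec = Recording(
        spo2=overnight,
        fs=1.0,
        hypnogram=clipped.hypnogram,
        events=clipped.events,
        demographics=clipped.demographics,
        ahi_label=clipped.ahi_label,
        subject_id=clipped.subject_id,
    )
    samples = segment_and_label(
        clean_rec, window_s=window_s, min_overlap_s=min_overlap_s,
        residual_mask=residual, flagged_mask=mask,
    )
    return sample_exclude(samples), clean_rec
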