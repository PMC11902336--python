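"""Synthetic overnight SpO2 recordings with known apnea/hypopnea annotations.

Each generated subject is an overnight pulse-oximetry trace in which every
annotated respiratory event leaves a desaturation footprint: after a
physiologic lag the saturation falls piecewise-linearly to a nadir, holds,
and recovers.  Event onsets follow a Poisson process at the configured
events/hour rate (the target AHI) with overlaps thinned out, and event
durations are lognormal around the 21.6 s / 11.81 s mean/SD of scored
apnea-hypopnea events in large polysomnography cohorts.  Optional slow
baseline wander, sporadic sensor-dropout artifacts and measurement noise
emulate the main nuisance structure of real oximetry.

The true AHI of a subject is 60 * n_events / sleep_minutes by construction,
so downstream detection and regression stages can be validated against an
exact ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SynthConfig",
    "Recording",
    "generate_subject",
    "generate_cohort",
    "write_recording",
    "read_recording",
]

SLEEP_STAGES = ("W", "N1", "N2", "N3", "R")
EPOCH_S = 30.0


class InvalidConfigError(ValueError):
    """Raised when a SynthConfig violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic subject.

    Parameters
    ----------
    duration_min:
        Minutes of sleep (the sleep period between the wake edges).
    baseline_spo2:
        Resting saturation in percent.
    event_rate_per_hour:
        Poisson rate of respiratory events, i.e. the target AHI.
    event_duration_mean_s, event_duration_sd_s:
        Mean / SD of the lognormal annotated event duration (seconds).
    desat_depth_range:
        (low, high) percent drop sampled per event.
    desat_lag_s:
        Delay from event onset to the start of the desaturation fall.
    artifact_rate_per_hour:
        Rate of sensor-dropout bursts (runs of 0) per hour.
    drift_amplitude:
        Amplitude (percent) of the slow sinusoidal baseline wander.
    noise_sd:
        SD of additive Gaussian measurement noise (percent); 0 disables it.
    fs:
        Output sampling rate in Hz.
    seed:
        RNG seed; fixed seed gives a bit-identical recording.
    """

    duration_min: float = 420.0
    baseline_spo2: float = 97.0
    event_rate_per_hour: float = 15.0
    event_duration_mean_s: float = 21.6
    event_duration_sd_s: float = 11.81
    desat_depth_range: tuple[float, float] = (3.0, 10.0)
    desat_lag_s: float = 10.0
    artifact_rate_per_hour: float = 0.0
    drift_amplitude: float = 1.0
    noise_sd: float = 0.0
    fs: float = 1.0
    seed: int | None = None

    def validate(self) -> None:
        if not self.duration_min > 0:
            raise InvalidConfigError("duration_min must be > 0")
        if self.event_rate_per_hour < 0:
            raise InvalidConfigError("event_rate_per_hour must be >= 0")
        lo, hi = self.desat_depth_range
        if not (0 < lo <= hi <= 30):
            raise InvalidConfigError("desat_depth_range must lie within (0, 30]")
        if self.fs < 1:
            raise InvalidConfigError("fs must be >= 1 Hz")


@dataclass
class Recording:
    """One subject's overnight recording plus ground truth.

    ``events`` holds ``(start_s, duration_s, type)`` tuples relative to the
    start of the signal, sorted and non-overlapping.  ``ahi_label`` is the
    true AHI (events per hour of sleep).
    """

    spo2: np.ndarray
    fs: float
    hypnogram: list[str]
    events: list[tuple[float, float, str]]
    demographics: tuple[float, float, int, int]
    ahi_label: float
    subject_id: str

    @property
    def duration_s(self) -> float:
        return len(self.spo2) / self.fs

    def tst_min(self) -> float:
        """Total sleep time in minutes (non-wake epochs)."""
        return sum(1 for s in self.hypnogram if s != "W") * EPOCH_S / 60.0


# --- hypnogram -------------------------------------------------------------

_STAGE_CYCLE = ["N1", "N2", "N3", "N2", "R"]


def _make_hypnogram(rng: np.random.Generator, sleep_epochs: int) -> tuple[list[str], int, int]:
    """Leading wake, a cyclic stage sequence, trailing wake.

    Returns (hypnogram, lead_epochs, trail_epochs).  Interior wake is kept
    rare and short so synthetic subjects pass sleep-quality screening by
    construction.
    """
    lead = int(rng.integers(6, 20))
    trail = int(rng.integers(4, 14))
    stages: list[str] = []
    ci = 0
    while len(stages) < sleep_epochs:
        stage = _STAGE_CYCLE[ci % len(_STAGE_CYCLE)]
        ci += 1
        block = int(rng.integers(8, 30))
        stages.extend([stage] * block)
        # brief interior arousal every few blocks
        if rng.random() < 0.15 and len(stages) < sleep_epochs - 2:
            stages.append("W")
    stages = stages[:sleep_epochs]
    return ["W"] * lead + stages + ["W"] * trail, lead, trail


# --- events ----------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_events(
    rng: np.random.Generator, cfg: SynthConfig, sleep_start_s: float, sleep_end_s: float
) -> list[tuple[float, float, str]]:
    hours = (sleep_end_s - sleep_start_s) / 3600.0
    n = rng.poisson(cfg.event_rate_per_hour * hours)
    if n == 0:
        return []
    hi = max(sleep_start_s + 1.0, sleep_end_s - 60.0)
    onsets = np.sort(rng.uniform(sleep_start_s, hi, size=n))
    mu, sigma = _lognormal_params(cfg.event_duration_mean_s, cfg.event_duration_sd_s)
    durations = np.clip(rng.lognormal(mu, sigma, size=n), 10.0, 90.0)
    # footprint of the desaturation: lag + fall(10) + hold(5) + recovery(15)
    footprint = cfg.desat_lag_s + 30.0
    kinds = np.where(rng.random(n) < 1.0 / 3.0, "apnea", "hypopnea")
    events: list[tuple[float, float, str]] = []
    t_free = -np.inf
    for onset, dur, kind in zip(onsets, durations, kinds):
        if onset < t_free:
            continue  # thin overlapping draws to enforce non-overlap
        events.append((float(onset), float(dur), str(kind)))
        t_free = onset + max(dur, footprint) + 5.0
    return events


def _desat_profile(t: np.ndarray, onset: float, depth: float, lag: float) -> np.ndarray:
    """Piecewise-linear drop: fall 10 s, hold 5 s, recover 15 s."""
    t0 = onset + lag
    knots = np.array([t0, t0 + 10.0, t0 + 15.0, t0 + 30.0])
    vals = np.array([0.0, -depth, -depth, 0.0])
    return np.interp(t, knots, vals, left=0.0, right=0.0)


def _sample_depth(rng: np.random.Generator, cfg: SynthConfig, kind: str) -> float:
    lo, hi = cfg.desat_depth_range
    mid = lo + 0.5 * (hi - lo)
    if kind == "apnea":  # apneas desaturate deeper on average
        return float(rng.uniform(mid, hi))
    return float(rng.uniform(lo, mid + 0.5 * (hi - mid)))


# --- public API ------------------------------------------------------------

def generate_subject(config: SynthConfig, subject_id: str = "S0000") -> Recording:
    """Generate one synthetic overnight recording.

    Deterministic for a fixed ``config.seed``.  The true AHI label is
    ``60 * n_events / duration_min``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sleep_epochs = int(round(config.duration_min * 60.0 / EPOCH_S))
    hypnogram, lead, trail = _make_hypnogram(rng, sleep_epochs)
    n_epochs = len(hypnogram)
    n_sec = n_epochs * int(EPOCH_S)
    t = np.arange(int(n_sec * config.fs)) / config.fs

    sleep_start = lead * EPOCH_S
    sleep_end = (n_epochs - trail) * EPOCH_S
    events = _draw_events(rng, config, sleep_start, sleep_end)

    signal = np.full(t.shape, config.baseline_spo2, dtype=float)
    if config.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.drift_amplitude * 0.5 * (
            np.sin(2 * np.pi * t / 3600.0 + phase) - 1.0
        )
    for onset, _dur, kind in events:
        depth = _sample_depth(rng, config, kind)
        signal += _desat_profile(t, onset, depth, config.desat_lag_s)
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=signal.shape)

    # sensor-dropout artifacts: runs of 0, geometric duration (mean 2 s)
    if config.artifact_rate_per_hour > 0:
        n_art = rng.poisson(config.artifact_rate_per_hour * n_sec / 3600.0)
        for _ in range(n_art):
            start = int(rng.integers(0, len(signal)))
            dur = int(rng.geometric(0.5)) * max(1, int(config.fs))
            signal[start : start + dur] = 0.0

    np.clip(signal, 0.0, 100.0, out=signal)

    age = float(np.clip(rng.normal(62.0, 11.0), 30, 90))
    bmi = float(np.clip(rng.normal(28.0, 5.0), 17, 50))
    sex = int(rng.integers(0, 2))
    smoking = int(rng.integers(0, 2))

    ahi = 60.0 * len(events) / config.duration_min
    return Recording(
        spo2=signal,
        fs=config.fs,
        hypnogram=hypnogram,
        events=events,
        demographics=(age, bmi, sex, smoking),
        ahi_label=ahi,
        subject_id=subject_id,
    )


def default_config_sampler(rng: np.random.Generator) -> SynthConfig:
    """Study-condition cohort sampler: target AHI uniform on [0, 60]."""
    return SynthConfig(
        duration_min=360.0,
        event_rate_per_hour=float(rng.uniform(0.0, 60.0)),
        artifact_rate_per_hour=2.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_subjects: int,
    config_sampler: Callable[[np.random.Generator], SynthConfig] | None = None,
    seed: int | None = None,
) -> list[Recording]:
    """Generate a reproducible cohort; per-subject seeds derive from ``seed``."""
    if n_subjects < 1:
        raise InvalidConfigError("n_subjects must be >= 1")
    sampler = config_sampler or default_config_sampler
    master = np.random.default_rng(seed)
    out = []
    for k in range(n_subjects):
        cfg = sampler(master)
        if cfg.seed is None:
            cfg = replace(cfg, seed=int(master.integers(0, 2**31 - 1)))
        out.append(generate_subject(cfg, subject_id=f"S{k:04d}"))
    return out


# --- canonical fixture formats --------------------------------------------

def write_recording(rec: Recording, directory: str | Path) -> None:
    """Write the per-subject CSV/TSV/JSON fixture triplet."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(rec.spo2)) / rec.fs
    with open(d / f"{rec.subject_id}_spo2.csv", "w") as fh:
        fh.write("time_s,spo2\n")
        for ti, v in zip(t, rec.spo2):
            fh.write(f"{ti:.3f},{v:.4f}\n")
    with open(d / f"{rec.subject_id}_events.tsv", "w") as fh:
        fh.write("start_s\tduration_s\ttype\n")
        for s, dur, kind in rec.events:
            fh.write(f"{s:.3f}\t{dur:.3f}\t{kind}\n")
    meta = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "hypnogram": rec.hypnogram,
        "demographics": list(rec.demographics),
        "ahi_label": rec.ahi_label,
    }
    with open(d / f"{rec.subject_id}_meta.json", "w") as fh:
        json.dump(meta, fh)


def read_recording(directory: str | Path, subject_id: str) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    d = Path(directory)
    with open(d / f"{subject_id}_meta.json") as fh:
        meta = json.load(fh)
    spo2 = np.loadtxt(d / f"{subject_id}_spo2.csv", delimiter=",", skiprows=1, usecols=1)
    events: list[tuple[float, float, str]] = []
    with open(d / f"{subject_id}_events.tsv") as fh:
        next(fh)
        for line in fh:
            s, dur, kind = line.rstrip("\n").split("\t")
            events.append((float(s), float(dur), kind))
    return Recording(
        spo2=np.atleast_1d(spo2),
        fs=float(meta["fs"]),
        hypnogram=list(meta["hypnogram"]),
        events=events,
        demographics=tuple(meta["demographics"]),
        ahi_label=float(meta["ahi_label"]),
        subject_id=subject_id,
    )
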