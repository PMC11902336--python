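"""SAS event-detection branch.

Stages: an initial BLS classifier yields per-window probabilities P0; the
SDFFU-corrected sequence P0' is expanded into a 5-window context block per
sample (probabilities at positions i-2..i+2, run statistics of the
thresholded context, and a run-length indicator); samples are split into
high/low-confidence groups by the softmax confidence of the initial
classifier and a separate context classifier is trained per group; the
context predictions finally enter an incremental BLS together with the raw
window features to produce the branch's event labels.

Sample order within each subject is preserved at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bls

__all__ = [
    "ContextBlock",
    "softmax2",
    "initial_detect",
    "build_context",
    "confidence_split",
    "ContextDetector",
    "final_detect",
]


class BranchError(ValueError):
    pass


def softmax2(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax over the class axis of a two-column score matrix."""
    s = np.asarray(scores, dtype=float)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def initial_detect(model: bls.BLSModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Initial probabilities and labels: P0 = softmax positive class, Y0 = P0 > 0.5."""
    scores = bls.predict(model, X)
    p0 = softmax2(scores)[:, 1]
    return p0, (p0 > 0.5).astype(int)


@dataclass
class ContextBlock:
    pcon: np.ndarray   # (N, 5) probabilities at i-2..i+2, zero-padded
    pcons: np.ndarray  # (N, 4) event count, total, mean, max run length
    llen: np.ndarray   # (N,) 1 iff the run containing i has length >= 3
    xcon: np.ndarray   # (N, 10) concatenation of the above


def build_context(p: np.ndarray, pad: str = "zero") -> ContextBlock:
    """Context expansion of one subject's (corrected) probability sequence.

    ``pcons`` summarizes the thresholded (> 0.5) 5-sample context: number of
    event runs, total, mean and maximum run length.  ``llen`` marks samples
    whose thresholded run — over the full subject sequence — spans at least
    3 windows.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n < 1:
        raise BranchError("subject has no samples")
    if pad == "zero":
        padded = np.concatenate([np.zeros(2), p, np.zeros(2)])
    elif pad == "edge":
        padded = np.concatenate([np.full(2, p[0]), p, np.full(2, p[-1])])
    else:
        raise BranchError(f"unknown pad mode {pad!r}")
    pcon = np.lib.stride_tricks.sliding_window_view(padded, 5).copy()

    binary = pcon > 0.5
    pcons = np.zeros((n, 4))
    for i in range(n):
        row = binary[i]
        lengths = []
        run = 0
        for b in row:
            if b:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
        if lengths:
            pcons[i] = [len(lengths), sum(lengths), np.mean(lengths), max(lengths)]

    # run length over the whole subject sequence
    mask = p > 0.5
    llen = np.zeros(n)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= 3:
                llen[i:j] = 1.0
            i = j
        else:
            i += 1
    return ContextBlock(pcon=pcon, pcons=pcons, llen=llen,
                        xcon=np.hstack([pcon, pcons, llen[:, None]]))


def confidence_split(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition sample indices by softmax confidence of the positive class.

    Returns (idx_hi, idx_lo); the exact-0.5 tie goes to the low group, so
    the partition is exhaustive and disjoint.
    """
    csas = softmax2(scores)[:, 1]
    hi = np.flatnonzero(csas > 0.5)
    lo = np.flatnonzero(csas <= 0.5)
    return hi, lo


class ContextDetector:
    """Confidence-gated pair of context classifiers.

    One BLS per confidence group; a group with no training members falls
    back to the other group's model.  Predictions are re-interleaved into
    the original sample order.
    """

    def __init__(self, config: bls.BLSConfig):
        self.config = config
        self.models: dict[str, bls.BLSModel | None] = {"hi": None, "lo": None}

    @staticmethod
    def _onehot(y: np.ndarray) -> np.ndarray:
        out = np.zeros((len(y), 2))
        out[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
        return out

    def fit(self, xcon: np.ndarray, y: np.ndarray, groups_hi: np.ndarray) -> "ContextDetector":
        """``groups_hi`` is a boolean mask of high-confidence training samples."""
        hi = np.asarray(groups_hi, dtype=bool)
        for name, mask in (("hi", hi), ("lo", ~hi)):
            if mask.sum() > 0:
                self.models[name] = bls.fit(xcon[mask], self._onehot(y[mask]), self.config)
        if self.models["hi"] is None:
            self.models["hi"] = self.models["lo"]
        if self.models["lo"] is None:
            self.models["lo"] = self.models["hi"]
        if self.models["hi"] is None:
            raise BranchError("no training samples in either confidence group")
        return self

    def predict_proba(self, xcon: np.ndarray, groups_hi: np.ndarray) -> np.ndarray:
        hi = np.asarray(groups_hi, dtype=bool)
        out = np.zeros(len(xcon))
        for name, mask in (("hi", hi), ("lo", ~hi)):
            if mask.sum() > 0:
                scores = bls.predict(self.models[name], xcon[mask])
                out[mask] = softmax2(scores)[:, 1]
        return out


def final_detect(
    model0: bls.BLSModel,
    X1_train: np.ndarray,
    ctx_train: np.ndarray,
    y_train: np.ndarray,
    X1_test: np.ndarray,
    ctx_test: np.ndarray,
) -> tuple[bls.BLSModel, np.ndarray, np.ndarray]:
    """Incremental BLS over [window features | context predictions].

    Returns the incremental model plus test probabilities and labels.
    """
    Y = ContextDetector._onehot(y_train)
    inc_model = bls.fit_incremental(model0, X1_train, np.atleast_2d(ctx_train.T).T, Y)
    scores = bls.predict(inc_model, X1_test, np.atleast_2d(ctx_test.T).T)
    p = softmax2(scores)[:, 1]
    return inc_model, p, (p > 0.5).astype(int)
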