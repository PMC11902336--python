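"""Broad Learning System: random feature maps + enhancement nodes + ridge.

A BLS is a flat random-feature network.  Standardized inputs are projected
through several groups of random linear feature maps; a bank of enhancement
nodes applies a bounded nonlinearity (tanh) to an orthonormalized random
projection of the concatenated feature nodes; the output layer is solved in
closed form by ridge regression on the joint design ``A = [Z | H]``:

    W = (A'A + lambda I)^{-1} A' Y

Incremental features (e.g. context predictions fed back into the network)
are appended as an extra standardized feature group that bypasses the
enhancement bank, and the output weights are re-solved — exactly, so the
incremental fit equals a from-scratch fit on the concatenated design.  A
Greville-style block-inverse update is available as a fast path and agrees
with the re-solve to numerical precision.

Random weights are drawn per input column from seeds spawned off the config
seed, so fits are bit-reproducible and the map of an existing column does
not depend on how many other columns are present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import linalg

__all__ = ["BLSConfig", "BLSModel", "fit", "predict", "fit_incremental"]


class BLSError(ValueError):
    pass


@dataclass(frozen=True)
class BLSConfig:
    n_feature_groups: int = 10
    nodes_per_group: int = 10
    n_enhancement: int = 100
    ridge_lambda: float = 2.0**-10
    activation: str = "tanh"
    seed: int = 0
    task: str = "classify"   # or "regress"
    feature_map: str = "random"   # "identity" degenerates the BLS to ridge

    def validate(self) -> None:
        if self.n_feature_groups < 1 or self.nodes_per_group < 1:
            raise BLSError("feature group counts must be >= 1")
        if self.n_enhancement < 0:
            raise BLSError("n_enhancement must be >= 0")
        if not self.ridge_lambda > 0:
            raise BLSError("ridge_lambda must be > 0 (closed form needs it)")
        if self.task not in ("classify", "regress"):
            raise BLSError(f"unknown task {self.task!r}")
        if self.activation not in ("tanh", "identity"):
            raise BLSError(f"unknown activation {self.activation!r}")
        if self.feature_map not in ("random", "identity"):
            raise BLSError(f"unknown feature_map {self.feature_map!r}")


def _col_weights(seed: int, group: int, col: int, k: int) -> np.ndarray:
    """Deterministic per-column random map row (seed-spawned)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group, col))
    return np.random.default_rng(ss).standard_normal(k)


def _group_bias(seed: int, group: int, k: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group, 0xFFFF))
    return np.random.default_rng(ss).standard_normal(k)


def _enh_weights(seed: int, d: int, k: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xE0,))
    w = np.random.default_rng(ss).standard_normal((d, max(k, 1)))
    if k == 0:
        return np.empty((d, 0))
    if d >= k:
        q, _ = np.linalg.qr(w[:, :k])
        return q
    q, _ = np.linalg.qr(w[:, :k].T)
    return q.T


@dataclass
class BLSModel:
    config: BLSConfig
    mu: np.ndarray               # training column means
    sigma: np.ndarray            # training column scales (0 -> 1)
    feature_weights: list[np.ndarray]
    feature_bias: list[np.ndarray]
    enh_weights: np.ndarray
    enh_scale: float
    W: np.ndarray                # output weights on [Z | H | Zinc]
    columns: list[str] | None = None
    inc_mu: np.ndarray | None = None
    inc_sigma: np.ndarray | None = None
    gram_inv: np.ndarray | None = None   # (A'A + lam I)^-1, kept for updates

    # -- design construction ------------------------------------------------
    # standardized inputs are clipped at |z| <= 8: far-out-of-distribution
    # rows (e.g. an event-free night among apneic training nights) otherwise
    # acquire unbounded leverage and the random-feature ridge extrapolates
    # wildly; the clip is inactive for in-distribution data
    Z_CLIP = 8.0

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return np.clip((X - self.mu) / self.sigma, -self.Z_CLIP, self.Z_CLIP)

    def _mapped(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardize(X)
        if self.config.feature_map == "identity":
            return Xs
        groups = [Xs @ Wg + bg for Wg, bg in zip(self.feature_weights, self.feature_bias)]
        return np.hstack(groups)

    def design(self, X: np.ndarray, X_inc: np.ndarray | None = None) -> np.ndarray:
        Z = self._mapped(X)
        parts = [Z]
        if self.enh_weights.shape[1] > 0:
            H = Z @ self.enh_weights * self.enh_scale
            if self.config.activation == "tanh":
                H = np.tanh(H)
            parts.append(H)
        if X_inc is not None:
            parts.append(np.clip((X_inc - self.inc_mu) / self.inc_sigma,
                                 -self.Z_CLIP, self.Z_CLIP))
        return np.hstack(parts)


def _check_X(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise BLSError(f"{name} must be 2-D")
    if not np.all(np.isfinite(X)):
        raise BLSError(f"{name} contains missing or non-finite values")
    return X


def _scales(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma = np.where(sigma == 0, 1.0, sigma)
    return mu, sigma


def fit(
    X: np.ndarray,
    Y: np.ndarray,
    config: BLSConfig | None = None,
    columns: list[str] | None = None,
    X_inc: np.ndarray | None = None,
) -> BLSModel:
    """Fit output weights in closed form on the BLS design of ``X``.

    ``Y`` is the target matrix (one-hot for classification, column vector of
    transformed targets for regression).  ``X_inc`` optionally appends an
    incremental feature group to the design, which makes this the reference
    "from-scratch fit on the concatenated design".
    """
    config = config or BLSConfig()
    config.validate()
    X = _check_X(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(X) != len(Y):
        raise BLSError("X and Y row counts differ")
    if config.task == "classify" and Y.shape[1] < 2:
        raise BLSError("classification expects one-hot targets with >= 2 columns")

    mu, sigma = _scales(X)
    d = X.shape[1]
    k = config.nodes_per_group
    fw = [
        np.vstack([_col_weights(config.seed, g, j, k) for j in range(d)])
        for g in range(config.n_feature_groups)
    ]
    fb = [_group_bias(config.seed, g, k) for g in range(config.n_feature_groups)]
    model = BLSModel(
        config=config, mu=mu, sigma=sigma,
        feature_weights=fw, feature_bias=fb,
        enh_weights=np.empty((config.n_feature_groups * k, 0)),
        enh_scale=1.0, W=np.empty((0, Y.shape[1])), columns=columns,
    )
    Z = model._mapped(X)
    if config.n_enhancement > 0:
        model.enh_weights = _enh_weights(config.seed, Z.shape[1], config.n_enhancement)
        raw = Z @ model.enh_weights
        amax = np.abs(raw).max()
        model.enh_scale = 0.8 / amax if amax > 0 else 1.0
    if X_inc is not None:
        X_inc = _check_X(X_inc, "X_inc")
        if len(X_inc) != len(X):
            raise BLSError("X_inc row count differs from X")
        model.inc_mu, model.inc_sigma = _scales(X_inc)
    A = model.design(X, X_inc)
    lam = config.ridge_lambda
    G = A.T @ A + lam * np.eye(A.shape[1])
    rhs = A.T @ Y
    model.W = linalg.solve(G, rhs, assume_a="pos", check_finite=False)
    model.gram_inv = linalg.inv(G, check_finite=False)
    return model


def predict(model: BLSModel, X: np.ndarray, X_inc: np.ndarray | None = None) -> np.ndarray:
    """Linear outputs of the fitted network (scores or transformed targets)."""
    if model.W.size == 0:
        raise BLSError("model is not fitted")
    X = _check_X(X)
    if X.shape[1] != len(model.mu):
        raise BLSError("column count does not match the training registry")
    if (X_inc is None) != (model.inc_mu is None):
        raise BLSError("incremental feature presence must match training")
    return model.design(X, X_inc) @ model.W


def fit_incremental(
    model: BLSModel,
    X: np.ndarray,
    X_inc: np.ndarray,
    Y: np.ndarray,
    method: str = "resolve",
) -> BLSModel:
    """Append incremental features and re-solve the output weights.

    ``method='resolve'`` refits on the concatenated design (exact);
    ``method='greville'`` performs the block-inverse update of the stored
    Gram inverse and agrees with the re-solve to numerical precision.
    """
    X = _check_X(X)
    X_inc = _check_X(X_inc, "X_inc")
    if len(X) != len(X_inc):
        raise BLSError("X and X_inc are not row-aligned")
    if method == "resolve":
        return fit(X, Y, model.config, columns=model.columns, X_inc=X_inc)
    if method != "greville":
        raise BLSError(f"unknown method {method!r}")
    if model.gram_inv is None:
        raise BLSError("greville update needs the stored Gram inverse")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    A = model.design(X)
    inc_mu, inc_sigma = _scales(X_inc)
    Zi = np.clip((X_inc - inc_mu) / inc_sigma,
                 -BLSModel.Z_CLIP, BLSModel.Z_CLIP)
    lam = model.config.ridge_lambda
    # block inverse of [[G, B],[B', C]] with G = A'A+lam I already inverted
    B = A.T @ Zi
    C = Zi.T @ Zi + lam * np.eye(Zi.shape[1])
    Ginv = model.gram_inv
    S = C - B.T @ (Ginv @ B)               # Schur complement
    Sinv = linalg.inv(S, check_finite=False)
    GB = Ginv @ B
    top = A.T @ Y
    bot = Zi.T @ Y
    W_top = Ginv @ top + GB @ (Sinv @ (B.T @ (Ginv @ top) - bot))
    W_bot = Sinv @ (bot - B.T @ (Ginv @ top))
    return BLSModel(
        config=model.config, mu=model.mu, sigma=model.sigma,
        feature_weights=model.feature_weights, feature_bias=model.feature_bias,
        enh_weights=model.enh_weights, enh_scale=model.enh_scale,
        W=np.vstack([W_top, W_bot]), columns=model.columns,
        inc_mu=inc_mu, inc_sigma=inc_sigma,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: BLSModel, path: str | Path) -> None:
    """Portable JSON serialization (round-trips predictions bit-exactly)."""
    def enc(a):
        return None if a is None else np.asarray(a).tolist()

    payload = {
        "config": asdict(model.config),
        "mu": enc(model.mu), "sigma": enc(model.sigma),
        "feature_weights": [enc(w) for w in model.feature_weights],
        "feature_bias": [enc(b) for b in model.feature_bias],
        "enh_weights": enc(model.enh_weights), "enh_scale": model.enh_scale,
        "W": enc(model.W), "columns": model.columns,
        "inc_mu": enc(model.inc_mu), "inc_sigma": enc(model.inc_sigma),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> BLSModel:
    p = json.loads(Path(path).read_text())

    def dec(a):
        return None if a is None else np.asarray(a, dtype=float)

    return BLSModel(
        config=BLSConfig(**p["config"]),
        mu=dec(p["mu"]), sigma=dec(p["sigma"]),
        feature_weights=[dec(w) for w in p["feature_weights"]],
        feature_bias=[dec(b) for b in p["feature_bias"]],
        enh_weights=dec(p["enh_weights"]), enh_scale=p["enh_scale"],
        W=dec(p["W"]), columns=p["columns"],
        inc_mu=dec(p["inc_mu"]), inc_sigma=dec(p["inc_sigma"]),
    )
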