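"""PLS1 regression by the classical NIPALS algorithm.

One model per analyte links the 24-channel absorbance spectra to reference
values. Components are extracted iteratively: each weight vector is the
covariance direction between the deflated predictors and the response,
scores are mutually orthogonal, and the final model collapses to a single
regression vector b so that prediction is an affine map of the spectrum.
Predictors are centered; autoscaling is off by default because the channels
share units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PLSModel", "fit_pls", "predict", "select_components"]


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    W are the NIPALS weights, P the predictor loadings, q the response
    loadings; B stacks the cumulative regression vectors for 1..k components
    (so truncated predictions need no refit) and ``b = B[:, k-1]`` is the
    full regression vector.
    """

    analyte: str
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    k: int
    W: np.ndarray  # (p, k)
    P: np.ndarray  # (p, k)
    q: np.ndarray  # (k,)
    B: np.ndarray  # (p, k) cumulative coefficient vectors

    @property
    def b(self) -> np.ndarray:
        return self.B[:, self.k - 1]

    @property
    def n_channels(self) -> int:
        return len(self.x_mean)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "analyte": self.analyte,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "k": self.k,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "B": self.B.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            analyte=d["analyte"],
            x_mean=np.asarray(d["x_mean"], float),
            x_scale=np.asarray(d["x_scale"], float),
            y_mean=float(d["y_mean"]),
            k=int(d["k"]),
            W=np.asarray(d["W"], float),
            P=np.asarray(d["P"], float),
            q=np.asarray(d["q"], float),
            B=np.asarray(d["B"], float),
        )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    *,
    scale: bool = False,
    analyte: str = "",
) -> PLSModel:
    """Fit a k-component PLS1 model by NIPALS deflation.

    Parameters
    ----------
    X : (n, p) spectra matrix, no missing values.
    y : (n,) reference values.
    k : number of latent variables, ``1 <= k <= min(n - 1, p)``.
    scale : divide each centered channel by its standard deviation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"rows(X)={n} must equal len(y)={len(y)}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be free of missing/non-finite values")
    k_cap = min(n - 1, p)
    if not 1 <= k <= k_cap:
        raise ValueError(f"k={k} out of range [1, {k_cap}] for n={n}, p={p}")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; the PLS direction is undefined")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    y_mean = float(y.mean())

    Xd = (X - x_mean) / x_scale
    yd = y - y_mean

    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    B = np.zeros((p, k))

    y_norm0 = np.linalg.norm(yd)
    for a in range(k):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm <= 1e-12 * max(y_norm0, 1e-300):
            # response variance exhausted: later components carry nothing,
            # freeze the regression vector and keep the requested k
            for rest in range(a, k):
                B[:, rest] = B[:, a - 1] if a > 0 else 0.0
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-28:
            for rest in range(a, k):
                B[:, rest] = B[:, a - 1] if a > 0 else 0.0
            break
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p_a)
        yd = yd - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        # cumulative regression vector via R = W (P' W)^-1
        R = W[:, : a + 1] @ np.linalg.inv(P[:, : a + 1].T @ W[:, : a + 1])
        B[:, a] = R @ q[: a + 1]

    return PLSModel(analyte=analyte, x_mean=x_mean, x_scale=x_scale,
                    y_mean=y_mean, k=k, W=W, P=P, q=q, B=B)


def predict(model: PLSModel, X: np.ndarray, ncomp: int | None = None) -> np.ndarray:
    """Predict with the regression vector: ``y_mean + (X - mean)/scale . b``."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_channels:
        raise ValueError(
            f"X has {X.shape[1]} channels, model expects {model.n_channels}"
        )
    k = model.k if ncomp is None else ncomp
    if not 1 <= k <= model.k:
        raise ValueError(f"ncomp={k} out of range [1, {model.k}]")
    return model.y_mean + ((X - model.x_mean) / model.x_scale) @ model.B[:, k - 1]


def _contiguous_ranges(n: int, blocks: int) -> list[tuple[int, int]]:
    base, rem = divmod(n, blocks)
    sizes = [base + 1] * rem + [base] * (blocks - rem)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(blocks)]


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    k_max: int = 10,
    blocks: int = 5,
    *,
    scale: bool = False,
    rtol: float = 0.02,
) -> int:
    """Choose the latent-variable count by inner contiguous-blocks CV.

    Computes RMSECV over ``blocks`` consecutive time blocks for each
    component count 1..k_max (capped by fold size), then returns the
    smallest k whose RMSECV is within ``rtol`` (2%) of the minimum — a
    parsimony rule that avoids chasing noise with extra components.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if n < 2 * blocks:
        raise ValueError(f"too few samples (n={n}) for {blocks} inner blocks")
    ranges = _contiguous_ranges(n, blocks)
    min_train = n - max(e - s for s, e in ranges)
    k_eff = min(k_max, min_train - 1, p)
    if k_eff < 1:
        raise ValueError("inner folds too small to fit any component")

    press = np.zeros(k_eff)
    for s, e in ranges:
        mask = np.ones(n, bool)
        mask[s:e] = False
        model = fit_pls(X[mask], y[mask], k_eff, scale=scale)
        for k in range(1, k_eff + 1):
            resid = predict(model, X[s:e], ncomp=k) - y[s:e]
            press[k - 1] += float(resid @ resid)
    rmsecv = np.sqrt(press / n)
    best = float(rmsecv.min())
    for k in range(1, k_eff + 1):
        if rmsecv[k - 1] <= best * (1 + rtol):
            return k
    return k_eff  # unreachable
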