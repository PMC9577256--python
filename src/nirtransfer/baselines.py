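"""Comparison methods: PLSR, slope/bias correction, piecewise direct standardization.

These are the classical calibration-transfer references the hybrid model
is benchmarked against. PLSR wraps the scikit-learn PLS1 implementation;
SBC is an ordinary least-squares affine correction of a master model's
predictions on transfer standards; PDS maps slave spectra into master
spectral space through per-wavelength windowed ridge regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = [
    "PlsrModel",
    "plsr_fit",
    "plsr_predict",
    "choose_plsr_components",
    "sbc_fit",
    "sbc_apply",
    "PdsTransform",
    "pds_fit",
    "pds_apply",
]


@dataclass
class PlsrModel:
    n_components: int
    _pls: PLSRegression = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._pls.predict(np.asarray(X, dtype=float)).ravel()


def plsr_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsrModel:
    """PLS1 regression (centred, SVD-based) with ``n_components`` latent vars."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_k = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}], got {n_components}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return PlsrModel(n_components=n_components, _pls=pls)


def plsr_predict(model: PlsrModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def choose_plsr_components(
    X: np.ndarray, y: np.ndarray, max_components: int = 20, folds: int = 10, seed: int = 0
) -> int:
    """Pick the component count minimising F-fold CV RMSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_k = min(max_components, X.shape[0] - 1 - X.shape[0] // folds, X.shape[1])
    folds = min(folds, X.shape[0])
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best_k, best = 1, np.inf
    for k in range(1, max_k + 1):
        sq = 0.0
        for tr, te in kf.split(X):
            m = plsr_fit(X[tr], y[tr], k)
            sq += float(np.sum((m.predict(X[te]) - y[te]) ** 2))
        rmse = np.sqrt(sq / len(y))
        if rmse < best - 1e-12:
            best, best_k = rmse, k
    return best_k


def sbc_fit(y_ref: np.ndarray, y_pred_master: np.ndarray) -> tuple[float, float]:
    """OLS of reference values on master-model predictions -> (slope, bias)."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred_master, dtype=float).ravel()
    if len(y_ref) < 2:
        raise ValueError("need at least 2 transfer standards")
    if np.ptp(y_pred) == 0:
        raise ValueError("master predictions are constant; slope undefined")
    slope, bias = np.polyfit(y_pred, y_ref, 1)
    return float(slope), float(bias)


def sbc_apply(slope: float, bias: float, y_pred: np.ndarray) -> np.ndarray:
    return slope * np.asarray(y_pred, dtype=float) + bias


@dataclass
class PdsTransform:
    """Banded map from slave to master spectral space."""

    half_width: int
    windows: list[np.ndarray]  # column indices per wavelength
    coefs: list[np.ndarray]
    intercepts: np.ndarray


def pds_fit(
    master_spectra: np.ndarray,
    slave_spectra: np.ndarray,
    half_width: int = 5,
    ridge: float = 1e-6,
) -> PdsTransform:
    """Fit PDS on paired standards measured in both domains.

    For each master wavelength j, the slave window [j-k, j+k] (clipped at
    the edges) is regressed onto master column j with a small ridge
    penalty for stability at narrow windows.
    """
    M = np.asarray(master_spectra, dtype=float)
    S = np.asarray(slave_spectra, dtype=float)
    if M.shape != S.shape:
        raise ValueError("master and slave standards must be paired (same shape)")
    n, p = M.shape
    windows, coefs = [], []
    intercepts = np.zeros(p)
    for j in range(p):
        lo, hi = max(0, j - half_width), min(p, j + half_width + 1)
        win = np.arange(lo, hi)
        A = S[:, win]
        mu = A.mean(axis=0)
        Ac = A - mu
        target = M[:, j]
        tm = target.mean()
        G = Ac.T @ Ac + ridge * np.eye(len(win))
        theta = np.linalg.solve(G, Ac.T @ (target - tm))
        windows.append(win)
        coefs.append(theta)
        intercepts[j] = tm - mu @ theta
    return PdsTransform(half_width=half_width, windows=windows, coefs=coefs, intercepts=intercepts)


def pds_apply(tf: PdsTransform, slave_spectra: np.ndarray) -> np.ndarray:
    """Map slave-domain spectra into master space."""
    S = np.asarray(slave_spectra, dtype=float)
    out = np.empty_like(S)
    for j, (win, theta) in enumerate(zip(tf.windows, tf.coefs)):
        out[:, j] = S[:, win] @ theta + tf.intercepts[j]
    return out
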