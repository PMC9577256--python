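"""RBF-kernel support vector regression with PSO hyperparameter search.

The regressor applied to bottleneck features is an epsilon-insensitive SVR
with an RBF kernel. Its three hyperparameters (penalty C, kernel width
gamma, tube width epsilon) are tuned by particle swarm optimisation in
log10 space, scored by F-fold cross-validated RMSE. Per-sample weights
(used by the boosting stage) scale each sample's slack penalty; they are
normalised to mean one before fitting so that a uniform weight vector is
exactly equivalent to an unweighted fit at the same C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = ["SvrParams", "PsoConfig", "SvrModel", "svr_fit", "cv_rmse", "pso_optimize"]


@dataclass(frozen=True)
class SvrParams:
    C: float = 10.0
    gamma: float = 0.01
    epsilon: float = 0.01
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValueError("C and gamma must be > 0, epsilon >= 0")
        if self.kernel != "rbf":
            raise ValueError("kernel is fixed to RBF")


@dataclass
class PsoConfig:
    swarm_size: int = 50
    c1: float = 1.5
    c2: float = 1.7
    max_iters: int = 50
    cv_folds: int = 10
    # log10-space search box: (low, high) per parameter
    bounds: dict = field(
        default_factory=lambda: {
            "C": (1e-2, 1e3),
            "gamma": (1e-4, 1e1),
            "epsilon": (1e-4, 1e0),
        }
    )
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    fix_epsilon: float | None = None  # set to optimise C and gamma only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        for k, (lo, hi) in self.bounds.items():
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {k} must satisfy 0 < low < high")


class SvrModel:
    """StandardScaler + weighted RBF SVR, the base learner everywhere.

    Column standardisation uses the fitting set's statistics; bottleneck
    feature magnitudes are scale-arbitrary so this keeps gamma meaningful.
    """

    def __init__(self, params: SvrParams, scale_features: bool = True):
        self.params = params
        self.scale_features = scale_features
        self._scaler: StandardScaler | None = None
        self._svr: SVR | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if np.allclose(X, X[0]):
            raise ValueError("all feature rows identical; SVR fit is degenerate")
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
            if np.any(sample_weight < 0):
                raise ValueError("sample weights must be nonnegative")
            pos = sample_weight > 0
            if not pos.any():
                raise ValueError("sample weights must not all be zero")
            # normalise by the mean positive weight: a constant weight vector
            # is then exactly an unweighted fit at the same C, and a
            # zero-weight sample behaves as if removed
            sample_weight = sample_weight / sample_weight[pos].mean()
        if self.scale_features:
            self._scaler = StandardScaler().fit(X)
            Xs = self._scaler.transform(X)
        else:
            Xs = X
        p = self.params
        self._svr = SVR(kernel="rbf", C=p.C, gamma=p.gamma, epsilon=p.epsilon)
        self._svr.fit(Xs, y, sample_weight=sample_weight)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._svr is None:
            raise RuntimeError("model not fitted")
        X = np.asarray(X, dtype=float)
        if self._scaler is not None:
            X = self._scaler.transform(X)
        return self._svr.predict(X)


def svr_fit(
    features: np.ndarray,
    y: np.ndarray,
    params: SvrParams,
    sample_weight: np.ndarray | None = None,
    scale_features: bool = True,
) -> SvrModel:
    """Fit a (possibly instance-weighted) RBF SVR and return the predictor."""
    return SvrModel(params, scale_features=scale_features).fit(features, y, sample_weight)


def cv_rmse(
    features: np.ndarray,
    y: np.ndarray,
    params: SvrParams,
    folds: int,
    seed: int,
    scale_features: bool = True,
) -> float:
    """Pooled F-fold cross-validated RMSE of an SVR at fixed parameters."""
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds > len(y):
        raise ValueError(f"cv_folds={folds} exceeds n_samples={len(y)}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq = 0.0
    for tr, te in kf.split(features):
        model = SvrModel(params, scale_features=scale_features).fit(features[tr], y[tr])
        resid = model.predict(features[te]) - y[te]
        sq += float(np.sum(resid**2))
    return float(np.sqrt(sq / len(y)))


def pso_optimize(
    features: np.ndarray,
    y: np.ndarray,
    cfg: PsoConfig | None = None,
    trace: list | None = None,
) -> SvrParams:
    """Particle swarm search for (C, gamma, epsilon) minimising CV RMSE.

    Positions live in log10 space of the bounded box; the velocity update
    is v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x) with linearly
    decaying inertia, and positions are clipped to the box. Seeded, hence
    reproducible; the global best never worsens. Pass a list as ``trace``
    to collect (iteration, params, cv_rmse) tuples.
    """
    cfg = cfg or PsoConfig()
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < cfg.cv_folds:
        raise ValueError(f"need at least cv_folds={cfg.cv_folds} samples")
    rng = np.random.default_rng(cfg.seed)

    names = ["C", "gamma", "epsilon"]
    lo = np.log10([cfg.bounds[k][0] for k in names])
    hi = np.log10([cfg.bounds[k][1] for k in names])
    dim = 3

    def to_params(pos: np.ndarray) -> SvrParams:
        vals = 10.0**pos
        eps = cfg.fix_epsilon if cfg.fix_epsilon is not None else vals[2]
        return SvrParams(C=vals[0], gamma=vals[1], epsilon=eps)

    def score(pos: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cv_rmse(features, y, to_params(pos), cfg.cv_folds, cfg.seed)

    pos = lo + (hi - lo) * rng.random((cfg.swarm_size, dim))
    vel = 0.1 * (hi - lo) * (rng.random((cfg.swarm_size, dim)) - 0.5)
    pbest = pos.copy()
    pbest_val = np.array([score(p) for p in pos])
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    for it in range(cfg.max_iters):
        w = cfg.inertia_start + (cfg.inertia_end - cfg.inertia_start) * (
            it / max(cfg.max_iters - 1, 1)
        )
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        vel = w * vel + cfg.c1 * r1 * (pbest - pos) + cfg.c2 * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(cfg.swarm_size):
            val = score(pos[i])
            if val < pbest_val[i]:
                pbest_val[i] = val
                pbest[i] = pos[i].copy()
                if val < gbest_val:
                    gbest_val = val
                    gbest = pos[i].copy()
        if trace is not None:
            trace.append((it, to_params(gbest), gbest_val))
    return to_params(gbest)
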