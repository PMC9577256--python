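"""Two-stage TrAdaBoost.R2 over bottleneck features with SVR base learners.

Instance-transfer boosting for regression: source- and target-domain
samples are pooled with one weight per instance. The outer loop runs K
steps. At each step an AdaBoost.R2 ensemble is fitted on the pooled data
(stage 2: source weights held fixed, only target weights boosted), its
target-domain error is estimated by F-fold cross-validation, and then the
source weights are geometrically down-weighted (stage 1) with a factor
beta found by binary search so that the summed target weight follows a
prescribed schedule, growing linearly from the target share n/(m+n) at
the first step to 1 at the last. The returned model is the step ensemble
with the smallest cross-validated error, which guards against negative
transfer: if down-weighting the source hurts, an earlier step wins.

Prediction uses the AdaBoost.R2 weighted median of member predictions,
members weighted by ln(1/beta_t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .svr_pso import SvrModel, SvrParams

__all__ = [
    "TransferConfig",
    "BoostState",
    "AdaBoostR2Ensemble",
    "TransferModel",
    "init_weights",
    "target_weight_fraction",
    "adjusted_error",
    "weighted_median",
    "adaboost_r2_fit",
    "stage1_update",
    "fit_two_stage",
    "predict",
]


@dataclass
class TransferConfig:
    K: int = 10  # outer steps
    N: int = 50  # inner AdaBoost.R2 iterations
    cv_folds: int = 10
    n_frozen_conv: int = 10
    loss_shape: str = "linear"  # linear | square | exponential
    strict_two_stage: bool = True  # freeze source weights inside stage 2
    cv_loss: str = "rmse"  # rmse | mse
    # fit each round on a weight-proportional bootstrap resample (the
    # classical AdaBoost.R2 formulation); False passes weights directly to
    # the base learner instead
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.loss_shape not in ("linear", "square", "exponential"):
            raise ValueError(f"unknown loss_shape {self.loss_shape!r}")


@dataclass
class BoostState:
    """Trace of one outer run: weights, betas, normalisers, errors."""

    w: np.ndarray
    beta: list[float] = field(default_factory=list)
    Z: list[float] = field(default_factory=list)
    adj_err: np.ndarray | None = None
    step_cv_error: list[float] = field(default_factory=list)
    target_fraction: list[float] = field(default_factory=list)
    w_history: list[np.ndarray] = field(default_factory=list)


def init_weights(m: int, n: int) -> np.ndarray:
    """Uniform initial distribution over m source + n target instances."""
    if m < 1 or n < 1:
        raise ValueError("need at least one source and one target instance")
    return np.full(m + n, 1.0 / (m + n))


def target_weight_fraction(m: int, n: int, t: int, K: int) -> float:
    """Scheduled summed target weight at outer step t (0-based).

    Grows linearly from the raw target share n/(m+n) at t=0 to 1.0 at
    t=K-1, so the final step trains almost purely on target instances.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0 <= t <= K - 1:
        raise ValueError(f"t must be in [0, {K - 1}]")
    share = n / (m + n)
    return share + (t / (K - 1)) * (1.0 - share)


def adjusted_error(residuals: np.ndarray, loss_shape: str = "linear") -> np.ndarray:
    """AdaBoost.R2 adjusted error in [0, 1].

    Linear: |r|/D with D the largest |residual|; square and exponential
    shapes as in AdaBoost.R2. All-zero residuals give all-zero errors
    (perfect learner).
    """
    r = np.abs(np.asarray(residuals, dtype=float))
    D = r.max() if r.size else 0.0
    if D == 0.0:
        return np.zeros_like(r)
    lin = r / D
    if loss_shape == "linear":
        return lin
    if loss_shape == "square":
        return lin**2
    if loss_shape == "exponential":
        return 1.0 - np.exp(-lin)
    raise ValueError(f"unknown loss_shape {loss_shape!r}")


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    csum = np.cumsum(weights[order])
    cut = 0.5 * weights.sum()
    idx = min(int(np.searchsorted(csum, cut)), len(values) - 1)
    return float(values[order][idx])


class AdaBoostR2Ensemble:
    """Members + log(1/beta) weights; weighted-median prediction."""

    def __init__(self, members: list[SvrModel], betas: list[float]):
        if not members:
            raise ValueError("empty ensemble")
        self.members = members
        self.betas = betas

    @property
    def member_weights(self) -> np.ndarray:
        return np.log(1.0 / np.clip(np.asarray(self.betas), 1e-300, None))

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.members], axis=1)
        w = self.member_weights
        # vectorised weighted median across members, per sample
        order = np.argsort(preds, axis=1)
        sorted_preds = np.take_along_axis(preds, order, axis=1)
        sorted_w = w[order]
        csum = np.cumsum(sorted_w, axis=1)
        cut = 0.5 * csum[:, -1:]
        pick = np.argmax(csum >= cut, axis=1)
        return sorted_preds[np.arange(preds.shape[0]), pick]


def adaboost_r2_fit(
    features: np.ndarray,
    y: np.ndarray,
    w_init: np.ndarray,
    N: int,
    base_params: SvrParams,
    loss_shape: str = "linear",
    source_mask: np.ndarray | None = None,
    state: BoostState | None = None,
    bootstrap: bool = False,
    rng: np.random.Generator | None = None,
) -> AdaBoostR2Ensemble:
    """AdaBoost.R2 with weighted SVR base learners.

    The adjusted error uses one shared denominator (the largest absolute
    residual over the whole pool) and the weighted error rate sums over
    every instance. When ``source_mask`` is given (stage-2 of the
    two-stage scheme) only target-instance weights are updated, and the
    target block is renormalised to keep its summed weight — hence the
    stage-1 schedule — constant; source weights stay fixed. Stops early
    if the weighted error rate reaches 0.5 or a learner is perfect.

    With ``bootstrap=True`` (the classical formulation, and the mode the
    transfer pipeline defaults to) each round fits an unweighted base
    learner on a weight-proportional bootstrap resample; otherwise the
    weights are passed to the base learner directly, which makes a
    1-round ensemble identical to a single weighted fit.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(w_init, dtype=float).copy()
    if w.min() < 0:
        raise ValueError("weights must be nonnegative")
    w = w / w.sum()
    tgt = (
        ~np.asarray(source_mask, dtype=bool)
        if source_mask is not None
        else np.ones(len(y), dtype=bool)
    )

    if bootstrap and rng is None:
        rng = np.random.default_rng(0)

    members: list[SvrModel] = []
    betas: list[float] = []
    for _it in range(N):
        if bootstrap:
            idx = rng.choice(len(y), size=len(y), p=w)
            model = SvrModel(base_params).fit(X[idx], y[idx])
        else:
            model = SvrModel(base_params).fit(X, y, sample_weight=w)
        resid = model.predict(X) - y
        e = adjusted_error(resid, loss_shape)
        eps = float(np.dot(w, e))
        if e.max() == 0.0:
            # perfect learner dominates; stop boosting
            members.append(model)
            betas.append(1e-12)
            break
        if eps >= 0.5:
            if not members:
                warnings.warn(
                    "first AdaBoost.R2 learner has weighted error >= 0.5; "
                    "returning a single-member ensemble",
                    stacklevel=2,
                )
                members.append(model)
                # cap just below 1 so the member weight ln(1/beta) stays positive
                betas.append(min(eps / (1.0 - eps), 1.0 - 1e-12) if eps < 1.0 else 1.0 - 1e-12)
            break
        beta = eps / (1.0 - eps)
        members.append(model)
        betas.append(beta)
        tgt_total = w[tgt].sum()
        upd = w[tgt] * beta ** (1.0 - e[tgt])
        # keep the target block's total weight constant (source frozen)
        w[tgt] = upd * (tgt_total / upd.sum())
        w = w / w.sum()
        if state is not None:
            state.beta.append(beta)
            state.Z.append(float(upd.sum() / tgt_total))
            state.adj_err = e
            state.w_history.append(w.copy())
    if not members:  # N learners all degenerate without appending
        model = SvrModel(base_params).fit(X, y, sample_weight=w)
        members.append(model)
        betas.append(1.0 - 1e-12)
    return AdaBoostR2Ensemble(members, betas)


def stage1_update(
    w: np.ndarray,
    source_adj_err: np.ndarray,
    target_fraction: float,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Down-weight source instances to hit a prescribed target share.

    Source weights become w_i * beta**e_i (target untouched before the
    final renormalisation); beta in (0, 1] is found by binary search so
    that the renormalised summed target weight equals ``target_fraction``
    within ``tol``. If the current share already meets or exceeds the
    request, beta = 1 is returned (source is never up-weighted).
    """
    w = np.asarray(w, dtype=float)
    e = np.asarray(source_adj_err, dtype=float)
    m = len(e)
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    w_src, w_tgt = w[:m], w[m:]
    tgt_total = w_tgt.sum()

    def frac(beta: float) -> float:
        s = np.sum(w_src * beta**e)
        return tgt_total / (s + tgt_total)

    if frac(1.0) >= target_fraction - tol:
        if frac(1.0) > target_fraction + tol:
            warnings.warn(
                "requested target fraction below current share; beta=1 (no "
                "source up-weighting)",
                stacklevel=2,
            )
        return w / w.sum(), 1.0

    lo_lim = np.sum(w_src * (e == 0.0))
    max_frac = tgt_total / (lo_lim + tgt_total) if (lo_lim + tgt_total) > 0 else 1.0
    if target_fraction > max_frac + tol:
        warnings.warn(
            "target fraction unreachable (zero-error source instances); "
            "using smallest attainable beta",
            stacklevel=2,
        )
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target_fraction:
            hi = mid  # need more down-weighting
        else:
            lo = mid
        if hi - lo < 1e-16:
            break
    beta = 0.5 * (lo + hi)
    new = w.copy()
    new[:m] = w_src * beta**e
    return new / new.sum(), float(beta)


@dataclass
class TransferModel:
    """Per-step ensembles, their CV errors, and the argmin selection."""

    ensembles: list[AdaBoostR2Ensemble]
    step_cv_error: list[float]
    selected: int
    state: BoostState

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.ensembles[self.selected].predict(X)


def _target_cv_error(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    m: int,
    cfg: TransferConfig,
    base_params: SvrParams,
    seed: int,
) -> float:
    """F-fold CV error on target instances of the stage-2 ensemble."""
    n = len(y) - m
    folds = min(cfg.cv_folds, n)
    if folds < cfg.cv_folds:
        warnings.warn(
            f"only {n} target samples; reducing CV folds to {folds}", stacklevel=2
        )
    if folds < 2:
        return float("nan")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    tgt_idx = np.arange(m, len(y))
    src_idx = np.arange(m)
    sq = 0.0
    for fold, (tr_t, te_t) in enumerate(kf.split(tgt_idx)):
        keep = np.concatenate([src_idx, tgt_idx[tr_t]])
        mask = np.zeros(len(keep), dtype=bool)
        mask[: len(src_idx)] = True
        ens = adaboost_r2_fit(
            X[keep],
            y[keep],
            w[keep],
            cfg.N,
            base_params,
            loss_shape=cfg.loss_shape,
            source_mask=mask if cfg.strict_two_stage else None,
            bootstrap=cfg.bootstrap,
            rng=np.random.default_rng([abs(seed) + 1, fold]),
        )
        resid = ens.predict(X[tgt_idx[te_t]]) - y[tgt_idx[te_t]]
        sq += float(np.sum(resid**2))
    mse = sq / n
    return float(np.sqrt(mse)) if cfg.cv_loss == "rmse" else float(mse)


def fit_two_stage(
    source_feats: np.ndarray,
    ys: np.ndarray,
    target_feats: np.ndarray,
    yt: np.ndarray,
    cfg: TransferConfig,
    base_params: SvrParams,
) -> TransferModel:
    """The full two-stage procedure; returns the argmin-CV step's ensemble."""
    Xs = np.asarray(source_feats, dtype=float)
    Xt = np.asarray(target_feats, dtype=float)
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target feature dimensionality differ")
    ys = np.asarray(ys, dtype=float).ravel()
    yt = np.asarray(yt, dtype=float).ravel()
    m, n = len(ys), len(yt)
    X = np.vstack([Xs, Xt])
    y = np.concatenate([ys, yt])
    src_mask = np.zeros(m + n, dtype=bool)
    src_mask[:m] = True

    w = init_weights(m, n)
    state = BoostState(w=w.copy())
    ensembles: list[AdaBoostR2Ensemble] = []
    errors: list[float] = []
    for t in range(cfg.K):
        ens = adaboost_r2_fit(
            X,
            y,
            w,
            cfg.N,
            base_params,
            loss_shape=cfg.loss_shape,
            source_mask=src_mask if cfg.strict_two_stage else None,
            bootstrap=cfg.bootstrap,
            rng=np.random.default_rng([abs(cfg.seed), t]),
        )
        ensembles.append(ens)
        err = _target_cv_error(X, y, w, m, cfg, base_params, seed=cfg.seed + t)
        errors.append(err)
        state.step_cv_error.append(err)
        state.target_fraction.append(float(w[m:].sum()))
        if t < cfg.K - 1:
            frac = target_weight_fraction(m, n, t + 1, cfg.K)
            base = SvrModel(base_params).fit(X, y, sample_weight=w)
            resid = base.predict(X) - y
            e_all = adjusted_error(resid, cfg.loss_shape)
            w, beta = stage1_update(w, e_all[:m], frac)
            state.beta.append(beta)
    state.w = w
    finite = [e for e in errors if np.isfinite(e)]
    if finite:
        selected = int(np.nanargmin(errors))  # ties -> smallest t
    else:
        selected = 0
    return TransferModel(
        ensembles=ensembles, step_cv_error=errors, selected=selected, state=state
    )


def predict(model: TransferModel, features: np.ndarray) -> np.ndarray:
    """Weighted-median prediction of the selected step's ensemble."""
    return model.predict(np.asarray(features, dtype=float))
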