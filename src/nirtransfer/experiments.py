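"""Experiment protocols: M sweep, method comparison, N sweep.

Each runner takes a source-domain and a target-domain
:class:`~nirtransfer.core.SpectralDataset` sharing one wavelength grid,
preprocesses them (SGS + SNV), builds deterministic SPXY splits, fits the
requested methods, and returns a tidy :class:`pandas.DataFrame`. Repeats
re-train the stochastic components (network initialisation, PSO) with
shifted seeds on the same deterministic splits, mirroring the
average-of-repeats protocol used for reporting.

Two sizing profiles are provided: :func:`full_profile` uses the
full-scale architecture and iteration counts; :func:`test_profile`
shrinks the network, the boosting depth and the CV folds so the entire
protocol runs in minutes on one CPU core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import (
    choose_plsr_components,
    pds_apply,
    pds_fit,
    plsr_fit,
    sbc_apply,
    sbc_fit,
)
from .core import Metrics, SpectralDataset, regression_metrics
from .preprocess import PreprocessConfig, apply_pipeline
from .resnet1d import ResnetConfig, TrainConfig, bottleneck_features, build_backbone, fine_tune, train
from .sampling import spxy_split
from .svr_pso import PsoConfig, SvrParams, pso_optimize, svr_fit
from .transfer import TransferConfig, fit_two_stage

__all__ = [
    "Profile",
    "ExperimentConfig",
    "test_profile",
    "full_profile",
    "run_m_sweep",
    "run_method_comparison",
    "run_n_sweep",
    "ALL_METHODS",
]

ALL_METHODS = (
    "PLSR",
    "SVR",
    "PLSR+SBC",
    "PLSR+PDS",
    "SVR+PDS",
    "Resnet1D-TL",
    "Resnet1D-SVR",
    "Resnet1D-SVR-TrAdaBoost.R2",
)


@dataclass
class Profile:
    """Bundled model/optimisation settings for one experiment scale."""

    resnet: ResnetConfig
    train: TrainConfig
    transfer: TransferConfig
    svr_params: SvrParams | None = None  # fixed params; None -> run PSO
    pso: PsoConfig | None = None
    pds_half_width: int = 5
    plsr_max_components: int = 15
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)


def full_profile(seed: int = 0) -> Profile:
    """Full-scale settings (slow; hours on one CPU)."""
    return Profile(
        resnet=ResnetConfig(),
        train=TrainConfig(seed=seed),
        transfer=TransferConfig(seed=seed),
        svr_params=None,
        pso=PsoConfig(seed=seed),
    )


def test_profile(seed: int = 0) -> Profile:
    """Desk-scale settings: tiny network, shallow boosting, fixed SVR params."""
    return Profile(
        resnet=ResnetConfig(
            n_stages=2,
            basic_blocks_per_stage=2,
            channels=(8, 16),
            fc_sizes=(32, 16),
            downsample_stride_per_stage=(2, 2),
        ),
        train=TrainConfig(
            batch_size=5,
            initial_lr=2e-3,
            lr_patience=6,
            early_stop_patience=15,
            max_epochs=120,
            val_fraction=0.15,
            seed=seed,
        ),
        # keep 6 of the 8 convolutions frozen during fine-tuning: with a
        # shallow backbone the last block suffices for adaptation, and the
        # shared frozen trunk keeps source/target bottleneck spaces aligned
        transfer=TransferConfig(K=3, N=10, cv_folds=3, n_frozen_conv=6, seed=seed),
        svr_params=None,
        pso=PsoConfig(swarm_size=6, max_iters=5, cv_folds=3, seed=seed),
    )


@dataclass
class ExperimentConfig:
    m_values: tuple = (20, 40, 60, 80, 100, 120, 140)
    n_values: tuple = (5, 10, 20, 50, 80)
    repeats: int = 5
    pred_size: int = 30
    methods: tuple = (
        "PLSR+SBC",
        "Resnet1D-TL",
        "Resnet1D-SVR",
        "Resnet1D-SVR-TrAdaBoost.R2",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}; choose from {ALL_METHODS}")


# ---------------------------------------------------------------------------
# shared per-repeat computation
# ---------------------------------------------------------------------------


class _Context:
    """Preprocessed data, splits, and lazily trained shared models."""

    def __init__(
        self,
        source: SpectralDataset,
        target: SpectralDataset,
        profile: Profile,
        pred_size: int,
        seed: int,
    ):
        if not np.array_equal(source.wavelengths_nm, target.wavelengths_nm):
            raise ValueError("source and target must share one wavelength grid")
        self.profile = profile
        self.seed = seed
        self.Xs = apply_pipeline(source.absorbance, profile.preprocess)
        self.Xt = apply_pipeline(target.absorbance, profile.preprocess)
        self.ys = source.density
        self.yt = target.density

        ns, nt = len(self.ys), len(self.yt)
        s_split = spxy_split(self.Xs, self.ys, ns - pred_size)
        t_split = spxy_split(self.Xt, self.yt, nt - pred_size)
        self.s_cal = np.array(s_split.cal_idx)
        self.s_pred = np.array(s_split.pred_idx)
        self.t_pool = np.array(t_split.cal_idx)  # target calibration pool
        self.t_pred = np.array(t_split.pred_idx)

        self._source_model = None
        self._target_models: dict[int, object] = {}
        self._svr_params_cache: dict[str, SvrParams] = {}

    # -- splits ------------------------------------------------------------

    def target_cal_idx(self, M: int) -> np.ndarray:
        """SPXY-select M calibration samples from the target pool."""
        if M >= len(self.t_pool):
            return self.t_pool
        sub = spxy_split(self.Xt[self.t_pool], self.yt[self.t_pool], M)
        return self.t_pool[np.array(sub.cal_idx)]

    # -- shared models -----------------------------------------------------

    @property
    def source_model(self):
        if self._source_model is None:
            prof = self.profile
            model = build_backbone(self.Xs.shape[1], prof.resnet, seed=self.seed)
            train(
                model,
                self.Xs[self.s_cal],
                self.ys[self.s_cal],
                replace(prof.train, seed=self.seed),
            )
            self._source_model = model
        return self._source_model

    def target_model(self, M: int):
        if M not in self._target_models:
            prof = self.profile
            cal = self.target_cal_idx(M)
            model = build_backbone(self.Xt.shape[1], prof.resnet, seed=self.seed + 1)
            fine_tune(
                model,
                self.source_model.get_weights(),
                prof.transfer.n_frozen_conv,
                self.Xt[cal],
                self.yt[cal],
                replace(prof.train, seed=self.seed + 1 + M),
            )
            self._target_models[M] = model
        return self._target_models[M]

    def svr_params_for(self, key: str, feats: np.ndarray, y: np.ndarray) -> SvrParams:
        if self.profile.svr_params is not None:
            return self.profile.svr_params
        if key not in self._svr_params_cache:
            cfg = replace(self.profile.pso, seed=self.seed)
            self._svr_params_cache[key] = pso_optimize(feats, y, cfg)
        return self._svr_params_cache[key]


def _evaluate_method(
    method: str, ctx: _Context, M: int, N: int | None = None
) -> dict[str, Metrics]:
    """Fit one method and return {'source': Metrics, 'target': Metrics}."""
    prof = ctx.profile
    Xs, ys, Xt, yt = ctx.Xs, ctx.ys, ctx.Xt, ctx.yt
    s_cal, s_pred, t_pred = ctx.s_cal, ctx.s_pred, ctx.t_pred
    t_cal = ctx.target_cal_idx(M)

    def both(pred_s, pred_t):
        return {
            "source": regression_metrics(ys[s_pred], pred_s),
            "target": regression_metrics(yt[t_pred], pred_t),
        }

    if method == "PLSR":
        ks = choose_plsr_components(Xs[s_cal], ys[s_cal], prof.plsr_max_components, seed=ctx.seed)
        kt = choose_plsr_components(Xt[t_cal], yt[t_cal], prof.plsr_max_components, seed=ctx.seed)
        ms = plsr_fit(Xs[s_cal], ys[s_cal], ks)
        mt = plsr_fit(Xt[t_cal], yt[t_cal], kt)
        return both(ms.predict(Xs[s_pred]), mt.predict(Xt[t_pred]))

    if method == "SVR":
        ps = ctx.svr_params_for("svr_src", Xs[s_cal], ys[s_cal])
        pt = ctx.svr_params_for(f"svr_tgt_{M}", Xt[t_cal], yt[t_cal])
        ms = svr_fit(Xs[s_cal], ys[s_cal], ps)
        mt = svr_fit(Xt[t_cal], yt[t_cal], pt)
        return both(ms.predict(Xs[s_pred]), mt.predict(Xt[t_pred]))

    if method in ("PLSR+SBC", "PLSR+PDS", "SVR+PDS"):
        if method.startswith("PLSR"):
            k = choose_plsr_components(Xs[s_cal], ys[s_cal], prof.plsr_max_components, seed=ctx.seed)
            master = plsr_fit(Xs[s_cal], ys[s_cal], k)
        else:
            ps = ctx.svr_params_for("svr_src", Xs[s_cal], ys[s_cal])
            master = svr_fit(Xs[s_cal], ys[s_cal], ps)
        pred_s = master.predict(Xs[s_pred])
        if method == "PLSR+SBC":
            slope, bias = sbc_fit(yt[t_cal], master.predict(Xt[t_cal]))
            pred_t = sbc_apply(slope, bias, master.predict(Xt[t_pred]))
        else:
            # transfer standards: the target-cal specimens in both domains
            tf = pds_fit(Xs[t_cal], Xt[t_cal], prof.pds_half_width)
            pred_t = master.predict(pds_apply(tf, Xt[t_pred]))
        return both(pred_s, pred_t)

    if method == "Resnet1D-TL":
        src, tgt = ctx.source_model, ctx.target_model(M)
        return both(src.predict(Xs[s_pred]), tgt.predict(Xt[t_pred]))

    if method == "Resnet1D-SVR":
        src, tgt = ctx.source_model, ctx.target_model(M)
        fs_cal = bottleneck_features(src, Xs[s_cal])
        ft_cal = bottleneck_features(tgt, Xt[t_cal])
        ps = ctx.svr_params_for("bneck_src", fs_cal, ys[s_cal])
        pt = ctx.svr_params_for(f"bneck_tgt_{M}", ft_cal, yt[t_cal])
        ms = svr_fit(fs_cal, ys[s_cal], ps)
        mt = svr_fit(ft_cal, yt[t_cal], pt)
        return both(
            ms.predict(bottleneck_features(src, Xs[s_pred])),
            mt.predict(bottleneck_features(tgt, Xt[t_pred])),
        )

    if method == "Resnet1D-SVR-TrAdaBoost.R2":
        src, tgt = ctx.source_model, ctx.target_model(M)
        fs_cal = bottleneck_features(src, Xs[s_cal])
        ft_cal = bottleneck_features(tgt, Xt[t_cal])
        # tune on the pooled aggregate the boosted regressor will fit
        ps = ctx.svr_params_for(
            f"bneck_pool_{M}",
            np.vstack([fs_cal, ft_cal]),
            np.concatenate([ys[s_cal], yt[t_cal]]),
        )
        tcfg = ctx.profile.transfer
        if N is not None:
            tcfg = replace(tcfg, N=N)
        tcfg = replace(tcfg, seed=ctx.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_two_stage(fs_cal, ys[s_cal], ft_cal, yt[t_cal], tcfg, ps)
        return both(
            model.predict(bottleneck_features(src, Xs[s_pred])),
            model.predict(bottleneck_features(tgt, Xt[t_pred])),
        )

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def run_m_sweep(
    cfg: ExperimentConfig,
    source: SpectralDataset,
    target: SpectralDataset,
    profile: Profile | None = None,
) -> pd.DataFrame:
    """Target-domain performance vs calibration-set size M.

    Returns tidy rows (method, M, repeat, r2, rmse, mae) measured on the
    held-out target prediction set.
    """
    profile = profile or test_profile(cfg.seed)
    rows = []
    for rep in range(cfg.repeats):
        ctx = _Context(source, target, profile, cfg.pred_size, seed=cfg.seed + 1000 * rep)
        for M in cfg.m_values:
            if M >= len(ctx.t_pool):
                warnings.warn(f"M={M} exceeds target pool; skipped", stacklevel=2)
                continue
            for method in cfg.methods:
                res = _evaluate_method(method, ctx, M)
                rows.append(
                    {"method": method, "M": M, "repeat": rep, **res["target"].to_dict()}
                )
    return pd.DataFrame(rows)


def run_method_comparison(
    cfg: ExperimentConfig,
    source: SpectralDataset,
    target: SpectralDataset,
    profile: Profile | None = None,
    cal_fraction: float = 0.7,
) -> pd.DataFrame:
    """Every requested method on both domains' held-out prediction sets.

    The split takes ``cal_fraction`` of each domain for calibration (SPXY);
    rows are (method, domain, repeat, r2, rmse, mae).
    """
    profile = profile or test_profile(cfg.seed)
    nt = target.n_samples
    pred_size = nt - int(round(cal_fraction * nt))
    rows = []
    for rep in range(cfg.repeats):
        ctx = _Context(source, target, profile, pred_size, seed=cfg.seed + 1000 * rep)
        M = len(ctx.t_pool)
        for method in cfg.methods:
            res = _evaluate_method(method, ctx, M)
            for domain in ("source", "target"):
                rows.append(
                    {
                        "method": method,
                        "domain": domain,
                        "repeat": rep,
                        **res[domain].to_dict(),
                    }
                )
    return pd.DataFrame(rows)


def run_n_sweep(
    cfg: ExperimentConfig,
    source: SpectralDataset,
    target: SpectralDataset,
    profile: Profile | None = None,
) -> pd.DataFrame:
    """Hybrid-model performance over the (N, M) grid of boosting depths."""
    profile = profile or test_profile(cfg.seed)
    rows = []
    for rep in range(cfg.repeats):
        ctx = _Context(source, target, profile, cfg.pred_size, seed=cfg.seed + 1000 * rep)
        for M in cfg.m_values:
            if M >= len(ctx.t_pool):
                warnings.warn(f"M={M} exceeds target pool; skipped", stacklevel=2)
                continue
            for N in cfg.n_values:
                res = _evaluate_method("Resnet1D-SVR-TrAdaBoost.R2", ctx, M, N=N)
                rows.append(
                    {"N": N, "M": M, "repeat": rep, **res["target"].to_dict()}
                )
    return pd.DataFrame(rows)
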