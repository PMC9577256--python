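"""Spectral preprocessing and sample screening.

The pipeline applied before any modelling is 21-point Savitzky-Golay
smoothing followed by the standard normal variate (SNV) transform; the
combination suppresses instrument noise and multiplicative scatter from
surface roughness / particle size. A synchronous 2-D correlation map is
provided as a diagnostic of inter-wavelength redundancy, and an outlier
screen combines leverage in a PLS latent space with externally studentized
residuals; flags from several moisture groups are merged by serial number
so all groups stay aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import t as student_t
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PreprocessConfig",
    "OutlierReport",
    "savitzky_golay",
    "snv",
    "apply_pipeline",
    "sync_2d_correlation",
    "flag_outliers",
    "union_outliers",
]


@dataclass
class PreprocessConfig:
    sg_window: int = 21
    sg_polyorder: int = 2
    step_order: tuple[str, ...] = ("SGS", "SNV")

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError(
                f"sg_window must be odd and > polyorder "
                f"(got window={self.sg_window}, polyorder={self.sg_polyorder})"
            )
        bad = set(self.step_order) - {"SGS", "SNV"}
        if bad:
            raise ValueError(f"unknown preprocessing steps: {sorted(bad)}")


@dataclass
class OutlierReport:
    """Per-sample influence diagnostics from one moisture group."""

    sample_ids: list[str]
    leverage: np.ndarray
    studentized_residual: np.ndarray
    leverage_threshold: float
    t_critical: float
    flagged_ids: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        flagged = set(self.flagged_ids)
        return pd.DataFrame(
            {
                "id": self.sample_ids,
                "leverage": self.leverage,
                "studentized_residual": self.studentized_residual,
                "flagged": [s in flagged for s in self.sample_ids],
            }
        )


def savitzky_golay(spectra: np.ndarray, window: int = 21, polyorder: int = 2) -> np.ndarray:
    """Row-wise Savitzky-Golay smoothing.

    Edge points use the polynomial fitted to the terminal window
    (``mode='interp'``), so the output has the same shape as the input and
    any row that is itself a polynomial of degree <= ``polyorder`` is
    reproduced exactly.
    """
    spectra = np.asarray(spectra, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"window must be odd and > polyorder (got {window}, {polyorder})"
        )
    if spectra.shape[-1] < window:
        raise ValueError(
            f"need at least {window} wavelengths, got {spectra.shape[-1]}"
        )
    return savgol_filter(spectra, window_length=window, polyorder=polyorder, axis=-1, mode="interp")


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum.

    Each row is centred by its mean and divided by its sample standard
    deviation (n-1 divisor). Idempotent up to floating point.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    sd = spectra.std(axis=1, ddof=1)
    const = np.where(sd == 0)[0]
    if const.size:
        raise ValueError(f"constant spectrum at row(s) {const.tolist()}: SNV undefined")
    return (spectra - spectra.mean(axis=1, keepdims=True)) / sd[:, None]


def apply_pipeline(spectra: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Apply the configured steps in order (default SGS then SNV)."""
    cfg = cfg or PreprocessConfig()
    out = np.asarray(spectra, dtype=float)
    for step in cfg.step_order:
        if step == "SGS":
            out = savitzky_golay(out, cfg.sg_window, cfg.sg_polyorder)
        elif step == "SNV":
            out = snv(out)
    return out


def sync_2d_correlation(spectra: np.ndarray) -> np.ndarray:
    """Synchronous 2-D correlation map over samples.

    Entry (j, k) is the Pearson correlation, across samples, between
    absorbance at wavelength j and wavelength k. Constant wavelength
    columns get zeroed rows/columns (with a warning) rather than NaN.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation map")
    sd = spectra.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant wavelength column(s); correlations set to 0",
            stacklevel=2,
        )
    centred = spectra - spectra.mean(axis=0)
    denom = np.where(const, 1.0, sd)
    z = centred / denom
    r = (z.T @ z) / spectra.shape[0]
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    ok = ~const
    d = np.arange(spectra.shape[1])
    r[d[ok], d[ok]] = 1.0
    return r


def flag_outliers(
    spectra: np.ndarray,
    y: np.ndarray,
    n_latent: int = 10,
    alpha: float = 0.05,
    sample_ids: list[str] | None = None,
    leverage_threshold: float | None = None,
) -> OutlierReport:
    """Leverage + externally studentized residual screen.

    A PLS regression with ``n_latent`` components is fitted; leverage is
    computed in the latent-score space (with intercept), residuals are
    externally studentized, and a sample is flagged when either its
    leverage exceeds the threshold (default 3(k+1)/n) or |t| exceeds the
    two-sided Student-t critical value at ``alpha``.
    """
    X = np.asarray(spectra, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n_latent >= n - 1:
        raise ValueError(f"n_latent={n_latent} too large for n={n} samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]

    pls = PLSRegression(n_components=n_latent, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, y)
    scores = pls.x_scores_
    yhat = pls.predict(X).ravel()

    # hat matrix in (intercept + scores) space
    T1 = np.column_stack([np.ones(n), scores])
    H = T1 @ np.linalg.pinv(T1.T @ T1) @ T1.T
    h = np.clip(np.diag(H), 0.0, 1.0)

    p = n_latent + 1  # parameters incl. intercept
    resid = y - yhat
    sse = float(np.sum(resid**2))
    df = n - p - 1
    if df < 1:
        raise ValueError("too few samples for studentized residuals")
    denom_h = np.clip(1.0 - h, 1e-12, None)
    s2_loo = np.clip((sse - resid**2 / denom_h) / df, 1e-300, None)
    t_i = resid / np.sqrt(s2_loo * denom_h)

    h_thresh = (
        leverage_threshold
        if leverage_threshold is not None
        else 3.0 * p / n
    )
    t_crit = float(student_t.ppf(1.0 - alpha / 2.0, df))
    flagged = [
        sample_ids[i]
        for i in range(n)
        if h[i] > h_thresh or abs(t_i[i]) > t_crit
    ]
    return OutlierReport(
        sample_ids=list(sample_ids),
        leverage=h,
        studentized_residual=t_i,
        leverage_threshold=h_thresh,
        t_critical=t_crit,
        flagged_ids=flagged,
    )


def union_outliers(reports: list[OutlierReport]) -> set[str]:
    """Merge flags from several groups into one id set.

    Removal by serial number is then applied to every group so the groups
    stay aligned sample-for-sample.
    """
    if not reports:
        return set()
    universe = set(reports[0].sample_ids)
    for rep in reports[1:]:
        if set(rep.sample_ids) != universe:
            raise ValueError("outlier reports cover different sample-id universes")
    out: set[str] = set()
    for rep in reports:
        out |= set(rep.flagged_ids)
    return out
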