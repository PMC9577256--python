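"""Synthetic domain-shifted Vis-NIR spectra with ground-truth density.

Emulates the structure of wood reflectance spectra measured at several
moisture contents: a handful of overlapping Gaussian absorption bands
(defaults near known O-H/C-H overtone regions, e.g. 1450 and 1940 nm)
whose amplitudes are affinely coupled to the density label, a smooth
instrument drift, per-sample multiplicative/additive scatter, and iid
noise. Raising the moisture content adds a baseline offset, shifts band
centres slightly, and broadens the bands — the overall spectral shape is
preserved, so source and target domains look alike but are systematically
displaced.

The same seed produces the same density labels at every moisture level
(paired samples: one set of specimens measured repeatedly), while the
noise draw is independent per level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpectralDataset

__all__ = ["SyntheticConfig", "generate", "generate_mixed_target"]


@dataclass
class SyntheticConfig:
    n_samples: int = 181
    wavelength_start: float = 350.0
    wavelength_stop: float = 2500.0
    n_points: int = 2151
    # (center nm, width nm, base amplitude AU)
    bands: tuple = (
        (480.0, 60.0, 0.10),
        (1200.0, 70.0, 0.22),
        (1450.0, 55.0, 0.40),
        (1730.0, 45.0, 0.18),
        (1940.0, 65.0, 0.45),
        (2100.0, 70.0, 0.28),
        (2270.0, 55.0, 0.20),
    )
    density_range: tuple[float, float] = (0.4, 0.8)
    # AU of band amplitude per g/cm^3 deviation from the range midpoint
    density_coupling: tuple = (0.05, 0.45, 0.25, 0.40, 0.15, 0.30, 0.35)
    moisture_levels: tuple = (10.0, 30.0, 50.0, 70.0)
    baseline_offset_per_moisture: float = 0.0015  # AU per % above the first level
    peak_shift_per_moisture: float = 0.04  # nm per %
    peak_broaden_per_moisture: float = 0.0015  # relative width per %
    # water O-H bands swell with moisture (relative gain per % above the
    # first level); indices refer to entries of ``bands``
    water_band_indices: tuple = (2, 4)  # 1450 and 1940 nm by default
    water_gain_per_moisture: float = 0.008
    drift_amplitude: float = 0.05  # smooth instrument drift, AU
    # specimen chemistry unrelated to density (extractives, ring structure):
    # per-band amplitude jitter tied to the specimen, shared across moistures
    amplitude_noise_sd: float = 0.05
    scatter_mult_sd: float = 0.02  # per-sample multiplicative scatter
    scatter_add_sd: float = 0.01  # per-sample additive offset, AU
    noise_sd: float = 0.003  # iid noise, AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 50:
            raise ValueError("n_points must be >= 50")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(set(self.moisture_levels)) != len(self.moisture_levels):
            raise ValueError("moisture levels must be distinct")
        if len(self.density_coupling) != len(self.bands):
            raise ValueError("density_coupling must have one coefficient per band")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_stop, self.n_points)


def _densities(cfg: SyntheticConfig) -> np.ndarray:
    """Density labels depend on the seed only -> paired across moistures."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.density_range
    return rng.uniform(lo, hi, size=cfg.n_samples)


def generate(cfg: SyntheticConfig, moisture: float) -> SpectralDataset:
    """One moisture-content group of spectra with paired density labels."""
    if moisture not in cfg.moisture_levels:
        raise ValueError(
            f"moisture {moisture} not in configured levels {cfg.moisture_levels}"
        )
    wl = cfg.grid
    rho = _densities(cfg)
    mid = 0.5 * (cfg.density_range[0] + cfg.density_range[1])
    delta_m = moisture - cfg.moisture_levels[0]

    shift = cfg.peak_shift_per_moisture * delta_m
    broaden = 1.0 + cfg.peak_broaden_per_moisture * delta_m
    baseline = cfg.baseline_offset_per_moisture * moisture

    u = (wl - cfg.wavelength_start) / (cfg.wavelength_stop - cfg.wavelength_start)
    drift = cfg.drift_amplitude * (0.5 * u + u**2)

    # nuisance chemistry: paired across moistures like the density labels
    jitter_rng = np.random.default_rng([cfg.seed, 555])
    jitter = cfg.amplitude_noise_sd * jitter_rng.standard_normal(
        (cfg.n_samples, len(cfg.bands))
    )

    spectra = np.zeros((cfg.n_samples, cfg.n_points))
    for bi, ((center, width, amp0), coup) in enumerate(
        zip(cfg.bands, cfg.density_coupling)
    ):
        amp = amp0 + coup * (rho - mid) + jitter[:, bi]  # (n_samples,)
        if bi in cfg.water_band_indices:
            amp = amp * (1.0 + cfg.water_gain_per_moisture * delta_m)
        c = center + shift
        wdt = width * broaden
        profile = np.exp(-0.5 * ((wl - c) / wdt) ** 2)  # (n_points,)
        spectra += amp[:, None] * profile[None, :]
    spectra += drift[None, :] + baseline

    # noise / scatter rng keyed on (seed, moisture) -> independent per level
    rng = np.random.default_rng([cfg.seed, int(round(moisture * 1000))])
    if cfg.scatter_mult_sd > 0:
        spectra *= 1.0 + cfg.scatter_mult_sd * rng.standard_normal(cfg.n_samples)[:, None]
    if cfg.scatter_add_sd > 0:
        spectra += cfg.scatter_add_sd * rng.standard_normal(cfg.n_samples)[:, None]
    if cfg.noise_sd > 0:
        spectra += cfg.noise_sd * rng.standard_normal(spectra.shape)

    ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    return SpectralDataset(
        sample_ids=ids,
        wavelengths_nm=wl,
        absorbance=spectra,
        density=rho,
        moisture_pct=float(moisture),
    )


def generate_mixed_target(cfg: SyntheticConfig, per_level: int) -> SpectralDataset:
    """Mixed-moisture target set: ``per_level`` samples from each non-source level.

    Samples are drawn disjointly (by specimen) from the paired pool, so a
    specimen appears at one moisture level only; the per-sample moisture
    tag records which. Requires ``n_samples >= per_level * (#levels - 1)``.
    """
    if per_level < 1:
        raise ValueError("per_level must be >= 1")
    levels = cfg.moisture_levels[1:]
    need = per_level * len(levels)
    if cfg.n_samples < need:
        raise ValueError(
            f"pool of {cfg.n_samples} specimens too small for {need} mixed draws"
        )
    rng = np.random.default_rng([cfg.seed, 987654321])
    perm = rng.permutation(cfg.n_samples)
    parts = []
    for li, lvl in enumerate(levels):
        ds = generate(cfg, lvl)
        take = perm[li * per_level : (li + 1) * per_level]
        parts.append(ds.subset(sorted(take)))
    return SpectralDataset(
        sample_ids=[s for p in parts for s in p.sample_ids],
        wavelengths_nm=cfg.grid,
        absorbance=np.vstack([p.absorbance for p in parts]),
        density=np.concatenate([p.density for p in parts]),
        moisture_pct=np.concatenate([p.moisture_pct for p in parts]),
    )
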