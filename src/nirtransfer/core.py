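"""Core containers, spectral-table I/O, and regression metrics.

A :class:`SpectralDataset` holds one moisture-content group of Vis-NIR
measurements: a shared wavelength grid, an absorbance matrix, the air-dry
density labels (g/cm^3), and the moisture-content tag (%) of each sample.
All downstream modules (preprocessing, sample selection, modelling) operate
on this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "Metrics",
    "read_dataset",
    "write_dataset",
    "regression_metrics",
]


class DatasetFormatError(ValueError):
    """Raised when a spectral table violates the expected layout."""


@dataclass
class SpectralDataset:
    """One group of spectra on a common wavelength grid.

    Parameters
    ----------
    sample_ids : sequence of str
        Opaque per-sample labels (serial numbers in a lab setting).
    wavelengths_nm : array, shape (n_wavelengths,)
        Strictly increasing grid in nanometres.
    absorbance : array, shape (n_samples, n_wavelengths)
        Unitless absorbance values.
    density : array, shape (n_samples,)
        Reference air-dry density, g/cm^3.
    moisture_pct : float or array, shape (n_samples,)
        Moisture content (%) at measurement time; a scalar is broadcast.
    """

    sample_ids: list[str]
    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    density: np.ndarray
    moisture_pct: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        n = len(self.sample_ids)
        if np.isscalar(self.moisture_pct) or np.ndim(self.moisture_pct) == 0:
            self.moisture_pct = np.full(n, float(self.moisture_pct))
        else:
            self.moisture_pct = np.asarray(self.moisture_pct, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = len(self.sample_ids)
        if self.absorbance.ndim != 2:
            raise DatasetFormatError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[0] != n or len(self.density) != n:
            raise DatasetFormatError(
                f"inconsistent sample counts: {n} ids, "
                f"{self.absorbance.shape[0]} spectra, {len(self.density)} labels"
            )
        if len(self.moisture_pct) != n:
            raise DatasetFormatError("moisture_pct length must match sample count")
        if self.absorbance.shape[1] != len(self.wavelengths_nm):
            raise DatasetFormatError(
                "absorbance column count does not match wavelength grid"
            )
        if len(self.wavelengths_nm) >= 2 and not np.all(
            np.diff(self.wavelengths_nm) > 0
        ):
            raise DatasetFormatError("wavelength grid must be strictly increasing")
        for name, arr in (
            ("wavelengths_nm", self.wavelengths_nm),
            ("absorbance", self.absorbance),
            ("density", self.density),
        ):
            if not np.all(np.isfinite(arr)):
                raise DatasetFormatError(f"{name} contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    def subset(self, idx: Sequence[int]) -> "SpectralDataset":
        """Row subset preserving order of ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            wavelengths_nm=self.wavelengths_nm,
            absorbance=self.absorbance[idx],
            density=self.density[idx],
            moisture_pct=self.moisture_pct[idx],
        )

    def drop_ids(self, ids: Sequence[str]) -> "SpectralDataset":
        """Remove the named samples (used after outlier screening)."""
        drop = set(map(str, ids))
        keep = [i for i, s in enumerate(self.sample_ids) if s not in drop]
        return self.subset(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.absorbance, other.absorbance)
            and np.array_equal(self.density, other.density)
            and np.array_equal(self.moisture_pct, other.moisture_pct)
        )


@dataclass(frozen=True)
class Metrics:
    """Goodness-of-fit summary: R^2, RMSE and MAE (label units)."""

    r2: float
    rmse: float
    mae: float

    def to_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def read_dataset(path: str | Path, format: str = "csv") -> SpectralDataset:
    """Read a spectral table.

    The CSV layout is ``id,density,moisture,<nm1>,<nm2>,...`` with numeric
    wavelength headers in ascending nm.
    """
    if format != "csv":
        raise ValueError(f"unsupported format: {format!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    expected = ["id", "density", "moisture"]
    if list(df.columns[:3]) != expected:
        raise DatasetFormatError(
            f"{path}: header must start with {expected}, got {list(df.columns[:3])}"
        )
    try:
        wl = np.array([float(c) for c in df.columns[3:]])
    except ValueError as exc:
        raise DatasetFormatError(f"{path}: non-numeric wavelength header") from exc
    if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
        raise DatasetFormatError(f"{path}: wavelength headers not strictly increasing")
    spec = df.iloc[:, 3:].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(spec).all(axis=1))[0]
    if bad.size:
        raise DatasetFormatError(
            f"{path}: row {bad[0] + 2} has missing or non-numeric absorbance values"
        )
    return SpectralDataset(
        sample_ids=list(df["id"]),
        wavelengths_nm=wl,
        absorbance=spec,
        density=df["density"].to_numpy(dtype=float),
        moisture_pct=df["moisture"].to_numpy(dtype=float),
    )


def write_dataset(ds: SpectralDataset, path: str | Path) -> None:
    """Write the CSV layout read by :func:`read_dataset` (round-trip exact).

    Floats are serialised with ``repr`` (shortest round-trip form), so
    ``read_dataset(write_dataset(D)) == D`` bit-exactly.
    """
    path = Path(path)
    cols = ["id", "density", "moisture"] + [repr(float(w)) for w in ds.wavelengths_nm]
    with path.open("w", encoding="utf-8") as fh:
        fh.write(",".join(cols) + "\n")
        for i in range(ds.n_samples):
            row = [ds.sample_ids[i], repr(float(ds.density[i])), repr(float(ds.moisture_pct[i]))]
            row.extend(repr(float(v)) for v in ds.absorbance[i])
            fh.write(",".join(row) + "\n")


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """R^2 (against the mean of ``y_true``), RMSE and MAE.

    Raises if the vectors differ in length or ``y_true`` is constant (R^2
    undefined).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_true is constant; R^2 undefined")
    resid = y_true - y_pred
    ss_res = float(np.sum(resid**2))
    return Metrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
    )
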