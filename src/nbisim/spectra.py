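"""Spectral grid and spectrum containers shared by every stage of the pipeline.

All spectra in the package — patch reflectances, illuminants, camera
sensitivities, colour-matching functions and reconstructed hypercube slices —
live on a :class:`SpectralGrid`, a uniform wavelength axis (default 380–780 nm
at 1 nm, i.e. 401 bands, the visible range the hypercube reconstruction
covers). Resampling between grids is linear interpolation with zero outside
the tabulated support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectralGrid", "Spectrum", "read_spectra_csv", "write_spectra_csv"]


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavelength axis: ``start_nm, start_nm + step_nm, ..., end_nm``."""

    start_nm: float = 380.0
    end_nm: float = 780.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.end_nm):
            raise ValueError(
                f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})"
            )
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        span = self.end_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"grid span {span} nm is not divisible by step {self.step_nm} nm"
            )

    @property
    def n_bands(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands)


@dataclass
class Spectrum:
    """Per-band values (reflectance or relative power) on a grid."""

    grid: SpectralGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError(
                f"expected {self.grid.n_bands} bands, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")

    def resample_to(self, grid: SpectralGrid) -> "Spectrum":
        """Linear interpolation onto ``grid``; zero outside the support."""
        if grid == self.grid:
            return Spectrum(grid, self.values.copy())
        vals = np.interp(
            grid.wavelengths, self.grid.wavelengths, self.values, left=0.0, right=0.0
        )
        return Spectrum(grid, vals)

    @classmethod
    def constant(cls, grid: SpectralGrid, value: float) -> "Spectrum":
        return cls(grid, np.full(grid.n_bands, float(value)))


def _grid_from_wavelengths(wl: np.ndarray) -> SpectralGrid:
    steps = np.diff(wl)
    if len(steps) == 0 or not np.allclose(steps, steps[0], atol=1e-9):
        raise ValueError("wavelength column is not a uniform grid")
    return SpectralGrid(float(wl[0]), float(wl[-1]), float(steps[0]))


def read_spectra_csv(path) -> tuple[SpectralGrid, pd.DataFrame]:
    """Read a wide spectra table: ``wavelength_nm`` column + one column per spectrum."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise KeyError(f"{path}: missing required column 'wavelength_nm'")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    grid = _grid_from_wavelengths(wl)
    return grid, df.drop(columns=["wavelength_nm"])


def write_spectra_csv(path, grid: SpectralGrid, columns: dict[str, np.ndarray]) -> None:
    out = {"wavelength_nm": grid.wavelengths}
    for name, vals in columns.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != (grid.n_bands,):
            raise ValueError(f"column {name!r}: expected {grid.n_bands} values")
        out[name] = vals
    pd.DataFrame(out).to_csv(path, index=False, float_format="%.10g")
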