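"""Reflectance-spectrum reconstruction: PCA basis + colour-feature regression.

The measured patch reflectances are decomposed by mean-centred PCA into a
small number k of principal components (k = 6 by default; for smooth natural
reflectances six components carry essentially all variance). A second
regression maps polynomial features of the *corrected* XYZ of each patch to
its PC scores:

    M = Score · pinv(V_color),     s(λ) = mean(λ) + EV · M · V_color(XYZ)

Applying this per pixel turns a calibrated RGB image into a reflectance
hypercube on the 380–780 nm grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import colorimetry as cm
from .calibration import (
    PINV_RCOND,
    CorrectionModel,
    FeatureExpansionSpec,
    PatchCalibrationSet,
    apply_correction,
    camera_xyz_from_srgb,
    expand_features,
)
from .spectra import SpectralGrid

__all__ = [
    "SpectralBasis",
    "SpectralMapping",
    "Hypercube",
    "fit_basis",
    "fit_mapping",
    "reconstruct_spectrum",
    "image_to_hypercube",
    "spectrum_rmse",
    "CLAMP_MAX",
]

logger = logging.getLogger(__name__)

# Reconstruction may overshoot physical reflectance slightly; 1.2 bounds
# nonphysical blow-up while allowing bright glossy patches.
CLAMP_MAX = 1.2


@dataclass
class SpectralBasis:
    """Mean spectrum + orthonormal PCA eigenvector basis."""

    grid: SpectralGrid
    mean_spectrum: np.ndarray  # (n_bands,)
    EV: np.ndarray  # (n_bands, k)
    explained_variance_ratio: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        self.EV = np.asarray(self.EV, dtype=float)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=float
        )
        nb = self.grid.n_bands
        if self.mean_spectrum.shape != (nb,):
            raise ValueError("mean spectrum does not match grid band count")
        if self.EV.shape[0] != nb:
            raise ValueError("eigenvector rows must match grid band count")
        gram = self.EV.T @ self.EV
        if np.max(np.abs(gram - np.eye(self.k))) > 1e-8:
            raise ValueError("eigenvector columns are not orthonormal")

    @property
    def k(self) -> int:
        return self.EV.shape[1]


@dataclass
class SpectralMapping:
    """Colour-feature → PC-score regression matrix."""

    expansion: FeatureExpansionSpec
    M: np.ndarray  # (k, n_terms)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[1] != self.expansion.n_terms:
            raise ValueError(
                f"M must be (k, {self.expansion.n_terms}), got {self.M.shape}"
            )

    @property
    def k(self) -> int:
        return self.M.shape[0]


@dataclass
class Hypercube:
    """Per-pixel reflectance spectra, shape (height, width, n_bands)."""

    grid: SpectralGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"hypercube must be (H, W, {self.grid.n_bands}), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("hypercube contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("hypercube contains negative reflectance")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def fit_basis(spectra: np.ndarray, grid: SpectralGrid, k: int = 6) -> SpectralBasis:
    """Mean-centred PCA of a (n, n_bands) reflectance matrix, keeping k PCs.

    Eigenvector signs are fixed so each column's largest-magnitude element is
    positive (reproducible serialization). Raises if ``k`` exceeds the
    numerical rank of the centred data.
    """
    R = np.atleast_2d(np.asarray(spectra, dtype=float))
    if R.shape[1] != grid.n_bands:
        raise ValueError(f"spectra have {R.shape[1]} bands, grid has {grid.n_bands}")
    if R.shape[0] < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} spectra, got {R.shape[0]}")
    mean = R.mean(axis=0)
    Xc = R - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # rank tolerance floored at the raw data scale so that numerically
    # identical spectra (centred residue ~1 ulp) register as rank 0
    eps = np.finfo(float).eps
    tol = max(Xc.shape) * eps * max(s[0] if s.size else 0.0, np.abs(R).max())
    rank = int(np.sum(s > tol))
    if k > rank:
        raise ValueError(
            f"requested {k} components but the centred spectra have rank {rank}"
        )
    EV = Vt[:k].T  # (n_bands, k)
    # deterministic sign: largest-|.| element of each column positive
    flip = np.sign(EV[np.argmax(np.abs(EV), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    EV = EV * flip
    var = s**2
    evr = var[:k] / var.sum()
    return SpectralBasis(grid, mean, EV, evr)


def scores_of(basis: SpectralBasis, spectra: np.ndarray) -> np.ndarray:
    """PC scores EVᵀ·(r − mean) for spectra (…, n_bands) → (…, k)."""
    return (np.asarray(spectra, dtype=float) - basis.mean_spectrum) @ basis.EV


def fit_mapping(
    basis: SpectralBasis,
    cal: PatchCalibrationSet,
    correction: CorrectionModel,
    spec: FeatureExpansionSpec | None = None,
) -> SpectralMapping:
    """M = Score · pinv(V_color) with V_color the expanded corrected XYZ."""
    if cal.grid != basis.grid:
        raise ValueError("calibration set and basis are on different grids")
    spec = spec or correction.expansion
    corrected = apply_correction(correction, camera_xyz_from_srgb(cal.camera_rgb))
    Vc = expand_features(corrected, spec).T  # (n_terms, n)
    Score = scores_of(basis, cal.reflectances).T  # (k, n)
    M = Score @ np.linalg.pinv(Vc, rcond=PINV_RCOND)
    return SpectralMapping(spec, M)


def _reconstruct(
    mapping: SpectralMapping, basis: SpectralBasis, xyz_corrected: np.ndarray
) -> np.ndarray:
    feats = expand_features(xyz_corrected, mapping.expansion)
    scores = feats @ mapping.M.T
    return basis.mean_spectrum + scores @ basis.EV.T


def reconstruct_spectrum(
    mapping: SpectralMapping, basis: SpectralBasis, xyz_corrected: np.ndarray
) -> np.ndarray:
    """Reflectance spectrum (…, n_bands) from corrected XYZ (…, 3).

    Output is clamped to [0, CLAMP_MAX]; the number of clamped bands is
    logged at DEBUG level.
    """
    s = _reconstruct(mapping, basis, xyz_corrected)
    n_clamped = int(np.sum((s < 0) | (s > CLAMP_MAX)))
    if n_clamped:
        logger.debug("clamped %d reconstructed band values", n_clamped)
    return np.clip(s, 0.0, CLAMP_MAX)


def image_to_hypercube(
    img: np.ndarray,
    correction: CorrectionModel,
    mapping: SpectralMapping,
    basis: SpectralBasis,
    dtype=np.float32,
) -> Hypercube:
    """Pixelwise sRGB decode → camera XYZ → correction → spectral reconstruction."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(float) / 65535.0
    h, w, _ = img.shape
    xyz = apply_correction(correction, camera_xyz_from_srgb(img.reshape(-1, 3)))
    cube = reconstruct_spectrum(mapping, basis, xyz).reshape(h, w, -1)
    return Hypercube(basis.grid, cube.astype(dtype))


def spectrum_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square per-band difference of two equal-grid spectra."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def basis_to_json(basis: SpectralBasis, mapping: SpectralMapping, path) -> None:
    payload = {
        "grid": {
            "start_nm": basis.grid.start_nm,
            "end_nm": basis.grid.end_nm,
            "step_nm": basis.grid.step_nm,
        },
        "mean_spectrum": basis.mean_spectrum.tolist(),
        "EV_shape": list(basis.EV.shape),
        "EV": basis.EV.ravel().tolist(),  # row-major
        "explained_variance_ratio": basis.explained_variance_ratio.tolist(),
        "mapping_terms": [list(t) for t in mapping.expansion.terms],
        "M_shape": list(mapping.M.shape),
        "M": mapping.M.ravel().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def basis_from_json(path) -> tuple[SpectralBasis, SpectralMapping]:
    with open(path) as fh:
        payload = json.load(fh)
    grid = SpectralGrid(**payload["grid"])
    EV = np.array(payload["EV"]).reshape(payload["EV_shape"])
    basis = SpectralBasis(
        grid,
        np.array(payload["mean_spectrum"]),
        EV,
        np.array(payload["explained_variance_ratio"]),
    )
    spec = FeatureExpansionSpec(tuple(tuple(t) for t in payload["mapping_terms"]))
    M = np.array(payload["M"]).reshape(payload["M_shape"])
    return basis, SpectralMapping(spec, M)
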