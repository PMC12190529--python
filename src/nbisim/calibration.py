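"""Camera colorimetric calibration against a 24-patch colour target.

The camera's sRGB values are linearized, mapped to camera XYZ with the
standard sRGB→XYZ(D65) matrix, expanded into a polynomial feature vector V,
and regressed onto the spectrum-derived XYZ of the same patches:

    C = XYZ_spectrum · pinv(V),        XYZ_corrected = C · V(camera XYZ)

The pseudo-inverse is the minimum-norm SVD solution, so the fit is a least
squares regression that can only reduce the training colour error. Colour
error ("chromatic aberration") is reported per patch as CIEDE2000 by default,
with CIE76 ΔE*ab available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import colorimetry as cm
from .spectra import SpectralGrid, Spectrum

__all__ = [
    "FeatureExpansionSpec",
    "PatchCalibrationSet",
    "CorrectionModel",
    "expand_features",
    "fit_correction",
    "apply_correction",
    "calibration_report",
]

PINV_RCOND = 1e-10


@dataclass(frozen=True)
class FeatureExpansionSpec:
    """Ordered monomial basis over a colour triple (X, Y, Z).

    Each term is an exponent triple (i, j, k) meaning X^i · Y^j · Z^k; the
    constant term (0, 0, 0) must appear exactly once.
    """

    terms: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("feature expansion needs at least one term")
        n_const = sum(1 for t in self.terms if t == (0, 0, 0))
        if n_const != 1:
            raise ValueError(
                f"constant term (0,0,0) must appear exactly once, found {n_const}"
            )
        for t in self.terms:
            if len(t) != 3 or any(e < 0 for e in t):
                raise ValueError(f"invalid exponent triple {t}")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def max_degree(self) -> int:
        return max(sum(t) for t in self.terms)

    @classmethod
    def polynomial(cls, degree: int) -> "FeatureExpansionSpec":
        """Canonical expansions: degree 1 {1,X,Y,Z}; degree 2 adds the
        pairwise products and squares; degree 3 (default) adds XYZ and cubes —
        14 terms, still overdetermined by a 24-patch target."""
        if degree < 1 or degree > 3:
            raise ValueError("polynomial expansion supported for degree 1..3")
        terms: list[tuple[int, int, int]] = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        if degree >= 2:
            terms += [(1, 1, 0), (1, 0, 1), (0, 1, 1), (2, 0, 0), (0, 2, 0), (0, 0, 2)]
        if degree >= 3:
            terms += [(1, 1, 1), (3, 0, 0), (0, 3, 0), (0, 0, 3)]
        return cls(tuple(terms))


DEFAULT_EXPANSION = FeatureExpansionSpec.polynomial(3)


def expand_features(xyz: np.ndarray, spec: FeatureExpansionSpec) -> np.ndarray:
    """Monomial features of XYZ (…,3) → (…, n_terms), in the spec's order.

    XYZ is rescaled by 1/100 before exponentiation so that higher-order
    monomials stay O(1) and the pseudo-inverse is well conditioned.
    """
    u = np.asarray(xyz, dtype=float) / 100.0
    cols = [
        u[..., 0] ** i * u[..., 1] ** j * u[..., 2] ** k for (i, j, k) in spec.terms
    ]
    return np.stack(cols, axis=-1)


@dataclass
class PatchCalibrationSet:
    """Paired camera sRGB triples and measured reflectance spectra."""

    grid: SpectralGrid
    camera_rgb: np.ndarray  # (n, 3) sRGB-encoded in [0, 1]
    reflectances: np.ndarray  # (n, n_bands)
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.camera_rgb = np.atleast_2d(np.asarray(self.camera_rgb, dtype=float))
        self.reflectances = np.atleast_2d(np.asarray(self.reflectances, dtype=float))
        n = self.camera_rgb.shape[0]
        if self.camera_rgb.shape != (n, 3):
            raise ValueError(f"camera_rgb must be (n, 3), got {self.camera_rgb.shape}")
        if self.reflectances.shape != (n, self.grid.n_bands):
            raise ValueError(
                "one reflectance spectrum per patch required: "
                f"got {self.reflectances.shape}, expected ({n}, {self.grid.n_bands})"
            )
        if self.names is None:
            self.names = [f"patch_{i:02d}" for i in range(n)]

    @property
    def n_patches(self) -> int:
        return self.camera_rgb.shape[0]


def camera_xyz_from_srgb(rgb: np.ndarray) -> np.ndarray:
    """sRGB-encoded camera values (…,3) → camera XYZ (white Y = 100)."""
    return cm.linear_rgb_to_xyz(cm.srgb_decode(rgb))


@dataclass
class CorrectionModel:
    """Fitted camera→colorimeter correction (matrix C over a feature basis)."""

    expansion: FeatureExpansionSpec
    C: np.ndarray  # (3, n_terms)
    white: np.ndarray  # (3,) white point of the target colorimetry
    fit_report: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (3, self.expansion.n_terms):
            raise ValueError(
                f"C must be (3, {self.expansion.n_terms}), got {self.C.shape}"
            )

    def to_json(self, path) -> None:
        payload = {
            "expansion_terms": [list(t) for t in self.expansion.terms],
            "C": self.C.tolist(),
            "white": np.asarray(self.white, dtype=float).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CorrectionModel":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("expansion_terms", "C", "white"):
            if key not in payload:
                raise KeyError(f"correction model JSON missing field {key!r}")
        spec = FeatureExpansionSpec(
            tuple(tuple(t) for t in payload["expansion_terms"])
        )
        return cls(spec, np.array(payload["C"]), np.array(payload["white"]))


def fit_correction(
    cal: PatchCalibrationSet,
    spec: FeatureExpansionSpec = DEFAULT_EXPANSION,
    illuminant: Spectrum | None = None,
    cmf: dict[str, Spectrum] | None = None,
    metric: str = "de00",
) -> CorrectionModel:
    """Fit C = XYZ_spectrum · pinv(V) on the calibration patches."""
    if cal.n_patches < 4:
        raise ValueError(f"need at least 4 patches, got {cal.n_patches}")
    if cal.n_patches < spec.n_terms:
        warnings.warn(
            f"underdetermined fit: {cal.n_patches} patches < {spec.n_terms} terms",
            stacklevel=2,
        )
    illuminant = illuminant or cm.d65_illuminant(cal.grid)
    cmf = cmf or cm.cmf_1931(cal.grid)
    if illuminant.grid != cal.grid:
        raise ValueError("illuminant grid does not match calibration grid")

    cam_xyz = camera_xyz_from_srgb(cal.camera_rgb)  # (n, 3)
    V = expand_features(cam_xyz, spec).T  # (n_terms, n)
    targets = cm.spectra_to_xyz(cal.reflectances, illuminant, cmf)  # (n, 3)

    rank = np.linalg.matrix_rank(V, tol=PINV_RCOND * np.linalg.norm(V, 2))
    if rank < min(V.shape):
        warnings.warn(
            f"feature matrix is rank deficient (effective rank {rank} of "
            f"{min(V.shape)}); minimum-norm solution returned",
            stacklevel=2,
        )
    C = targets.T @ np.linalg.pinv(V, rcond=PINV_RCOND)

    white = cm.white_point(illuminant, cmf)
    model = CorrectionModel(spec, C, white)
    model.fit_report = _build_report(model, cal, cam_xyz, targets, metric)
    return model


def _delta_e(metric: str, lab_a: np.ndarray, lab_b: np.ndarray):
    if metric == "de00":
        return cm.ciede2000(lab_a, lab_b)
    if metric == "deab":
        return cm.delta_e_ab(lab_a, lab_b)
    raise ValueError(f"unknown colour-difference metric {metric!r}")


def _build_report(model, cal, cam_xyz, targets, metric) -> pd.DataFrame:
    corrected = apply_correction(model, cam_xyz)
    lab_target = cm.xyz_to_lab(targets, model.white)
    pre = _delta_e(metric, cm.xyz_to_lab(cam_xyz, model.white), lab_target)
    post = _delta_e(metric, cm.xyz_to_lab(corrected, model.white), lab_target)
    return pd.DataFrame(
        {
            "patch": cal.names,
            f"pre_{metric}": pre,
            f"post_{metric}": post,
        }
    )


def apply_correction(model: CorrectionModel, xyz: np.ndarray) -> np.ndarray:
    """XYZ_corrected = C · V(xyz); vectorized over leading axes."""
    return expand_features(xyz, model.expansion) @ model.C.T


def calibration_report(model: CorrectionModel) -> pd.DataFrame:
    """Per-patch pre/post colour error with a trailing mean row."""
    if model.fit_report is None:
        raise ValueError("model has no stored fit report (was it fitted?)")
    rep = model.fit_report.copy()
    means = rep.iloc[:, 1:].mean()
    mean_row = pd.DataFrame({"patch": ["mean"], **{c: [means[c]] for c in means.index}})
    return pd.concat([rep, mean_row], ignore_index=True)
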