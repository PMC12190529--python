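"""Synthetic world with known ground truth: smooth patch reflectances, a
configurable synthetic camera, patch-grid scenes, and an independent oracle
NBI renderer.

The generator emulates the measurement setting of a 24-patch colour-target
calibration: reflectance spectra are smooth, low-intrinsic-dimension curves
(logistic-squashed sums of a few wide Gaussian bumps), and the camera is
colorimetric (its sensitivities are nonnegative linear combinations of the
CIE 1931 observer) with an optional mild polynomial nonlinearity in XYZ and
optional Gaussian sensor noise. Every output is a pure function of
(parameters, seed).

The camera nonlinearity is *declared* as the polynomial map ``g`` from camera
XYZ back to scene XYZ (scene_xyz = g(camera_xyz) up to the linear mixing);
the render applies g⁻¹ by Newton iteration. Declaring the recovery direction
makes the noiseless world exactly invertible by a polynomial feature
expansion of matching degree, which is what anchors the pipeline's
exact-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import colorimetry as cm
from .spectra import SpectralGrid, Spectrum

__all__ = [
    "SyntheticCamera",
    "SyntheticScene",
    "gen_reflectances",
    "gen_lowrank_reflectances",
    "gen_camera",
    "render_wli",
    "oracle_nbi",
]

logger = logging.getLogger(__name__)

# quadratic monomials in u = XYZ/100, order fixed for the distortion coeffs
_QUAD_TERMS = ((2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1))


def gen_reflectances(
    n: int = 24,
    grid: SpectralGrid | None = None,
    n_gaussians: int = 3,
    width_range: tuple[float, float] = (50.0, 90.0),
    amplitude: float = 1.6,
    seed: int = 0,
) -> np.ndarray:
    """Smooth random reflectance spectra (n, n_bands), values in (0, 1).

    Each spectrum is ``sigmoid(sum of n_gaussians Gaussian bumps)``: smooth,
    bounded, and of low intrinsic dimension — the regime in which six
    principal components carry essentially all the variance of a 24-patch
    set. Constraints: at most 4 bumps, bump widths at least 40 nm.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_gaussians > 4:
        raise ValueError("smoothness constraint: n_gaussians must be <= 4")
    if n_gaussians > 0 and width_range[0] < 40.0:
        raise ValueError("smoothness constraint: bump width must be >= 40 nm")
    grid = grid or SpectralGrid()
    wl = grid.wavelengths
    if n_gaussians == 0:
        return np.full((n, grid.n_bands), 0.5)
    rng = np.random.default_rng(seed)
    amps = rng.uniform(-amplitude, amplitude, size=(n, n_gaussians))
    mus = rng.uniform(grid.start_nm, grid.end_nm, size=(n, n_gaussians))
    sigmas = rng.uniform(width_range[0], width_range[1], size=(n, n_gaussians))
    bumps = amps[:, :, None] * np.exp(
        -0.5 * ((wl[None, None, :] - mus[:, :, None]) / sigmas[:, :, None]) ** 2
    )
    return 1.0 / (1.0 + np.exp(-bumps.sum(axis=1)))


def gen_lowrank_reflectances(
    n: int,
    grid: SpectralGrid | None = None,
    dim: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Reflectances lying exactly in a ``dim``-dimensional affine span.

    Used for the exact-recovery world: 0.5 + a bounded linear combination of
    ``dim`` fixed wide Gaussian basis curves, rescaled into [0.05, 0.95].
    """
    grid = grid or SpectralGrid()
    wl = grid.wavelengths
    centers = np.linspace(grid.start_nm + 40, grid.end_nm - 40, dim)
    basis = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / 80.0) ** 2)
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(-1.0, 1.0, size=(n, dim))
    raw = 0.5 + coeffs @ basis
    lo, hi = raw.min(), raw.max()
    # 0.35 headroom keeps every patch comfortably inside the sRGB gamut of
    # the synthetic camera, so noiseless renders never clip
    scale = min(1.0, 0.35 / max(hi - 0.5, 0.5 - lo, 1e-12))
    return 0.5 + scale * (raw - 0.5)


@dataclass
class SyntheticCamera:
    """Colorimetric camera with declared polynomial XYZ nonlinearity."""

    grid: SpectralGrid
    B: np.ndarray  # (3,3) nonnegative observer mixing, scene XYZ -> raw
    distortion: np.ndarray  # (3,6) coeffs of g over _QUAD_TERMS, u = XYZ/100
    exposure: float = 0.85
    noise_sd: float = 0.0
    cmf: dict[str, Spectrum] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.distortion = np.asarray(self.distortion, dtype=float)
        if self.B.shape != (3, 3) or np.any(self.B < 0):
            raise ValueError("B must be a nonnegative 3x3 matrix")
        if self.distortion.shape != (3, len(_QUAD_TERMS)):
            raise ValueError(f"distortion must be (3, {len(_QUAD_TERMS)})")
        if self.cmf is None:
            self.cmf = cm.cmf_1931(self.grid)

    @property
    def sensitivities(self) -> list[Spectrum]:
        stack = np.stack(
            [self.cmf["xbar"].values, self.cmf["ybar"].values, self.cmf["zbar"].values]
        )
        return [Spectrum(self.grid, row) for row in self.B @ stack]

    # --- declared nonlinearity -------------------------------------------
    def _quad(self, u: np.ndarray) -> np.ndarray:
        cols = [
            u[..., 0] ** i * u[..., 1] ** j * u[..., 2] ** k
            for (i, j, k) in _QUAD_TERMS
        ]
        return np.stack(cols, axis=-1)

    def g(self, camera_xyz: np.ndarray) -> np.ndarray:
        """Declared polynomial: raw response = g(camera XYZ)."""
        d = np.asarray(camera_xyz, dtype=float)
        u = d / 100.0
        return d + 100.0 * self._quad(u) @ self.distortion.T

    def _g_inverse(self, raw: np.ndarray) -> np.ndarray:
        """Solve g(d) = raw by damped Newton iteration (g ≈ identity)."""
        raw = np.asarray(raw, dtype=float)
        d = raw.copy()
        for _ in range(60):
            resid = self.g(d) - raw
            if np.max(np.abs(resid)) < 1e-11:
                break
            u = d / 100.0
            # Jacobian of g at each point: I + d(quad)/dd @ coeffs
            J = np.broadcast_to(np.eye(3), d.shape[:-1] + (3, 3)).copy()
            for t_idx, (i, j, k) in enumerate(_QUAD_TERMS):
                grads = np.stack(
                    [
                        i * u[..., 0] ** max(i - 1, 0) * u[..., 1] ** j * u[..., 2] ** k,
                        j * u[..., 0] ** i * u[..., 1] ** max(j - 1, 0) * u[..., 2] ** k,
                        k * u[..., 0] ** i * u[..., 1] ** j * u[..., 2] ** max(k - 1, 0),
                    ],
                    axis=-1,
                )
                J += self.distortion[:, t_idx][..., :, None] * grads[..., None, :]
            step = np.linalg.solve(J, resid[..., None])[..., 0]
            d = d - step
        return d

    # --- rendering --------------------------------------------------------
    def respond(self, scene_xyz: np.ndarray) -> np.ndarray:
        """Noiseless linear sRGB response (…,3) in [0,1] to scene XYZ (…,3)."""
        raw = self.exposure * np.asarray(scene_xyz, dtype=float) @ self.B.T
        d = self._g_inverse(raw)
        lin = (d / 100.0) @ cm.XYZ_TO_SRGB.T
        n_clip = int(np.sum((lin < 0) | (lin > 1)))
        if n_clip:
            logger.debug("camera response clipped %d channel values", n_clip)
        return np.clip(lin, 0.0, 1.0)

    def true_xyz_of(self, camera_xyz: np.ndarray) -> np.ndarray:
        """Exact recovery map: scene XYZ as a polynomial of camera XYZ."""
        inv = np.linalg.inv(self.exposure * self.B)
        return self.g(camera_xyz) @ inv.T


def gen_camera(
    grid: SpectralGrid | None = None,
    seed: int = 0,
    distortion_degree: int = 2,
    mixing: float = 0.15,
    distortion_scale: float = 0.03,
    exposure: float = 0.85,
    noise_sd: float = 0.0,
    cmf: dict[str, Spectrum] | None = None,
) -> SyntheticCamera:
    """Random colorimetric camera: near-identity nonnegative observer mixing
    and, for ``distortion_degree == 2``, small random quadratic coefficients."""
    grid = grid or SpectralGrid()
    rng = np.random.default_rng(seed)
    if distortion_degree not in (1, 2):
        raise ValueError("distortion_degree must be 1 or 2")
    S = rng.uniform(0.0, 1.0, size=(3, 3))
    S /= S.sum(axis=1, keepdims=True)
    B = (1.0 - mixing) * np.eye(3) + mixing * S
    if distortion_degree == 2:
        coeffs = rng.uniform(-distortion_scale, distortion_scale, size=(3, 6))
    else:
        coeffs = np.zeros((3, 6))
    return SyntheticCamera(
        grid, B, coeffs, exposure=exposure, noise_sd=noise_sd, cmf=cmf
    )


@dataclass
class SyntheticScene:
    """Patch-grid scene: each patch is a constant-reflectance square tile."""

    grid: SpectralGrid
    reflectances: np.ndarray  # (n, n_bands) in [0, 1]
    rows: int = 4
    cols: int = 6
    patch_px: int = 32

    def __post_init__(self) -> None:
        self.reflectances = np.atleast_2d(np.asarray(self.reflectances, dtype=float))
        if self.reflectances.shape != (self.rows * self.cols, self.grid.n_bands):
            raise ValueError(
                f"need rows*cols = {self.rows * self.cols} spectra of "
                f"{self.grid.n_bands} bands, got {self.reflectances.shape}"
            )
        if np.any(self.reflectances < 0) or np.any(self.reflectances > 1):
            raise ValueError("scene reflectances must lie in [0, 1]")

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.rows * self.patch_px, self.cols * self.patch_px

    def tile(self, per_patch: np.ndarray) -> np.ndarray:
        """Expand per-patch values (n, c) into the (H, W, c) patch-grid image."""
        per_patch = np.asarray(per_patch)
        img = per_patch.reshape(self.rows, self.cols, -1)
        img = np.repeat(np.repeat(img, self.patch_px, axis=0), self.patch_px, axis=1)
        return img

    def patch_means(self, img: np.ndarray) -> np.ndarray:
        """Mean value of each patch tile of an (H, W, c) image → (n, c)."""
        h, w = self.image_shape
        img = np.asarray(img).reshape(
            self.rows, self.patch_px, self.cols, self.patch_px, -1
        )
        return img.mean(axis=(1, 3)).reshape(self.n_patches, -1)


def render_wli(
    scene: SyntheticScene,
    camera: SyntheticCamera,
    illuminant: Spectrum | None = None,
    cmf: dict[str, Spectrum] | None = None,
    noise_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """White-light render: (sRGB float image (H, W, 3), true patch XYZ (n, 3)).

    Noiseless renders are deterministic; with ``camera.noise_sd > 0`` a
    ``noise_seed`` is required and Gaussian noise is added per pixel in
    linear RGB before encoding.
    """
    illuminant = illuminant or cm.d65_illuminant(scene.grid)
    cmf = cmf or cm.cmf_1931(scene.grid)
    true_xyz = cm.spectra_to_xyz(scene.reflectances, illuminant, cmf)
    lin = camera.respond(true_xyz)  # (n, 3)
    img_lin = scene.tile(lin)
    if camera.noise_sd > 0:
        if noise_seed is None:
            raise ValueError("noise_sd > 0 requires an explicit noise_seed")
        rng = np.random.default_rng(noise_seed)
        img_lin = img_lin + rng.normal(0.0, camera.noise_sd, img_lin.shape)
    img = np.asarray(cm.srgb_encode(np.clip(img_lin, 0.0, 1.0)))
    return img, true_xyz


def oracle_nbi(
    scene: SyntheticScene,
    band_spec,
    cmf: dict[str, Spectrum] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth NBI render from the TRUE reflectances.

    Independent of the reconstruction pipeline: band integration is coded
    inline here (explicit Lorentzian formula and per-band loop) and consumes
    the scene's true spectra, never a reconstructed hypercube. Returns the
    sRGB float image and the per-patch CIELAB targets (sRGB D65 white).
    """
    cmf = cmf or cm.cmf_1931(scene.grid)
    wl = scene.grid.wavelengths
    ybar = cmf["ybar"].values
    responses = np.empty((scene.n_patches, len(band_spec.bands)))
    for b_idx, band in enumerate(band_spec.bands):
        unit = (band.gamma / np.pi) / ((wl - band.x0) ** 2 + band.gamma**2)
        kernel = unit * ybar
        kernel = kernel / kernel.sum()
        for p in range(scene.n_patches):
            responses[p, b_idx] = band.amplitude * float(
                np.dot(scene.reflectances[p], kernel)
            )
    lin = np.clip(responses @ band_spec.mix.T, 0.0, 1.0)
    srgb = np.asarray(cm.srgb_encode(lin))
    lab = cm.xyz_to_lab(cm.linear_rgb_to_xyz(lin), cm.srgb_white_xyz())
    return np.asarray(scene.tile(srgb)), lab
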