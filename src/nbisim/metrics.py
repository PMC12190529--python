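"""Image-level validation metrics for the simulated NBI: SSIM, PSNR,
histogram entropy difference and CIEDE2000 summaries.

SSIM uses the standard 11×11 Gaussian window (σ = 1.5, K1 = 0.01, K2 = 0.03)
on the BT.601 luma of the sRGB-encoded image. Entropy is Shannon entropy of
the 256-bin grayscale histogram (0–8 bits); its percent difference is
normalized by the reference image's entropy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from . import colorimetry as cm

__all__ = [
    "QualityReport",
    "to_gray",
    "ssim",
    "psnr",
    "entropy",
    "entropy_diff",
    "patchwise_delta_e",
    "evaluate_pair",
]

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601


def _as_float(img: np.ndarray) -> tuple[np.ndarray, float]:
    """Image as float plus its dynamic range (255 for 8-bit-style data)."""
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float), 255.0
    if img.dtype == np.uint16:
        return img.astype(float), 65535.0
    return img.astype(float), 1.0


def to_gray(img: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB image; grayscale input passes through."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 3 and img.shape[2] == 3:
        return img @ _LUMA
    if img.ndim == 2:
        return img
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {img.shape}")


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if np.asarray(a).shape != np.asarray(b).shape:
        raise ValueError(
            f"image shapes differ: {np.asarray(a).shape} vs {np.asarray(b).shape}"
        )


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Mean SSIM over the luminance map (11×11 Gaussian window, σ=1.5)."""
    _check_same_shape(a, b)
    af, ra = _as_float(a)
    bf, rb = _as_float(b)
    data_range = data_range if data_range is not None else max(ra, rb)
    return float(
        structural_similarity(
            to_gray(af),
            to_gray(bf),
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def psnr(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """10·log10(range²/MSE) in dB; identical images give +infinity."""
    _check_same_shape(a, b)
    af, ra = _as_float(a)
    bf, rb = _as_float(b)
    data_range = data_range if data_range is not None else max(ra, rb)
    if np.array_equal(af, bf):
        return math.inf
    return float(peak_signal_noise_ratio(af, bf, data_range=data_range))


def entropy(img: np.ndarray, data_range: float | None = None) -> float:
    """Shannon entropy (bits) of the 256-bin grayscale histogram."""
    g = to_gray(_as_float(img)[0])
    if g.size == 0:
        raise ValueError("empty image")
    rng = data_range if data_range is not None else _as_float(img)[1]
    hist, _ = np.histogram(g, bins=256, range=(0.0, float(rng)))
    p = hist[hist > 0] / g.size
    return float(-np.sum(p * np.log2(p)))


def entropy_diff(
    a: np.ndarray, b: np.ndarray, data_range: float | None = None
) -> tuple[float, float, float]:
    """(entropy_a, entropy_b, |Ha−Hb|/Ha·100); ``a`` is the reference."""
    _check_same_shape(a, b)
    ha = entropy(a, data_range)
    hb = entropy(b, data_range)
    pct = 0.0 if ha == hb else abs(ha - hb) / ha * 100.0
    return ha, hb, pct


def patchwise_delta_e(
    predicted_lab: np.ndarray, target_lab: np.ndarray
) -> dict[str, object]:
    """CIEDE2000 per patch plus mean/max summaries."""
    predicted_lab = np.atleast_2d(np.asarray(predicted_lab, dtype=float))
    target_lab = np.atleast_2d(np.asarray(target_lab, dtype=float))
    if predicted_lab.shape != target_lab.shape:
        raise ValueError("predicted and target patch counts differ")
    per_patch = np.asarray(cm.ciede2000(predicted_lab, target_lab))
    return {
        "per_patch": per_patch,
        "mean": float(per_patch.mean()),
        "max": float(per_patch.max()),
    }


@dataclass
class QualityReport:
    """All metrics for one (reference, test) image pair."""

    ssim: float
    psnr_db: float | None  # None flags identical images (infinite PSNR)
    entropy_ref: float
    entropy_test: float
    entropy_diff_percent: float
    deltaE00_mean: float | None = None
    deltaE00_max: float | None = None
    deltaE00_per_patch: list[float] | None = None
    n_images: int = 1
    ssim_params: str = "11x11 gaussian, sigma=1.5, K1=0.01, K2=0.03, BT.601 luma"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def as_table(self) -> str:
        rows = [
            ("ssim", f"{self.ssim:.6f}"),
            ("psnr_db", "inf" if self.psnr_db is None else f"{self.psnr_db:.4f}"),
            ("entropy_ref_bits", f"{self.entropy_ref:.4f}"),
            ("entropy_test_bits", f"{self.entropy_test:.4f}"),
            ("entropy_diff_percent", f"{self.entropy_diff_percent:.4f}"),
        ]
        if self.deltaE00_mean is not None:
            rows.append(("deltaE00_mean", f"{self.deltaE00_mean:.4f}"))
            rows.append(("deltaE00_max", f"{self.deltaE00_max:.4f}"))
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def evaluate_pair(
    reference: np.ndarray,
    test: np.ndarray,
    predicted_lab: np.ndarray | None = None,
    target_lab: np.ndarray | None = None,
    data_range: float | None = None,
) -> QualityReport:
    """Full quality report for a reference/test image pair."""
    s = ssim(reference, test, data_range)
    p = psnr(reference, test, data_range)
    h_ref, h_test, pct = entropy_diff(reference, test, data_range)
    report = QualityReport(
        ssim=s,
        psnr_db=None if math.isinf(p) else p,
        entropy_ref=h_ref,
        entropy_test=h_test,
        entropy_diff_percent=pct,
    )
    if predicted_lab is not None and target_lab is not None:
        summary = patchwise_delta_e(predicted_lab, target_lab)
        report.deltaE00_mean = summary["mean"]
        report.deltaE00_max = summary["max"]
        report.deltaE00_per_patch = [float(v) for v in summary["per_patch"]]
    return report
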