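"""Image filter transforms applied before texture extraction.

Seven transform classes produce 18 derived images from each original
volume: a one-level 3D stationary wavelet transform (8 sub-bands),
Laplacian-of-Gaussian at 5 sigmas, and 5 single-output intensity/spatial
maps (square, square root, logarithm, exponential, gradient magnitude).
The intensity maps rescale their output back into the original dynamic
range so one discretization bin width remains meaningful across images.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["filter_image", "all_filtered_images", "FILTER_KINDS"]

FILTER_KINDS = (
    "wavelet",
    "log",
    "square",
    "squareroot",
    "logarithm",
    "exponential",
    "gradient",
)

DEFAULT_LOG_SIGMAS = (1.0, 2.0, 3.0, 4.0, 5.0)  # mm
DEFAULT_WAVELET = "coif1"


def _wavelet(volume: np.ndarray, wavelet: str) -> list[tuple[str, np.ndarray]]:
    # stationary transform needs even dims; edge-pad then crop back
    pads = [(0, s % 2) for s in volume.shape]
    padded = np.pad(volume, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    out = []
    for key in sorted(coeffs):  # 'aaa' .. 'ddd', deterministic order
        name = "wavelet-" + "".join("L" if ch == "a" else "H" for ch in key)
        sub = coeffs[key][tuple(slice(0, s) for s in volume.shape)]
        out.append((name, sub))
    return out


def _log_filter(volume, spacing, sigmas_mm) -> list[tuple[str, np.ndarray]]:
    out = []
    for sigma in sigmas_mm:
        voxel_sigma = [sigma / s for s in spacing]
        name = f"log-sigma-{sigma:g}-mm-3D".replace(".", "-")
        out.append((name, ndimage.gaussian_laplace(volume, voxel_sigma)))
    return out


def _square(v):
    m = np.abs(v).max()
    return (v / np.sqrt(m)) ** 2 if m > 0 else v.copy()


def _squareroot(v):
    m = np.abs(v).max()
    if m == 0:
        return v.copy()
    return np.where(v >= 0, np.sqrt(m * v.clip(min=0)), -np.sqrt(-m * v.clip(max=0)))


def _logarithm(v):
    m = np.abs(v).max()
    if m == 0:
        return v.copy()
    out = np.sign(v) * np.log(np.abs(v) + 1)
    return out * (m / np.abs(out).max())


def _exponential(v):
    m = np.abs(v).max()
    if m == 0:
        return np.ones_like(v)
    return np.exp(np.log(m) / m * v)


def _gradient(v, spacing):
    grads = np.gradient(v, *spacing)
    return np.sqrt(sum(g**2 for g in grads))


def filter_image(
    volume: np.ndarray,
    kind: str,
    spacing=(1.0, 1.0, 1.0),
    log_sigmas=DEFAULT_LOG_SIGMAS,
    wavelet: str = DEFAULT_WAVELET,
) -> list[tuple[str, np.ndarray]]:
    """Apply one filter class; returns a list of (image_name, volume)."""
    volume = np.asarray(volume, dtype=float)
    if kind == "wavelet":
        return _wavelet(volume, wavelet)
    if kind == "log":
        return _log_filter(volume, spacing, log_sigmas)
    if kind == "square":
        return [("square", _square(volume))]
    if kind == "squareroot":
        return [("squareroot", _squareroot(volume))]
    if kind == "logarithm":
        return [("logarithm", _logarithm(volume))]
    if kind == "exponential":
        return [("exponential", _exponential(volume))]
    if kind == "gradient":
        return [("gradient", _gradient(volume, spacing))]
    raise ValueError(f"unknown filter kind {kind!r}; choose from {FILTER_KINDS}")


def all_filtered_images(volume, spacing, log_sigmas=DEFAULT_LOG_SIGMAS,
                        wavelet=DEFAULT_WAVELET) -> list[tuple[str, np.ndarray]]:
    """The 18 derived images, in stable order."""
    out = []
    for kind in FILTER_KINDS:
        out.extend(filter_image(volume, kind, spacing, log_sigmas, wavelet))
    return out
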