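"""setMag reconstruction and image preprocessing.

A multi-echo gradient-echo (QSM-type) acquisition yields one magnitude
volume per echo time (TE).  The short-echo-time magnitude image
("setMag") — the voxelwise combination of the three shortest-TE
magnitude volumes — retains mostly T1-weighted contrast and is
sensitive to neuromelanin in the substantia nigra pars compacta.

This module reconstructs setMag volumes, resamples them to a common
voxel grid, normalizes intensities, and provides the patch-level
contrast enhancement (grayscale inversion followed by histogram
equalization) applied to brainstem crops before they enter the CNN.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "EchoMagnitudeSeries",
    "SetMagVolume",
    "reconstruct_setmag",
    "resample",
    "normalize_intensity",
    "invert_gray",
    "equalize_hist",
    "load_nifti",
    "save_nifti",
]

DEFAULT_TARGET_SPACING = (0.5, 0.5, 1.0)  # mm, in-plane x2 upsampling typical


@dataclass
class EchoMagnitudeSeries:
    """Per-echo 3D magnitude volumes of a multi-echo acquisition.

    Parameters
    ----------
    volumes : list of ndarray
        One 3D magnitude array per echo, all the same shape.
    echo_times : sequence of float
        Echo times in milliseconds, one per volume.
    voxel_spacing : tuple of float
        Voxel size in mm along each axis.
    """

    volumes: list[np.ndarray]
    echo_times: tuple[float, ...]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.volumes = [np.asarray(v, dtype=float) for v in self.volumes]
        self.echo_times = tuple(float(t) for t in self.echo_times)
        if len(self.volumes) != len(self.echo_times):
            raise ValueError("one echo time per volume required")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError(f"echo volumes differ in shape: {shapes}")

    @property
    def n_echoes(self) -> int:
        return len(self.volumes)


@dataclass
class SetMagVolume:
    """A single 3D neuromelanin-sensitive volume with voxel spacing."""

    intensity: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensity.shape


def reconstruct_setmag(series: EchoMagnitudeSeries) -> SetMagVolume:
    """Combine the three shortest-TE magnitude volumes into a setMag volume.

    The combination operator is the voxelwise arithmetic mean, which
    preserves the intensity scale of the inputs.  Echo order in the
    series is irrelevant: the three smallest echo times are located
    explicitly.
    """
    if series.n_echoes < 3:
        raise ValueError(f"need at least 3 echoes, got {series.n_echoes}")
    order = np.argsort(series.echo_times, kind="stable")[:3]
    combined = np.mean([series.volumes[i] for i in order], axis=0)
    return SetMagVolume(combined, series.voxel_spacing)


def resample(
    volume: SetMagVolume,
    target_spacing: tuple[float, float, float] = DEFAULT_TARGET_SPACING,
) -> SetMagVolume:
    """Resample to `target_spacing` (mm) with nearest-neighbor interpolation.

    Nearest-neighbor is used so that resampling a label mask through the
    same code path introduces no new values.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"spacings must be positive, got {target_spacing}")
    if target_spacing == tuple(volume.voxel_spacing):
        return SetMagVolume(volume.intensity.copy(), volume.voxel_spacing)
    zoom = [src / tgt for src, tgt in zip(volume.voxel_spacing, target_spacing)]
    out = ndimage.zoom(volume.intensity, zoom, order=0, mode="nearest", prefilter=False)
    return SetMagVolume(out, target_spacing)


def normalize_intensity(volume: SetMagVolume) -> SetMagVolume:
    """Min-max scale intensities to [0, 1]. Errors on a constant volume."""
    lo = float(volume.intensity.min())
    hi = float(volume.intensity.max())
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant volume")
    return SetMagVolume((volume.intensity - lo) / (hi - lo), volume.voxel_spacing)


def invert_gray(patch: np.ndarray) -> np.ndarray:
    """Grayscale inversion: subtract every pixel from the patch maximum.

    On the inverted image the (dark) neuromelanin-depleted regions become
    bright, broadening the effective gray-level distribution of the
    mostly-dark brainstem crop.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty patch")
    return patch.max() - patch


def equalize_hist(patch: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """Global cumulative-histogram equalization over `n_levels` gray levels.

    The patch is quantized to ``n_levels`` bins spanning its range; each
    bin is remapped through the normalized cumulative distribution.  The
    output takes integer levels in ``[0, n_levels - 1]`` and preserves
    the rank order of the input pixel values (ties allowed).
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty patch")
    lo, hi = float(patch.min()), float(patch.max())
    if hi == lo:
        return np.zeros_like(patch)
    levels = np.minimum(
        ((patch - lo) / (hi - lo) * n_levels).astype(int), n_levels - 1
    )
    hist = np.bincount(levels.ravel(), minlength=n_levels)
    cdf = np.cumsum(hist).astype(float)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom == 0:  # single occupied bin
        return np.zeros_like(patch)
    mapping = np.round((cdf - cdf_min) / denom * (n_levels - 1))
    return mapping[levels].astype(float)


def load_nifti(path: str) -> SetMagVolume:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SetMagVolume(np.asarray(img.dataobj, dtype=float), spacing)


def save_nifti(volume: SetMagVolume, path: str) -> None:
    affine = np.diag(list(volume.voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.intensity.astype(np.float32), affine), path)
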