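"""Full-profile radiomics extraction for one case.

The default configuration yields exactly 1781 named features:

* original image: 18 first-order + 14 shape + 24 GLCM + 16 GLRLM
  + 16 GLSZM + 14 GLDM + 5 NGTDM = 107;
* 18 filtered images (8 wavelet sub-bands, 5 LoG sigmas, square,
  square root, logarithm, exponential, gradient), each contributing
  the 93 non-shape features: 18 x 93 = 1674.

Shape is geometric and therefore computed once, on the original mask
only.  The LoG sigma list {1..5} mm is the package's choice; together
with the 8 wavelet sub-bands and the 5 remaining single-output filters
it is the unique count that closes the 107 + 18 x 93 = 1781
decomposition.

Feature names follow the "<image>_<family>_<feature>" convention,
e.g. ``original_glcm_Contrast`` or ``wavelet-LLH_firstorder_Mean``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..preprocess import SetMagVolume
from .filters import DEFAULT_LOG_SIGMAS, DEFAULT_WAVELET, all_filtered_images
from .firstorder import first_order_features
from .shape import shape_features
from .texture import (
    discretize,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["ExtractionConfig", "RadiomicsFeatureRow", "extract_all", "feature_table"]

EXPECTED_N_FEATURES = 1781


@dataclass(frozen=True)
class ExtractionConfig:
    bin_width: float = 25.0
    log_sigmas: tuple[float, ...] = DEFAULT_LOG_SIGMAS
    wavelet: str = DEFAULT_WAVELET
    padding: tuple[int, int, int] = (10, 10, 2)  # crop margin around the mask


@dataclass
class RadiomicsFeatureRow:
    case_id: str
    values: dict[str, float]  # insertion-ordered, stable across cases

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.case_id)


def _crop_to_mask(intensity, mask, padding):
    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - p) for i, p in zip(idx, padding)]
    hi = [
        min(n, int(i.max()) + p + 1)
        for i, p, n in zip(idx, padding, mask.shape)
    ]
    window = tuple(slice(a, b) for a, b in zip(lo, hi))
    return intensity[window], mask[window]


def _texture_block(intensity, mask, bin_width):
    roi = discretize(intensity, mask, bin_width)
    return {
        "glcm": glcm_features(roi),
        "glrlm": glrlm_features(roi),
        "glszm": glszm_features(roi),
        "gldm": gldm_features(roi),
        "ngtdm": ngtdm_features(roi),
    }


def extract_all(
    volume: SetMagVolume,
    mask: np.ndarray,
    config: ExtractionConfig | None = None,
    case_id: str = "",
) -> RadiomicsFeatureRow:
    """Extract the full 1781-feature profile of one (volume, mask) pair."""
    config = config or ExtractionConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    spacing = volume.voxel_spacing
    voxel_volume = float(np.prod(spacing))
    crop, crop_mask = _crop_to_mask(volume.intensity, mask, config.padding)

    row: dict[str, float] = {}

    def add(image, family, feats):
        for name, value in feats.items():
            row[f"{image}_{family}_{name}"] = float(value)

    add("original", "firstorder",
        first_order_features(crop[crop_mask], voxel_volume, config.bin_width))
    add("original", "shape", shape_features(crop_mask, spacing))
    for family, feats in _texture_block(crop, crop_mask, config.bin_width).items():
        add("original", family, feats)

    for image_name, filtered in all_filtered_images(
        crop, spacing, config.log_sigmas, config.wavelet
    ):
        add(image_name, "firstorder",
            first_order_features(filtered[crop_mask], voxel_volume, config.bin_width))
        for family, feats in _texture_block(filtered, crop_mask, config.bin_width).items():
            add(image_name, family, feats)

    assert len(row) == EXPECTED_N_FEATURES, f"feature count {len(row)}"
    return RadiomicsFeatureRow(case_id, row)


def feature_table(rows: list[RadiomicsFeatureRow]) -> pd.DataFrame:
    """Stack per-case rows into a (cases x features) DataFrame."""
    df = pd.DataFrame([r.values for r in rows], index=[r.case_id for r in rows])
    df.index.name = "case_id"
    return df
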