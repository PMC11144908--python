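"""Brainstem localization and 40x40x4 patch extraction.

The classification CNN consumes a fixed 40 x 40 crop of the brainstem
on each of 4 contiguous axial slices.  Localization is done by a small
convolutional center regressor: the (min-max normalized, 2x
average-pooled) slice passes through two valid 5x5 convolutions to a
single-channel heatmap, a spatial softmax turns the heatmap into a
probability map, and the predicted center is its expected coordinate
(soft-argmax).  Training minimizes squared error to the true box
center.  An intensity-centroid heuristic is available when no model
has been trained.

Crops are clamped (never padded) at image borders so the downstream
contrast enhancement never sees artificial zero margins.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from . import nn
from .preprocess import SetMagVolume, equalize_hist, invert_gray

__all__ = [
    "PATCH_SIZE",
    "BrainstemBox",
    "PatchStack",
    "DetectorModel",
    "train_detector",
    "detect_brainstem",
    "heuristic_detect",
    "iou",
]

PATCH_SIZE = 40
_DS = 2  # average-pool factor fed to the regressor
_CONV_OFFSET = 4  # two valid 5x5 convs shift coordinates by 2 + 2


@dataclass(frozen=True)
class BrainstemBox:
    """A fixed-size axial bounding box, stored by center."""

    slice_index: int
    center_row: float
    center_col: float
    height: int = PATCH_SIZE
    width: int = PATCH_SIZE

    @classmethod
    def clamped(cls, slice_index: int, center_row: float, center_col: float,
                slice_shape: tuple[int, int]) -> "BrainstemBox":
        """Shift the center so the box lies fully inside the slice."""
        h, w = PATCH_SIZE, PATCH_SIZE
        cr = float(np.clip(center_row, h / 2, slice_shape[0] - h / 2))
        cc = float(np.clip(center_col, w / 2, slice_shape[1] - w / 2))
        return cls(slice_index, cr, cc)

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open."""
        r0 = int(round(self.center_row - self.height / 2))
        c0 = int(round(self.center_col - self.width / 2))
        return r0, r0 + self.height, c0, c0 + self.width


@dataclass
class PatchStack:
    """The 4 preprocessed 40x40 brainstem patches of one case."""

    case_id: str
    patches: np.ndarray  # (4, 40, 40)
    source_boxes: list[BrainstemBox]

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        if self.patches.shape != (4, PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"expected (4, {PATCH_SIZE}, {PATCH_SIZE}), got {self.patches.shape}"
            )
        if not np.all(np.isfinite(self.patches)):
            raise ValueError("patch intensities must be finite")


def iou(a: BrainstemBox, b: BrainstemBox) -> float:
    """Intersection-over-union of two boxes on the same slice."""
    if a.slice_index != b.slice_index:
        raise ValueError("boxes lie on different slices")
    ar0, ar1, ac0, ac1 = a.bounds
    br0, br1, bc0, bc1 = b.bounds
    ih = max(0, min(ar1, br1) - max(ar0, br0))
    iw = max(0, min(ac1, bc1) - max(ac0, bc0))
    inter = ih * iw
    union = a.height * a.width + b.height * b.width - inter
    return inter / union


def _normalize_slice(sl: np.ndarray) -> np.ndarray:
    lo, hi = sl.min(), sl.max()
    return (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)


def _downsample(sl: np.ndarray, f: int = _DS) -> np.ndarray:
    h, w = sl.shape
    return sl[: h - h % f, : w - w % f].reshape(h // f, f, w // f, f).mean(axis=(1, 3))


@dataclass
class DetectorModel:
    """Two-conv heatmap regressor with soft-argmax readout."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    seed: int = 0
    loss_curve: list[float] = field(default_factory=list)
    trained: bool = False

    @classmethod
    def initialize(cls, seed: int, n_hidden: int = 8) -> "DetectorModel":
        rng = np.random.default_rng(seed)
        w1, b1 = nn.init_conv(rng, n_hidden, 1, 5)
        w2, b2 = nn.init_conv(rng, 1, n_hidden, 5)
        return cls(w1, b1, w2, b2, seed=seed)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, self.b2]

    def _forward(self, x: np.ndarray):
        """x: (n, 1, h, w) downsampled slices -> predicted (row, col) per item."""
        h1, c1 = nn.conv_forward(x, self.w1, self.b1)
        a1, m1 = nn.relu_forward(h1)
        heat, c2 = nn.conv_forward(a1, self.w2, self.b2)
        n, _, hh, hw = heat.shape
        flat = heat.reshape(n, hh * hw)
        p = nn.softmax(flat)
        rows = np.arange(hh).repeat(hw).astype(float)
        cols = np.tile(np.arange(hw), hh).astype(float)
        pred = np.stack([p @ rows, p @ cols], axis=1)  # heatmap coords
        cache = (c1, m1, c2, p, rows, cols, heat.shape)
        return pred, cache

    def _backward(self, dpred: np.ndarray, cache):
        c1, m1, c2, p, rows, cols, heat_shape = cache
        # soft-argmax: d pred_r / d p_i = rows_i, so dL/dp = dr*rows + dc*cols,
        # then softmax Jacobian: dlogit = p * (dL/dp - sum(p * dL/dp))
        dLdp = dpred[:, 0:1] * rows[None, :] + dpred[:, 1:2] * cols[None, :]
        inner = (p * dLdp).sum(axis=1, keepdims=True)
        dflat = p * (dLdp - inner)
        dheat = dflat.reshape(heat_shape)
        da1, dw2, db2 = nn.conv_backward(dheat, c2)
        dh1 = nn.relu_backward(da1, m1)
        _, dw1, db1 = nn.conv_backward(dh1, c1)
        return [dw1, db1, dw2, db2]

    def predict_center(self, sl: np.ndarray) -> tuple[float, float]:
        """Predicted (row, col) center in full-resolution slice coordinates."""
        if not self.trained:
            raise ValueError("detector has not been trained")
        x = _downsample(_normalize_slice(np.asarray(sl, dtype=float)))[None, None]
        pred, _ = self._forward(x)
        r, c = pred[0]
        return (
            (r + _CONV_OFFSET) * _DS + (_DS - 1) / 2,
            (c + _CONV_OFFSET) * _DS + (_DS - 1) / 2,
        )

    def save(self, path: str) -> None:
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 w1=self.w1, b1=self.b1, w2=self.w2, b2=self.b2)
        sidecar = {
            "seed": self.seed, "trained": self.trained,
            "loss_curve": self.loss_curve, "downsample": _DS,
        }
        with open(os.path.splitext(path)[0] + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "DetectorModel":
        arrs = np.load(path if path.endswith(".npz") else path + ".npz")
        with open(os.path.splitext(path)[0] + ".json") as fh:
            meta = json.load(fh)
        model = cls(arrs["w1"], arrs["b1"], arrs["w2"], arrs["b2"],
                    seed=meta["seed"], loss_curve=meta["loss_curve"])
        model.trained = meta["trained"]
        return model


def _training_samples(cases) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for case in cases:
        from .preprocess import reconstruct_setmag

        vol = reconstruct_setmag(case.echoes).intensity
        for z, (cr, cc) in case.true_box_per_slice.items():
            xs.append(_downsample(_normalize_slice(vol[:, :, z])))
            # invert the coordinate map used at prediction time
            ys.append([
                (cr - (_DS - 1) / 2) / _DS - _CONV_OFFSET,
                (cc - (_DS - 1) / 2) / _DS - _CONV_OFFSET,
            ])
    return np.asarray(xs)[:, None], np.asarray(ys, dtype=float)


def train_detector(cases, seed: int = 0, epochs: int = 60,
                   batch_size: int = 16, lr: float = 2e-3) -> DetectorModel:
    """Fit the center regressor on synthetic cases with known boxes."""
    if len(cases) == 0:
        raise ValueError("empty training set")
    x, y = _training_samples(cases)
    model = DetectorModel.initialize(seed)
    opt = nn.Adam(model.params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    n = x.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            pred, cache = model._forward(x[idx])
            err = pred - y[idx]
            losses.append(float((err**2).mean()))
            grads = model._backward(2 * err / err.size, cache)
            opt.step(grads)
        model.loss_curve.append(float(np.mean(losses)))
    model.trained = True
    return model


def heuristic_detect(volume: SetMagVolume, slice_index: int) -> BrainstemBox:
    """Model-free fallback: intensity centroid of the upper half of the
    slice's Otsu foreground (the brainstem sits anterior to the cerebellum
    on axial slices through the midbrain)."""
    sl = volume.intensity[:, :, slice_index]
    if not np.any(sl > 0):
        raise ValueError(f"slice {slice_index} is entirely zero")
    fg = sl > threshold_otsu(sl) if sl.min() < sl.max() else sl > 0
    rows = np.nonzero(fg.any(axis=1))[0]
    mid = (rows.min() + rows.max()) / 2
    upper = fg & (np.arange(sl.shape[0])[:, None] <= mid)
    if not upper.any():
        upper = fg
    weights = sl * upper
    total = weights.sum()
    cr = float((weights.sum(axis=1) @ np.arange(sl.shape[0])) / total)
    cc = float((weights.sum(axis=0) @ np.arange(sl.shape[1])) / total)
    return BrainstemBox.clamped(slice_index, cr, cc, sl.shape)


def detect_brainstem(volume: SetMagVolume, slices, model: DetectorModel | None,
                     case_id: str = "") -> PatchStack:
    """Crop, enhance and stack the 4 brainstem patches of one volume.

    Each patch is the 40x40 crop centered at the predicted brainstem
    center (clamped inside the slice), then grayscale-inverted and
    histogram-equalized.
    """
    slices = list(slices)
    if len(slices) != 4:
        raise ValueError(f"exactly 4 slice indices required, got {len(slices)}")
    nz = volume.shape[2]
    if any(z < 0 or z >= nz for z in slices):
        raise ValueError(f"slice index out of range for volume with {nz} slices")
    patches, boxes = [], []
    for z in slices:
        if model is not None:
            cr, cc = model.predict_center(volume.intensity[:, :, z])
            box = BrainstemBox.clamped(z, cr, cc, volume.shape[:2])
        else:
            box = heuristic_detect(volume, z)
        r0, r1, c0, c1 = box.bounds
        crop = volume.intensity[r0:r1, c0:c1, z]
        patches.append(equalize_hist(invert_gray(crop)))
        boxes.append(box)
    return PatchStack(case_id, np.stack(patches), boxes)
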