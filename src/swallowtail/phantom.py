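"""Synthetic midbrain phantom generator.

Produces multi-echo magnitude series with the statistical structure the
classification pipeline assumes, so every downstream stage (setMag
reconstruction, brainstem detection, radiomics, CNN, fusion,
evaluation) is testable without patient data.

Each synthetic case renders, on a dark background:

* a bright midbrain ellipsoid;
* bilateral hyperintense SNpc crescents spanning exactly 4 contiguous
  axial slices (the slab a rater would delineate);
* a dorsolateral "swallow-tail" hyperintensity inside each crescent —
  the nigrosome-1 analogue.  In the PD class its intensity uplift is
  multiplied by an attenuation factor and the crescent area is shrunk,
  emulating neuromelanin loss;
* multi-echo T2* signal decay S(TE) = S0 * exp(-TE / T2*), so the three
  shortest-TE volumes are the brightest;
* Rician noise (magnitude of a complex Gaussian perturbation);
* an optional second-rater mask obtained by random boundary jitter,
  for ICC / Dice reproducibility testing.

All outputs are pure functions of (params, seed).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import EchoMagnitudeSeries, SetMagVolume, save_nifti

__all__ = [
    "PhantomParams",
    "SyntheticCase",
    "generate_case",
    "generate_cohort",
    "perturb_mask",
    "write_cohort",
]

HC, PD = "HC", "PD"

# tissue T2* (ms) and proton-density-like base signal, loosely iron-rich
# midbrain values at 3T; contrast, not quantitative accuracy, is the goal
_T2STAR = {"background": 40.0, "midbrain": 35.0, "snpc": 30.0}
_S0 = {"background": 150.0, "midbrain": 420.0, "snpc": 700.0}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, contrast and noise knobs of the synthetic phantom.

    The disease effect has two components: `swallowtail_attenuation_pd`
    multiplies the swallow-tail intensity uplift, and
    `snpc_area_shrink_pd` scales the in-plane crescent area; both apply
    to PD cases only.  The defaults give a cohort that a simple
    intensity threshold can separate almost perfectly in the noiseless
    limit, guaranteeing downstream models have signal to find.
    """

    volume_shape: tuple[int, int, int] = (96, 96, 16)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    n_echoes: int = 5
    echo_times: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)
    midbrain_center: tuple[int, int, int] = (48, 48, 8)
    midbrain_axes: tuple[int, int, int] = (16, 20, 6)
    snpc_offset: tuple[int, int] = (4, 9)  # (posterior rows, lateral cols)
    snpc_axes: tuple[int, int] = (6, 8)  # in-plane semi-axes, voxels
    snpc_slices: int = 4  # contiguous axial slices carrying the ROI
    swallowtail_contrast_hc: float = 220.0  # S0 uplift inside the tail
    swallowtail_attenuation_pd: float = 0.5
    snpc_area_shrink_pd: float = 0.8
    noise_sigma: float = 6.0
    jitter_amplitude: float = 0.6  # second-rater boundary jitter, voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.echo_times) != self.n_echoes:
            raise ValueError("echo_times length must equal n_echoes")
        if any(b <= a for a, b in zip(self.echo_times, self.echo_times[1:])):
            raise ValueError("echo_times must be strictly increasing")
        if not (0.0 <= self.swallowtail_attenuation_pd <= 1.0):
            raise ValueError("swallowtail_attenuation_pd must be in [0, 1]")
        if not (0.0 < self.snpc_area_shrink_pd <= 1.0):
            raise ValueError("snpc_area_shrink_pd must be in (0, 1]")
        cr, cc, cz = self.midbrain_center
        ar, ac, az = self.midbrain_axes
        nr, nc, nz = self.volume_shape
        lateral = self.snpc_offset[1] + self.snpc_axes[1]
        if not (
            0 <= cr - ar and cr + ar < nr
            and 0 <= cc - ac and cc + ac < nc
            and 0 <= cz - az and cz + az < nz
            and cc - lateral >= 0 and cc + lateral < nc
            and cr + self.snpc_offset[0] + self.snpc_axes[0] < nr
        ):
            raise ValueError("phantom geometry does not fit inside volume_shape")
        z0 = cz - self.snpc_slices // 2
        if z0 < 0 or z0 + self.snpc_slices > nz:
            raise ValueError("SNpc slice slab falls outside the volume")


@dataclass
class SyntheticCase:
    """One simulated subject: echo series, masks, label, and true boxes."""

    case_id: str
    echoes: EchoMagnitudeSeries
    snpc_mask: np.ndarray
    rater2_mask: np.ndarray
    swallowtail_mask: np.ndarray
    label: str
    true_box_per_slice: dict[int, tuple[int, int]]  # slice -> (center_row, center_col)

    @property
    def mask_slices(self) -> list[int]:
        return sorted(np.unique(np.nonzero(self.snpc_mask)[2]).tolist())


def _ellipse2d(shape, center, axes):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _crescent(shape, center, axes, side):
    """Posterior crescent: an ellipse with its anterior core removed."""
    outer = _ellipse2d(shape, center, axes)
    notch_center = (center[0] - 0.9 * axes[0], center[1] - side * 0.25 * axes[1])
    inner = _ellipse2d(shape, notch_center, (axes[0] * 1.05, axes[1] * 0.9))
    crescent = outer & ~inner
    return crescent if crescent.any() else outer


def _render_case(params: PhantomParams, label: str, rng: np.random.Generator):
    """Noiseless S0 / T2* maps plus masks for one subject."""
    nr, nc, nz = params.volume_shape
    cr, cc, cz = params.midbrain_center
    # per-subject anatomical variability
    jr, jc = rng.integers(-2, 3, size=2)
    gain = float(rng.normal(1.0, 0.03))
    cr, cc = cr + int(jr), cc + int(jc)

    s0 = np.full(params.volume_shape, _S0["background"])
    t2s = np.full(params.volume_shape, _T2STAR["background"])

    rr, ccg, zz = np.ogrid[:nr, :nc, :nz]
    ar, ac, az = params.midbrain_axes
    midbrain = (
        ((rr - cr) / ar) ** 2 + ((ccg - cc) / ac) ** 2 + ((zz - cz) / az) ** 2
    ) <= 1.0
    s0[midbrain] = _S0["midbrain"]
    t2s[midbrain] = _T2STAR["midbrain"]

    shrink = params.snpc_area_shrink_pd if label == PD else 1.0
    axes = (
        params.snpc_axes[0] * np.sqrt(shrink),
        params.snpc_axes[1] * np.sqrt(shrink),
    )
    uplift = params.swallowtail_contrast_hc * (
        params.swallowtail_attenuation_pd if label == PD else 1.0
    )

    mask = np.zeros(params.volume_shape, dtype=bool)
    tail = np.zeros(params.volume_shape, dtype=bool)
    z0 = cz - params.snpc_slices // 2
    row0 = cr + params.snpc_offset[0]
    for z in range(z0, z0 + params.snpc_slices):
        for side in (-1, 1):
            col0 = cc + side * params.snpc_offset[1]
            cres = _crescent((nr, nc), (row0, col0), axes, side)
            mask[:, :, z] |= cres
            # dorsolateral sector of the crescent = swallow-tail analogue;
            # the sector boundaries use the unshrunk geometry so the PD
            # area shrink carries through to the rendered tail
            lateral = (np.arange(nc)[None, :] - cc) * side > (
                params.snpc_offset[1] + 0.25 * params.snpc_axes[1]
            )
            posterior = np.arange(nr)[:, None] > row0 - 0.2 * params.snpc_axes[0]
            tail[:, :, z] |= cres & lateral & posterior

    s0[mask] = _S0["snpc"]
    t2s[mask] = _T2STAR["snpc"]
    s0[tail] += uplift
    s0 *= gain

    boxes = {int(z): (int(cr), int(cc)) for z in range(z0, z0 + params.snpc_slices)}
    return s0, t2s, mask, tail, boxes


def generate_case(params: PhantomParams, label: str, seed: int) -> SyntheticCase:
    """Render one synthetic subject; deterministic for fixed (params, seed)."""
    if label not in (HC, PD):
        raise ValueError(f"label must be {HC!r} or {PD!r}, got {label!r}")
    rng = np.random.default_rng(seed)
    s0, t2s, mask, tail, boxes = _render_case(params, label, rng)

    volumes = []
    for te in params.echo_times:
        signal = s0 * np.exp(-te / t2s)
        if params.noise_sigma > 0:
            re = signal + rng.normal(0.0, params.noise_sigma, signal.shape)
            im = rng.normal(0.0, params.noise_sigma, signal.shape)
            signal = np.hypot(re, im)  # Rician magnitude noise
        volumes.append(signal)
    echoes = EchoMagnitudeSeries(volumes, params.echo_times, params.voxel_spacing)

    rater2 = perturb_mask(
        mask, seed=int(rng.integers(0, 2**31)), amplitude=params.jitter_amplitude
    )
    return SyntheticCase(
        case_id=f"case-{seed:08d}",
        echoes=echoes,
        snpc_mask=mask,
        rater2_mask=rater2,
        swallowtail_mask=tail,
        label=label,
        true_box_per_slice=boxes,
    )


def generate_cohort(
    n_hc: int, n_pd: int, params: PhantomParams | None = None, seed: int = 0
) -> list[SyntheticCase]:
    """Generate `n_hc` + `n_pd` cases with per-case seeds derived from `seed`."""
    if n_hc < 0 or n_pd < 0:
        raise ValueError("cohort sizes must be non-negative")
    params = params or PhantomParams()
    labels = [HC] * n_hc + [PD] * n_pd
    cases = []
    for i, label in enumerate(labels):
        case_seed = int(
            np.random.SeedSequence(params.seed + seed, spawn_key=(i,)).generate_state(1)[0]
            % 2**31
        )
        case = generate_case(params, label, case_seed)
        case.case_id = f"{label.lower()}-{i:04d}"
        cases.append(case)
    return cases


def perturb_mask(mask: np.ndarray, seed: int, amplitude: float = 0.6) -> np.ndarray:
    """Jitter a mask's boundary, emulating a second rater's delineation.

    Per mask-bearing slice, the signed Euclidean distance to the
    boundary is perturbed by a smooth Gaussian random field of the given
    amplitude (voxels) and re-thresholded.  Amplitude 0 returns the mask
    unchanged; the default amplitude yields Dice overlap in roughly
    [0.85, 0.98] on the default phantom.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot perturb an empty mask")
    if amplitude == 0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    out = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        # signed distance: positive inside, negative outside
        dist = ndimage.distance_transform_edt(sl) - ndimage.distance_transform_edt(~sl)
        bump = ndimage.gaussian_filter(rng.normal(0.0, 1.0, sl.shape), sigma=3.0)
        bump *= amplitude / max(bump.std(), 1e-12)
        jittered = dist + bump > 0.5
        out[:, :, z] = jittered if jittered.any() else sl
    return out


def write_cohort(cases: list[SyntheticCase], out_dir: str) -> str:
    """Write setMag-ready echo volumes and masks as NIfTI plus a CSV manifest.

    Returns the manifest path.  Echo volumes are stored as one 4D NIfTI
    per case (echo along the 4th axis).
    """
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "echoes", "mask", "rater2_mask"])
        for case in cases:
            spacing = case.echoes.voxel_spacing
            affine = np.diag(list(spacing) + [1.0])
            stack = np.stack(case.echoes.volumes, axis=-1).astype(np.float32)
            paths = {
                "echoes": f"{case.case_id}_echoes.nii.gz",
                "mask": f"{case.case_id}_mask.nii.gz",
                "rater2_mask": f"{case.case_id}_rater2.nii.gz",
            }
            nib.save(nib.Nifti1Image(stack, affine), os.path.join(out_dir, paths["echoes"]))
            for key in ("mask", "rater2_mask"):
                arr = case.snpc_mask if key == "mask" else case.rater2_mask
                nib.save(
                    nib.Nifti1Image(arr.astype(np.uint8), affine),
                    os.path.join(out_dir, paths[key]),
                )
            writer.writerow([case.case_id, case.label, paths["echoes"], paths["mask"], paths["rater2_mask"]])
    return manifest
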