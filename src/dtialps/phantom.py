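"""Voxel-level DWI phantoms with ALPS-compatible fiber geometry.

The phantom emulates a slab at the level of the body of the lateral
ventricles, where the ALPS method is defined. Axis convention (RAS+,
enforced everywhere in this package):

- x: left-right — the perivascular direction of the medullary veins;
- y: anterior-posterior — the dominant direction of association fibers;
- z: superior-inferior — the dominant direction of projection fibers.

Each hemisphere carries a projection-fiber band (largest diagonal
diffusivity on z), an association-fiber band (largest on y), a CSF-filled
ventricle box, and optionally a spherical tumor with a peritumoral-edema
shell. Glymphatic impairment is modelled by scaling the x-axis
diffusivity inside the fiber bands by a perivascular factor alpha < 1.

Signal generation uses the single-tensor Stejskal-Tanner forward model
S = S0 * exp(-b g^T D g), with optional Rician noise
|S + n_re + i n_im|, n ~ N(0, sigma), sigma = S0 / SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from dtialps.acquisition import GradientTable

# Integer labels emitted in the region mask.
LABELS = {
    "background": 0,
    "gm": 1,
    "projection": 2,
    "association": 3,
    "csf": 4,
    "tumor": 5,
    "ptbe": 6,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

# Region diffusion tensors, diagonal, mm^2/s. Fiber bands are prolate with
# the long axis along the fiber direction; the ventricle is free-water-like.
DEFAULT_TENSORS: dict[str, tuple[float, float, float]] = {
    "gm": (0.8e-3, 0.8e-3, 0.8e-3),
    "projection": (0.6e-3, 0.45e-3, 1.5e-3),  # long axis z
    "association": (0.6e-3, 1.5e-3, 0.45e-3),  # long axis y
    "csf": (3.0e-3, 3.0e-3, 3.0e-3),
    "tumor": (1.0e-3, 1.0e-3, 1.0e-3),
    "ptbe": (1.6e-3, 1.6e-3, 1.6e-3),
}


def _box(lo: tuple[int, int, int], hi: tuple[int, int, int]) -> tuple:
    """0-based, half-open voxel box."""
    return (tuple(int(v) for v in lo), tuple(int(v) for v in hi))


@dataclass
class PhantomSpec:
    """Geometry, tissue tensors, and noise settings of the DWI phantom.

    Defaults give a 64x64x16 grid at 2x2x4 mm (4 mm slices as in the
    acquisition protocol): small enough for seconds-scale tests. Boxes are
    0-based half-open voxel-index ranges ((x0,y0,z0),(x1,y1,z1)).
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 4.0)  # mm

    brain_box: tuple = field(default_factory=lambda: _box((4, 4, 1), (60, 60, 16)))
    # per-hemisphere structures; left = low x indices under RAS with the
    # subject supine is actually subject-right, but the package labels sides
    # by array halves and keeps the convention consistent throughout.
    ventricle_boxes: dict = field(
        default_factory=lambda: {
            "left": _box((24, 24, 6), (31, 40, 10)),
            "right": _box((33, 24, 6), (40, 40, 10)),
        }
    )
    projection_boxes: dict = field(
        default_factory=lambda: {
            "left": _box((14, 20, 4), (20, 48, 12)),
            "right": _box((44, 20, 4), (50, 48, 12)),
        }
    )
    association_boxes: dict = field(
        default_factory=lambda: {
            "left": _box((6, 20, 4), (12, 48, 12)),
            "right": _box((52, 20, 4), (58, 48, 12)),
        }
    )
    tumor_center: tuple[int, int, int] | None = None  # voxel index
    tumor_radius_mm: float = 6.0
    ptbe_radius_mm: float = 12.0  # edema shell outer radius; excludes tumor

    tensors: dict = field(default_factory=lambda: dict(DEFAULT_TENSORS))
    alpha_left: float = 1.0  # perivascular Dxx multiplier, left fiber bands
    alpha_right: float = 1.0
    s0: float = 1000.0
    snr: float | None = None  # None = noiseless; else Rician sigma = s0/snr
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_left <= 0 or self.alpha_right <= 0:
            raise ValueError("perivascular factor alpha must be > 0")
        for name, d in self.tensors.items():
            if np.any(np.asarray(d) <= 0):
                raise ValueError(f"diffusivities must be > 0 (region {name!r})")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("SNR must be > 0 or None")

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine: positive diagonal voxel scaling, volume centered."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        aff[:3, 3] = -0.5 * np.array(self.shape) * np.array(self.voxel_size)
        return aff

    def with_tumor(self, center: tuple[int, int, int] = (16, 11, 8)) -> "PhantomSpec":
        """Return a copy carrying the default left-hemisphere tumor."""
        import dataclasses

        return dataclasses.replace(self, tumor_center=center)


@dataclass
class DwiVolume:
    """4D diffusion-weighted signal (x, y, z, volume) with affine + gradients."""

    signal: np.ndarray
    affine: np.ndarray
    gtab: GradientTable

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[3] != len(self.gtab):
            raise ValueError("4th dimension must match gradient-table length")
        if np.any(self.signal < 0):
            raise ValueError("signals must be nonnegative")


def _fill_box(arr: np.ndarray, box: tuple, value: int) -> None:
    (x0, y0, z0), (x1, y1, z1) = box
    arr[x0:x1, y0:y1, z0:z1] = value


def build_label_volume(spec: PhantomSpec) -> np.ndarray:
    """Region labels on the phantom grid; raises on tumor/ventricle overlap."""
    lab = np.zeros(spec.shape, dtype=np.int16)
    _fill_box(lab, spec.brain_box, LABELS["gm"])
    for side in ("left", "right"):
        _fill_box(lab, spec.projection_boxes[side], LABELS["projection"])
        _fill_box(lab, spec.association_boxes[side], LABELS["association"])
    for side in ("left", "right"):
        _fill_box(lab, spec.ventricle_boxes[side], LABELS["csf"])

    if spec.tumor_center is not None:
        ii = np.indices(spec.shape).astype(float)
        vox = np.asarray(spec.voxel_size)
        center = np.asarray(spec.tumor_center, dtype=float)
        dist = np.sqrt(sum(((ii[k] - center[k]) * vox[k]) ** 2 for k in range(3)))
        tumor = dist <= spec.tumor_radius_mm
        ptbe = (dist <= spec.ptbe_radius_mm) & ~tumor
        if np.any(tumor & (lab == LABELS["csf"])):
            raise ValueError("tumor region overlaps the ventricle; adjust geometry")
        inside_brain = lab != LABELS["background"]
        lab[ptbe & inside_brain] = LABELS["ptbe"]
        lab[tumor & inside_brain] = LABELS["tumor"]
    return lab


def region_tensor(spec: PhantomSpec, region: str, side: str | None = None) -> np.ndarray:
    """3x3 diagonal tensor of a region, with alpha applied to fiber-band Dxx."""
    dxx, dyy, dzz = spec.tensors[region]
    if region in ("projection", "association") and side is not None:
        alpha = spec.alpha_left if side == "left" else spec.alpha_right
        dxx = dxx * alpha
    return np.diag([dxx, dyy, dzz])


def ground_truth_tensors(spec: PhantomSpec) -> np.ndarray:
    """Per-voxel generating tensors as an (X,Y,Z,3,3) array (background 0)."""
    lab = build_label_volume(spec)
    midline = spec.shape[0] // 2
    out = np.zeros(spec.shape + (3, 3))
    xs = np.arange(spec.shape[0])
    side_of_x = np.where(xs < midline, "left", "right")
    for name, code in LABELS.items():
        if name == "background":
            continue
        sel = lab == code
        if not np.any(sel):
            continue
        if name in ("projection", "association"):
            for side in ("left", "right"):
                sel_side = sel & (side_of_x == side)[:, None, None]
                out[sel_side] = region_tensor(spec, name, side)
        else:
            out[sel] = region_tensor(spec, name)
    return out


def synthesize_dwi(spec: PhantomSpec, gtab: GradientTable) -> tuple[DwiVolume, "LabelMask"]:
    """Forward-simulate the DWI signal and return it with the region mask.

    Noiseless signal is S0 * exp(-b g^T D g) per voxel; background voxels
    have zero signal. With finite SNR, Rician noise is applied as the
    magnitude of a complex Gaussian perturbation with sigma = S0/SNR.
    Deterministic for a fixed spec.seed.
    """
    from dtialps.volumetrics import LabelMask

    lab = build_label_volume(spec)
    tensors = ground_truth_tensors(spec)

    b = gtab.bvals
    g = gtab.bvecs
    # quadratic form b * g^T D g for every voxel/volume
    bq = b * np.einsum("ni,xyzij,nj->xyzn", g, tensors, g, optimize=True)
    signal = spec.s0 * np.exp(-bq)
    signal[lab == LABELS["background"]] = 0.0

    if spec.snr is not None:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        noise_re = rng.normal(0.0, sigma, signal.shape)
        noise_im = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + noise_re) ** 2 + noise_im**2)

    dwi = DwiVolume(signal, spec.affine, gtab)
    mask = LabelMask(lab, spec.affine, dict(LABEL_NAMES))
    return dwi, mask


# ---------------------------------------------------------------------------
# NIfTI I/O

def write_dwi(dwi: DwiVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(dwi.signal.astype(np.float32), dwi.affine), str(path))


def read_dwi(path: str | Path, gtab: GradientTable) -> DwiVolume:
    img = nib.load(str(path))
    return DwiVolume(np.asarray(img.dataobj, dtype=float), img.affine, gtab)
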