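"""The DTI-ALPS index: fiber-region VOIs and the diffusivity ratio.

At the level of the lateral-ventricle body, medullary-vein perivascular
spaces run left-right (x), perpendicular to both the projection fibers
(superior-inferior, z) and the association fibers (anterior-posterior, y).
Water diffusivity measured along x inside those fiber regions is therefore
dominated by perivascular flow, and the index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

compares it against the fiber-perpendicular diffusivities that share no
perivascular component. An index near 1 means no preferential x-axis
diffusion; higher values mean stronger perivascular-direction diffusion.

VOIs here are 0-based half-open voxel boxes, by default 2x2 voxels
in-plane on a single designated slice (a literal reading of a "4-voxel"
VOI), with configurable edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dtialps.phantom import LABELS
from dtialps.tensorfit import TensorField

SIDES = ("left", "right")
FIBERS = ("projection", "association")


@dataclass(frozen=True)
class Voi:
    """In-plane square VOI: center voxel (x, y), edge length, slice index."""

    center_xy: tuple[int, int]
    edge: int = 2
    slice_index: int = 0

    def box(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """0-based half-open ((x0,y0,z0),(x1,y1,z1))."""
        cx, cy = self.center_xy
        half_lo = self.edge // 2
        x0, y0 = cx - half_lo, cy - half_lo
        return (x0, y0, self.slice_index), (x0 + self.edge, y0 + self.edge, self.slice_index + 1)

    @property
    def n_voxels(self) -> int:
        return self.edge * self.edge

    def slicer(self) -> tuple[slice, slice, slice]:
        (x0, y0, z0), (x1, y1, z1) = self.box()
        return (slice(x0, x1), slice(y0, y1), slice(z0, z1))


@dataclass
class AlpsVoiSet:
    """The four ALPS VOIs: {projection, association} per hemisphere."""

    vois: dict  # {"left": {"projection": Voi, "association": Voi}, "right": {...}}

    def __post_init__(self) -> None:
        for side in SIDES:
            if side not in self.vois:
                raise ValueError(f"missing hemisphere {side!r}")
            for fiber in FIBERS:
                if fiber not in self.vois[side]:
                    raise ValueError(f"missing {fiber!r} VOI on side {side!r}")
                if self.vois[side][fiber].n_voxels < 4:
                    raise ValueError("each VOI must contain at least 4 voxels")
        for side in SIDES:
            a = set(_voxels(self.vois[side]["projection"]))
            b = set(_voxels(self.vois[side]["association"]))
            if a & b:
                raise ValueError(f"projection and association VOIs overlap on side {side!r}")

    def __getitem__(self, side: str) -> dict:
        return self.vois[side]

    def to_json(self, path: str | Path) -> None:
        rows = [
            {
                "side": side,
                "fiber": fiber,
                "slice": v.slice_index,
                "center_xy": list(v.center_xy),
                "edge": v.edge,
            }
            for side in SIDES
            for fiber, v in self.vois[side].items()
        ]
        Path(path).write_text(json.dumps(rows, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AlpsVoiSet":
        rows = json.loads(Path(path).read_text())
        vois: dict = {s: {} for s in SIDES}
        for r in rows:
            vois[r["side"]][r["fiber"]] = Voi(tuple(r["center_xy"]), r["edge"], r["slice"])
        return cls(vois)


def _voxels(voi: Voi):
    (x0, y0, z0), (x1, y1, z1) = voi.box()
    return [(x, y, z) for x in range(x0, x1) for y in range(y0, y1) for z in range(z0, z1)]


@dataclass
class AlpsResult:
    """Per-hemisphere VOI-mean diffusivities, indices, and the bilateral mean."""

    diffusivities: dict  # {side: {"dxx_proj":..., "dxx_assoc":..., "dyy_proj":..., "dzz_assoc":...}}
    index_by_side: dict  # {"left": float, "right": float}
    bilateral_mean: float
    side_labels: dict  # {"left": "tumor"|"contralateral"|"left", ...}

    @property
    def tumor_side_index(self) -> float | None:
        for side, lab in self.side_labels.items():
            if lab == "tumor":
                return self.index_by_side[side]
        return None

    @property
    def contralateral_index(self) -> float | None:
        for side, lab in self.side_labels.items():
            if lab == "contralateral":
                return self.index_by_side[side]
        return None


def _voi_mean(tf: TensorField, voi: Voi, component: str) -> float:
    (x0, y0, z0), (x1, y1, z1) = voi.box()
    shape = tf.mask.shape
    if x0 < 0 or y0 < 0 or z0 < 0 or x1 > shape[0] or y1 > shape[1] or z1 > shape[2]:
        raise ValueError(f"VOI {voi} extends outside the volume {shape}")
    sl = voi.slicer()
    if not np.all(tf.mask[sl]):
        raise ValueError(f"VOI {voi} contains voxels outside the fit mask")
    vals = tf.component(component)[sl]
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        voxel = (x0 + int(bad[0]), y0 + int(bad[1]), z0 + int(bad[2]))
        raise ValueError(f"non-finite {component} at voxel {voxel}")
    return float(vals.mean())


def extract_voi_diffusivities(tf: TensorField, vois: AlpsVoiSet) -> dict:
    """VOI-mean diffusivities per hemisphere.

    Returns ``{side: {dxx_proj, dxx_assoc, dyy_proj, dzz_assoc}}`` in
    mm^2/s: Dxx over both VOIs, Dyy over the projection VOI, Dzz over the
    association VOI.
    """
    out = {}
    for side in SIDES:
        proj, assoc = vois[side]["projection"], vois[side]["association"]
        out[side] = {
            "dxx_proj": _voi_mean(tf, proj, "Dxx"),
            "dxx_assoc": _voi_mean(tf, assoc, "Dxx"),
            "dyy_proj": _voi_mean(tf, proj, "Dyy"),
            "dzz_assoc": _voi_mean(tf, assoc, "Dzz"),
        }
    return out


def alps_index(dxx_proj: float, dxx_assoc: float, dyy_proj: float, dzz_assoc: float) -> float:
    """mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    for v in (dxx_proj, dxx_assoc, dyy_proj, dzz_assoc):
        if not np.isfinite(v):
            raise ValueError("non-finite diffusivity passed to alps_index")
    denom = 0.5 * (dyy_proj + dzz_assoc)
    if denom <= 0:
        raise ValueError(f"nonpositive denominator mean ({denom:g}): unphysical fit")
    return 0.5 * (dxx_proj + dxx_assoc) / denom


def subject_alps(
    tf: TensorField,
    vois: AlpsVoiSet,
    tumor_side: str | None = None,
) -> AlpsResult:
    """Per-hemisphere ALPS indices, side labels, and the bilateral mean.

    ``tumor_side`` is ``"left"``/``"right"`` for patients (labels the two
    hemispheres tumor / contralateral) or None for controls (labels stay
    left / right).
    """
    if tumor_side not in (None, "left", "right"):
        raise ValueError("tumor_side must be 'left', 'right', or None")
    diff = extract_voi_diffusivities(tf, vois)
    idx = {
        side: alps_index(d["dxx_proj"], d["dxx_assoc"], d["dyy_proj"], d["dzz_assoc"])
        for side, d in diff.items()
    }
    if tumor_side is None:
        labels = {"left": "left", "right": "right"}
    else:
        other = "right" if tumor_side == "left" else "left"
        labels = {tumor_side: "tumor", other: "contralateral"}
    bilateral = 0.5 * (idx["left"] + idx["right"])
    return AlpsResult(diff, idx, bilateral, labels)


def average_results(results: list[AlpsResult]) -> AlpsResult:
    """Combine multiple readers' VOI sets by averaging resulting indices."""
    if not results:
        raise ValueError("no results to average")
    idx = {
        side: float(np.mean([r.index_by_side[side] for r in results])) for side in SIDES
    }
    diff = {
        side: {
            k: float(np.mean([r.diffusivities[side][k] for r in results]))
            for k in results[0].diffusivities[side]
        }
        for side in SIDES
    }
    return AlpsResult(diff, idx, 0.5 * (idx["left"] + idx["right"]), results[0].side_labels)


def auto_place_vois(label_volume: np.ndarray, edge: int = 2, slice_index: int | None = None) -> AlpsVoiSet:
    """Place VOIs at the fiber-band centroids of a phantom label mask.

    Picks the slice with the most fiber-band voxels unless given, then
    centers one VOI on each band's in-plane centroid per hemisphere.
    Intended for phantoms; on real data VOIs are reader-supplied.
    """
    midline = label_volume.shape[0] // 2
    band = (label_volume == LABELS["projection"]) | (label_volume == LABELS["association"])
    if slice_index is None:
        slice_index = int(np.argmax(band.sum(axis=(0, 1))))
    vois: dict = {s: {} for s in SIDES}
    for side, xsel in (("left", slice(0, midline)), ("right", slice(midline, None))):
        for fiber in FIBERS:
            sel = np.zeros_like(label_volume, dtype=bool)
            sel[xsel] = label_volume[xsel] == LABELS[fiber]
            coords = np.argwhere(sel[:, :, slice_index])
            if coords.size == 0:
                raise ValueError(f"no {fiber} voxels on side {side!r} at slice {slice_index}")
            cx, cy = np.round(coords.mean(axis=0)).astype(int)
            vois[side][fiber] = Voi((int(cx), int(cy)), edge, slice_index)
    return AlpsVoiSet(vois)
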