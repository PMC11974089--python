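"""CSF, tumor, and peritumoral-edema volumes from label masks.

Segmentation itself (tissue classification, manual tumor/edema
delineation) is an input here: the module owns only the volumetry.
Volume of a label = voxel count x |det of the 3x3 affine block| in mm^3,
reported in cm^3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

# canonical label names used by subject_volumes
CSF, TUMOR, PTBE = "csf", "tumor", "ptbe"


@dataclass
class LabelMask:
    """Integer 3D label volume with affine and a {code: name} dictionary."""

    data: np.ndarray
    affine: np.ndarray
    labels: dict  # {int code: str name}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if np.any(self.data < 0):
            raise ValueError("labels must be nonnegative")
        present = set(np.unique(self.data).tolist()) - {0}
        known = set(int(k) for k in self.labels)
        missing = present - known
        if missing:
            raise ValueError(f"label dictionary does not cover values {sorted(missing)}")

    def code_of(self, name: str) -> int | None:
        for code, nm in self.labels.items():
            if nm == name:
                return int(code)
        return None

    @property
    def voxel_volume_mm3(self) -> float:
        m = np.asarray(self.affine)[:3, :3]
        off = m - np.diag(np.diag(m))
        if np.any(np.abs(off) > 1e-9 * max(1.0, np.abs(m).max())):
            warnings.warn(
                "affine has shear/rotation; volume computed from the determinant",
                stacklevel=2,
            )
        return float(abs(np.linalg.det(m)))


def mask_volume(mask: LabelMask, label: int) -> float:
    """Volume of one label in cm^3."""
    if int(label) not in {int(k) for k in mask.labels}:
        raise ValueError(f"label {label} absent from the label dictionary")
    count = int(np.count_nonzero(mask.data == int(label)))
    return count * mask.voxel_volume_mm3 / 1000.0


@dataclass
class SubjectVolumes:
    csf_cm3: float
    tumor_cm3: float
    ptbe_cm3: float
    control_like: bool  # no tumor/PTBE labels present


def subject_volumes(mask: LabelMask) -> SubjectVolumes:
    """CSF, tumor, and PTBE volumes for one subject's label mask.

    The CSF label must exist; tumor/PTBE labels are optional (controls),
    yielding zero volumes and ``control_like=True``. Overlapping tumor and
    PTBE voxels (possible in hand-edited data) trigger a warning, and the
    PTBE volume excludes the overlap (edema is defined exclusive of tumor).
    """
    csf_code = mask.code_of(CSF)
    if csf_code is None:
        raise ValueError("mask has no 'csf' label")
    tumor_code = mask.code_of(TUMOR)
    ptbe_code = mask.code_of(PTBE)

    csf = mask_volume(mask, csf_code)
    tumor = mask_volume(mask, tumor_code) if tumor_code is not None else 0.0
    ptbe = mask_volume(mask, ptbe_code) if ptbe_code is not None else 0.0
    control_like = (tumor_code is None or tumor == 0.0) and (ptbe_code is None or ptbe == 0.0)
    return SubjectVolumes(csf, tumor, ptbe, control_like)


def load_label_mask(nifti_path: str | Path, labels_json: str | Path) -> LabelMask:
    """Read an integer NIfTI label volume plus its JSON label dictionary.

    If both tumor and PTBE labels are present and any voxel carries the
    tumor label inside a separately-supplied PTBE mask this cannot happen
    in a single-label volume, but the exclusivity rule is still enforced
    semantically in :func:`subject_volumes`.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj).astype(np.int32)
    labels = {int(k): v for k, v in json.loads(Path(labels_json).read_text()).items()}
    return LabelMask(data, img.affine, labels)


def write_label_mask(mask: LabelMask, nifti_path: str | Path, labels_json: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.int16), mask.affine), str(nifti_path))
    if labels_json is not None:
        Path(labels_json).write_text(
            json.dumps({str(k): v for k, v in mask.labels.items()}, indent=2) + "\n"
        )


def synthetic_volume_mask(
    csf_cm3: float,
    tumor_cm3: float = 0.0,
    ptbe_cm3: float = 0.0,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 4.0),
    shape: tuple[int, int, int] = (48, 48, 24),
) -> LabelMask:
    """Synthetic label mask realizing requested volumes (to the voxel).

    Fills disjoint voxel runs with each label until the rounded voxel
    count matching each requested volume is reached; used to exercise the
    volumetric path on simulated subjects for whom no image exists.
    """
    vox_mm3 = float(np.prod(voxel_size))
    counts = {
        2: int(round(1000.0 * csf_cm3 / vox_mm3)),
        3: int(round(1000.0 * tumor_cm3 / vox_mm3)),
        4: int(round(1000.0 * ptbe_cm3 / vox_mm3)),
    }
    total = sum(counts.values())
    if total > int(np.prod(shape)):
        raise ValueError("requested volumes exceed the mask grid")
    flat = np.zeros(int(np.prod(shape)), dtype=np.int16)
    pos = 0
    for code, n in counts.items():
        flat[pos : pos + n] = code
        pos += n
    affine = np.diag(list(voxel_size) + [1.0])
    labels = {1: "gm", 2: CSF, 3: TUMOR, 4: PTBE}
    return LabelMask(flat.reshape(shape), affine, labels)
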