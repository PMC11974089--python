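"""Per-voxel diffusion tensor estimation and scalar maps.

Fits the log-linearized single-tensor model

    ln S = ln S0 - b (gx^2 Dxx + gy^2 Dyy + gz^2 Dzz
                      + 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz)

by ordinary least squares over all volumes, optionally followed by one
weighted pass with weights equal to the squared predicted signal (the
classic WLS correction for the log transform). The diagonal elements
Dxx/Dyy/Dzz are reported in the scanner frame — not eigenvalues — which
is what the ALPS index consumes.

Negative fitted diagonal values are deliberately kept as-is (clamping
would bias ALPS ratios); eigenvalues are clamped at zero only when
computing FA/MD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from dtialps.acquisition import GradientTable, design_matrix
from dtialps.phantom import DwiVolume

COMPONENT_NAMES = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorField:
    """Per-voxel symmetric tensor components in mm^2/s.

    ``components`` has shape (X, Y, Z, 6), ordered Dxx, Dyy, Dzz, Dxy,
    Dxz, Dyz; ``ln_s0`` the fitted log baseline; ``mask`` the fitted
    voxels (components are zero outside).
    """

    components: np.ndarray
    ln_s0: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.components.shape[:3] != self.mask.shape:
            raise ValueError("component array shape must match mask shape")
        if self.components.shape[-1] != 6:
            raise ValueError("expected 6 tensor components per voxel")
        if not np.all(np.isfinite(self.components[self.mask])):
            raise ValueError("non-finite tensor components inside mask")

    def component(self, name: str) -> np.ndarray:
        return self.components[..., COMPONENT_NAMES.index(name)]

    @property
    def tensor_3x3(self) -> np.ndarray:
        """(X, Y, Z, 3, 3) symmetric tensors."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.components, -1, 0)
        t = np.empty(self.components.shape[:3] + (3, 3))
        t[..., 0, 0] = dxx
        t[..., 1, 1] = dyy
        t[..., 2, 2] = dzz
        t[..., 0, 1] = t[..., 1, 0] = dxy
        t[..., 0, 2] = t[..., 2, 0] = dxz
        t[..., 1, 2] = t[..., 2, 1] = dyz
        return t

    def scaled(self, c: float) -> "TensorField":
        return TensorField(self.components * c, self.ln_s0.copy(), self.affine.copy(), self.mask.copy())


@dataclass
class ScalarMaps:
    """FA, MD, principal eigenvector and direction-encoded color per voxel."""

    fa: np.ndarray
    md: np.ndarray
    principal_direction: np.ndarray  # (X, Y, Z, 3), unit norm where defined
    color: np.ndarray  # |e1| * FA, (X, Y, Z, 3)
    affine: np.ndarray


def _check_design(gtab: GradientTable) -> np.ndarray:
    x = design_matrix(gtab)
    if gtab.n_directions < 6:
        raise ValueError("need at least 6 nonzero-b directions")
    if np.linalg.matrix_rank(x) < 7:
        dirs = gtab.bvecs[gtab.bvals > 0]
        raise ValueError(
            "rank-deficient diffusion design matrix; offending direction set:\n"
            f"{np.array2string(dirs, precision=4)}"
        )
    return x


def fit_tensor(
    dwi: DwiVolume,
    mask: np.ndarray | None = None,
    method: str = "wls",
) -> TensorField:
    """Estimate the diffusion tensor per voxel by OLS or one-pass WLS.

    Parameters
    ----------
    dwi:
        The 4D signal with its gradient table.
    mask:
        Boolean fit mask; defaults to voxels whose mean b=0 signal is
        positive. Signals are clamped at 1e-6 of the voxel's b=0 level
        before the log.
    method:
        ``"ols"`` for plain least squares, ``"wls"`` (default) for one
        reweighted pass with weights = squared predicted signal.
    """
    if method not in ("ols", "wls"):
        raise ValueError(f"unknown method {method!r}")
    x = _check_design(dwi.gtab)
    signal = dwi.signal
    s0_obs = signal[..., dwi.gtab.b0_mask].mean(axis=-1)
    if mask is None:
        mask = s0_obs > 0
    mask = np.asarray(mask, dtype=bool)

    y_sig = signal[mask]  # (V, N)
    floor = 1e-6 * np.maximum(s0_obs[mask], np.finfo(float).tiny)[:, None]
    y = np.log(np.maximum(y_sig, floor))

    # OLS via a shared pseudoinverse
    theta = y @ np.linalg.pinv(x).T  # (V, 7)

    if method == "wls":
        w = np.exp(2.0 * (theta @ x.T))  # squared predicted signal
        xtw = x.T[None, :, :] * w[:, None, :]  # (V, 7, N)
        a = xtw @ x  # (V, 7, 7)
        rhs = np.einsum("vpn,vn->vp", xtw, y)
        theta = np.linalg.solve(a, rhs[..., None])[..., 0]

    comps = np.zeros(signal.shape[:3] + (6,))
    ln_s0 = np.zeros(signal.shape[:3])
    comps[mask] = theta[:, 1:]
    ln_s0[mask] = theta[:, 0]

    n_neg = int(np.sum(np.any(theta[:, 1:4] < 0, axis=1)))
    if n_neg:
        warnings.warn(
            f"{n_neg} voxels have negative fitted diagonal diffusivities; "
            "kept unclamped for ALPS extraction",
            stacklevel=2,
        )
    return TensorField(comps, ln_s0, dwi.affine, mask)


def scalar_maps(tf: TensorField) -> ScalarMaps:
    """Eigendecomposition-derived maps; eigenvalues clamped at 0 for FA/MD.

    Degenerate (all-zero) tensors yield FA = 0 by convention.
    """
    tens = tf.tensor_3x3
    evals, evecs = np.linalg.eigh(tens)  # ascending eigenvalues
    evals = np.clip(evals, 0.0, None)
    md = evals.mean(axis=-1)
    lam_norm = np.linalg.norm(evals, axis=-1)
    dev = evals - md[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / lam_norm
    fa = np.where(lam_norm > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    e1 = evecs[..., :, -1]
    color = np.abs(e1) * fa[..., None]
    return ScalarMaps(fa, md, e1, color, tf.affine)


# ---------------------------------------------------------------------------
# NIfTI I/O

def write_tensor(tf: TensorField, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(tf.components.astype(np.float32), tf.affine), str(path))


def write_map(arr: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))


def read_tensor(path: str | Path, mask: np.ndarray | None = None) -> TensorField:
    img = nib.load(str(path))
    comps = np.asarray(img.dataobj, dtype=float)
    if mask is None:
        mask = np.any(comps != 0, axis=-1)
    return TensorField(comps, np.zeros(comps.shape[:3]), img.affine, np.asarray(mask, bool))
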