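"""Diffusion sensitization schemes (b-values and gradient directions).

The gradient table is shared between the forward signal simulator and the
tensor fitter, mirroring an FSL-style acquisition: one or more b=0 volumes
followed by diffusion-weighted volumes with unit direction vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions, one row per volume.

    b=0 volumes carry a zero direction vector. Directions of nonzero-b
    volumes must be unit norm to 1e-6.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(f"bvecs shape {bvecs.shape} does not match {bvals.size} bvals")
        if np.any(bvals < 0):
            raise ValueError("b-values must be nonnegative")
        if not np.any(bvals == 0):
            raise ValueError("gradient table needs at least one b=0 volume")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("nonzero-b directions must be unit vectors (tol 1e-6)")

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def n_directions(self) -> int:
        return int(np.count_nonzero(self.bvals > 0))

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


def make_gradient_table(
    n_directions: int,
    b: float = 1000.0,
    n_b0: int = 1,
    seed: int = 0,
) -> GradientTable:
    """Build a gradient table with approximately uniform directions.

    Directions are placed on a Fibonacci spiral over the upper hemisphere
    (antipodal directions are equivalent for diffusion encoding, so a
    hemisphere gives better effective coverage) and then rotated by a
    seeded random rotation, which keeps the scheme deterministic per seed
    while decoupling it from the coordinate axes.

    Parameters
    ----------
    n_directions:
        Number of diffusion-weighted directions; at least 6 (the symmetric
        tensor has 6 unknowns).
    b:
        Diffusion weighting in s/mm^2 for the weighted volumes.
    n_b0:
        Number of leading unweighted volumes.
    seed:
        Seed for the random rotation.
    """
    if n_directions < 6:
        raise ValueError(
            f"n_directions={n_directions} < 6: the diffusion tensor is underdetermined"
        )
    if n_b0 < 1:
        raise ValueError("need at least one b=0 volume")

    k = np.arange(n_directions)
    z = (k + 0.5) / n_directions  # upper hemisphere, excludes exact pole/equator
    r = np.sqrt(1.0 - z**2)
    phi = k * _GOLDEN_ANGLE
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix, sign-fixed for determinism
    q, rmat = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(rmat))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    dirs = dirs @ q.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-linear design matrix: columns [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz] for unknowns
    [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = gtab.bvals
    gx, gy, gz = gtab.bvecs.T
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


# ---------------------------------------------------------------------------
# FSL-dialect I/O: bvals one space-separated row; bvecs three rows (x, y, z).

def write_bval_bvec(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    Path(bval_path).write_text(" ".join(f"{v:g}" for v in gtab.bvals) + "\n")
    rows = [" ".join(f"{v:.8f}" for v in gtab.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_bval_bvec(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    # renormalize against text round-off
    nz = bvals > 0
    norms = np.linalg.norm(bvecs[nz], axis=1)
    bvecs = bvecs.copy()
    bvecs[nz] /= norms[:, None]
    return GradientTable(bvals, bvecs)
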