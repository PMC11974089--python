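"""Shared fixtures: gradient tables, fitted phantoms, and small cohorts.

Expensive phantom synthesis + tensor fits are session-scoped and reused
across test modules.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from dtialps.acquisition import GradientTable, make_gradient_table
from dtialps.alps import auto_place_vois
from dtialps.phantom import PhantomSpec, synthesize_dwi
from dtialps.tensorfit import fit_tensor


@pytest.fixture(scope="session")
def gtab48() -> GradientTable:
    """The study acquisition: b=1000 s/mm^2, 48 directions, one b=0."""
    return make_gradient_table(48, 1000.0, 1, seed=7)


@pytest.fixture(scope="session")
def axis_gtab() -> GradientTable:
    """b=0 plus the three coordinate axes and three diagonal directions."""
    s = 1.0 / np.sqrt(2.0)
    bvecs = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [s, s, 0],
            [s, 0, s],
            [0, s, s],
        ]
    )
    return GradientTable(np.array([0.0] + [1000.0] * 6), bvecs)


@pytest.fixture(scope="session")
def noiseless_phantom(gtab48):
    """Default noiseless phantom: (spec, dwi, label mask)."""
    spec = PhantomSpec()
    dwi, lab = synthesize_dwi(spec, gtab48)
    return spec, dwi, lab


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_phantom):
    """(spec, TensorField, label mask) from an OLS fit of the noiseless phantom."""
    spec, dwi, lab = noiseless_phantom
    tf = fit_tensor(dwi, lab.data > 0, method="ols")
    return spec, tf, lab


@pytest.fixture(scope="session")
def alpha_sweep_fits(gtab48):
    """Noiseless fits at perivascular factors 1.0 / 0.8 / 0.6 (both sides)."""
    out = {}
    for alpha in (1.0, 0.8, 0.6):
        spec = PhantomSpec(alpha_left=alpha, alpha_right=alpha)
        dwi, lab = synthesize_dwi(spec, gtab48)
        out[alpha] = (spec, fit_tensor(dwi, lab.data > 0, method="ols"), lab)
    return out


@pytest.fixture(scope="session")
def asymmetric_fit(gtab48):
    """Noiseless fit with impairment (alpha=0.7) on the left side only."""
    spec = PhantomSpec(alpha_left=0.7, alpha_right=1.0)
    dwi, lab = synthesize_dwi(spec, gtab48)
    return spec, fit_tensor(dwi, lab.data > 0, method="ols"), lab


@pytest.fixture(scope="session")
def noisy_fit(gtab48):
    """SNR=30 Rician phantom and its WLS fit: (spec, TensorField, labels)."""
    spec = PhantomSpec(snr=30.0, seed=11)
    dwi, lab = synthesize_dwi(spec, gtab48)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tf = fit_tensor(dwi, lab.data > 0, method="wls")
    return spec, tf, lab


@pytest.fixture(scope="session")
def phantom_vois(noiseless_phantom):
    _, _, lab = noiseless_phantom
    return auto_place_vois(lab.data)
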