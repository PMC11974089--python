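"""Simulated glioma/control cohorts with the published group structure.

The generator emulates a study of 112 glioma patients (35 low-grade, 77
high-grade) and 56 healthy controls, reproducing, in population:

- group marginals of the bilateral-mean ALPS index (glioma 1.266 +- 0.258,
  control 1.395 +- 0.174) and CSF volume (174.53 +- 34.89 vs
  154.25 +- 20.89 cm^3);
- the paired hemispheric structure of patients: tumor-side ALPS
  1.233 +- 0.297 vs contralateral 1.299 +- 0.296. The within-subject
  difference is N(0.066, 0.292^2); 0.292 is the unique difference-SD
  consistent with all three printed SDs (it implies an inter-hemisphere
  correlation of 0.51);
- rank correlations among ALPS, tumor volume and PTBE volume
  (-0.353, -0.266, +0.427) through a Gaussian copula, with log-normal
  tumor/PTBE marginals parameterized from the printed median (IQR)
  (29.77 (36.79) and 37.48 (65.11) cm^3);
- a linear structural model for the patient ALPS index on standardized
  grade, age and Olig-2 with multivariate standardized coefficients
  (-0.244, -0.20, -0.22) and predictor correlations (-0.142, +0.029,
  +0.285), solved so the population univariate correlations equal
  (-0.222, -0.228, -0.284) and the implied LGG/HGG means are 1.351/1.227.

Categorical structure (sex 63/49 vs 29/27, tumor side 60/42/10, IDH 36/76,
type 44/14/54) is assigned by exact-count permutation. Ki-67 is log-normal
median 20 (IQR 25) %.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

Z75 = float(sps.norm.ppf(0.75))


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR.

    Closed form: with q = IQR/median and u = (q + sqrt(q^2+4))/2,
    sigma = ln(u)/z_0.75 and mu = ln(median).
    """
    if median <= 0 or iqr <= 0:
        raise ValueError("median and IQR must be positive")
    q = iqr / median
    u = 0.5 * (q + np.sqrt(q * q + 4.0))
    return float(np.log(median)), float(np.log(u) / Z75)


def spearman_to_latent(rho_s: float) -> float:
    """Latent Gaussian-copula Pearson correlation for a Spearman target."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass
class CohortSpec:
    """Population parameters of the simulated cohort (study defaults)."""

    # sample sizes
    n_glioma: int = 112
    n_lgg: int = 35
    n_control: int = 56

    # bilateral-mean ALPS marginals
    glioma_alps_mean: float = 1.266
    glioma_alps_sd: float = 0.258
    control_alps_mean: float = 1.395
    control_alps_sd: float = 0.174

    # paired hemispheric model: difference = contralateral - tumor side
    paired_shift: float = 0.066
    paired_sd: float = 0.292
    control_paired_sd: float = 0.20  # left/right difference SD, controls

    # CSF volume (cm^3), Gaussian
    glioma_csf_mean: float = 174.53
    glioma_csf_sd: float = 34.89
    control_csf_mean: float = 154.25
    control_csf_sd: float = 20.89

    # log-normal marginals as (median, IQR)
    tumor_vol_median_iqr: tuple[float, float] = (29.77, 36.79)
    ptbe_vol_median_iqr: tuple[float, float] = (37.48, 65.11)
    ki67_median_iqr: tuple[float, float] = (20.0, 25.0)

    # demographics
    glioma_age_mean: float = 52.8
    glioma_age_sd: float = 13.1
    control_age_mean: float = 53.4
    control_age_sd: float = 10.7
    glioma_n_female: int = 49
    control_n_female: int = 27
    side_counts: tuple[int, int, int] = (60, 42, 10)  # left, right, both
    n_idh_mutant: int = 36
    type_counts: tuple[int, int, int] = (44, 14, 54)  # astro, oligo, glioblastoma

    # Spearman rank-correlation targets of the Gaussian copula
    rho_alps_tumor: float = -0.353
    rho_alps_ptbe: float = -0.266
    rho_tumor_ptbe: float = 0.427
    rho_alps_csf: float = 0.0
    rho_tumor_csf: float = 0.0
    rho_ptbe_csf: float = 0.0

    # structural model of the patient ALPS index (standardized scale)
    beta_grade: float = -0.244
    beta_age: float = -0.20
    beta_olig2: float = -0.22
    r_grade_age: float = -0.142
    r_grade_olig2: float = 0.029
    r_age_olig2: float = 0.285

    # Olig-2 immunopositivity marginal (%), linear in the latent predictor
    olig2_mean: float = 50.0
    olig2_sd: float = 20.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "glioma_alps_sd",
            "control_alps_sd",
            "paired_sd",
            "control_paired_sd",
            "glioma_csf_sd",
            "control_csf_sd",
            "glioma_age_sd",
            "control_age_sd",
            "olig2_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.n_lgg <= self.n_glioma):
            raise ValueError("n_lgg must lie in [0, n_glioma]")
        if sum(self.side_counts) != self.n_glioma:
            raise ValueError("side_counts must sum to n_glioma")
        if sum(self.type_counts) != self.n_glioma:
            raise ValueError("type_counts must sum to n_glioma")
        self.copula_matrix()  # validates positive definiteness
        pr = self.predictor_corr()
        ev = np.linalg.eigvalsh(pr)
        if ev.min() <= 0:
            raise ValueError(f"predictor correlation matrix not positive definite (eigenvalue {ev.min():.4g})")

    def copula_matrix(self) -> np.ndarray:
        """Latent 4x4 correlation matrix over (ALPS, tumor, PTBE, CSF)."""
        m = np.eye(4)
        pairs = {
            (0, 1): self.rho_alps_tumor,
            (0, 2): self.rho_alps_ptbe,
            (1, 2): self.rho_tumor_ptbe,
            (0, 3): self.rho_alps_csf,
            (1, 3): self.rho_tumor_csf,
            (2, 3): self.rho_ptbe_csf,
        }
        for (i, j), rho in pairs.items():
            m[i, j] = m[j, i] = spearman_to_latent(rho)
        ev = np.linalg.eigvalsh(m)
        if ev.min() <= 0:
            raise ValueError(
                f"copula correlation matrix not positive definite (offending eigenvalue {ev.min():.6g})"
            )
        return m

    def predictor_corr(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.r_grade_age, self.r_grade_olig2],
                [self.r_grade_age, 1.0, self.r_age_olig2],
                [self.r_grade_olig2, self.r_age_olig2, 1.0],
            ]
        )


@dataclass
class SubjectRecord:
    """One simulated subject (one row of the cohort table)."""

    id: str
    group: str  # glioma | control
    grade: str | None  # LGG | HGG | None
    idh: str | None  # mutant | wildtype | None
    glioma_type: str | None  # astrocytoma | oligodendroglioma | glioblastoma | None
    age: float
    sex: str  # male | female
    tumor_side: str | None  # left | right | both | None
    alps_tumor_side: float | None
    alps_contralateral: float | None
    alps_mean: float
    alps_left: float
    alps_right: float
    csf_volume_cm3: float
    tumor_volume_cm3: float | None
    ptbe_volume_cm3: float | None
    ki67_pct: float | None
    olig2_pct: float | None

    def __post_init__(self) -> None:
        if self.alps_mean <= 0:
            raise ValueError("ALPS values must be positive")
        for v in (self.csf_volume_cm3, self.tumor_volume_cm3, self.ptbe_volume_cm3):
            if v is not None and v < 0:
                raise ValueError("volumes must be nonnegative")


def _permuted_counts(rng: np.random.Generator, pairs: list[tuple[str, int]]) -> np.ndarray:
    vals = np.concatenate([np.full(n, v, dtype=object) for v, n in pairs])
    return rng.permutation(vals)


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw one cohort; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []

    # ---- glioma group -----------------------------------------------------
    n = spec.n_glioma
    grade = _permuted_counts(rng, [("LGG", spec.n_lgg), ("HGG", n - spec.n_lgg)])
    # glioblastomas are all high-grade; astro/oligo fill the rest
    n_astro, n_oligo, n_gbm = spec.type_counts
    gtype = np.empty(n, dtype=object)
    hgg_idx = np.flatnonzero(grade == "HGG")
    lgg_idx = np.flatnonzero(grade == "LGG")
    n_gbm_eff = min(n_gbm, hgg_idx.size)
    gbm_slots = rng.choice(hgg_idx, size=n_gbm_eff, replace=False)
    gtype[gbm_slots] = "glioblastoma"
    rest = np.array([i for i in range(n) if gtype[i] is None])
    pool = _permuted_counts(rng, [("astrocytoma", n_astro), ("oligodendroglioma", n_oligo)])
    gtype[rest] = pool[: rest.size]

    idh = _permuted_counts(rng, [("mutant", spec.n_idh_mutant), ("wildtype", n - spec.n_idh_mutant)])
    sex = _permuted_counts(rng, [("female", spec.glioma_n_female), ("male", n - spec.glioma_n_female)])
    side = _permuted_counts(
        rng, [("left", spec.side_counts[0]), ("right", spec.side_counts[1]), ("both", spec.side_counts[2])]
    )

    # standardized predictors with the configured correlation structure;
    # grade is the (exact-count) standardized binary, age and Olig-2 fill in
    # via the Cholesky factor of the predictor correlation matrix.
    p_hgg = (n - spec.n_lgg) / n
    sd_g = np.sqrt(p_hgg * (1 - p_hgg))
    g_std = (np.asarray(grade == "HGG", dtype=float) - p_hgg) / sd_g
    chol = np.linalg.cholesky(spec.predictor_corr())
    u_a, u_o = rng.standard_normal(n), rng.standard_normal(n)
    a_std = chol[1, 0] * g_std + chol[1, 1] * u_a
    o_std = chol[2, 0] * g_std + chol[2, 1] * u_a + chol[2, 2] * u_o

    age = spec.glioma_age_mean + spec.glioma_age_sd * a_std
    olig2 = np.clip(spec.olig2_mean + spec.olig2_sd * o_std, 0.0, 100.0)

    c = np.array([spec.beta_grade, spec.beta_age, spec.beta_olig2])
    r_pred = spec.predictor_corr()
    resid_var = 1.0 - float(c @ r_pred @ c)
    if resid_var <= 0:
        raise ValueError("structural coefficients explain more than total variance")
    z_alps = c[0] * g_std + c[1] * a_std + c[2] * o_std + np.sqrt(resid_var) * rng.standard_normal(n)
    alps_mean = spec.glioma_alps_mean + spec.glioma_alps_sd * z_alps

    # volumes conditional on the ALPS latent through the Gaussian copula
    sigma = spec.copula_matrix()
    s_va = sigma[1:, 0]  # correlations of (tumor, ptbe, csf) with ALPS
    s_vv = sigma[1:, 1:] - np.outer(s_va, s_va)
    chol_v = np.linalg.cholesky(s_vv)
    eta = rng.standard_normal((n, 3))
    z_vol = z_alps[:, None] * s_va[None, :] + eta @ chol_v.T
    mu_t, sg_t = lognormal_from_median_iqr(*spec.tumor_vol_median_iqr)
    mu_p, sg_p = lognormal_from_median_iqr(*spec.ptbe_vol_median_iqr)
    tumor_vol = np.exp(mu_t + sg_t * z_vol[:, 0])
    ptbe_vol = np.exp(mu_p + sg_p * z_vol[:, 1])
    csf_vol = spec.glioma_csf_mean + spec.glioma_csf_sd * z_vol[:, 2]

    mu_k, sg_k = lognormal_from_median_iqr(*spec.ki67_median_iqr)
    ki67 = np.exp(mu_k + sg_k * rng.standard_normal(n))

    # hemispheric split: contralateral - tumor-side difference
    delta = rng.normal(spec.paired_shift, spec.paired_sd, n)
    alps_ts = alps_mean - 0.5 * delta
    alps_cl = alps_mean + 0.5 * delta
    # bilateral tumors: the labeled tumor side is the hemisphere holding the
    # larger simulated tumor fraction (drawn here), recorded as 'both'
    frac_left = rng.uniform(size=n)
    eff_side = np.where(side == "both", np.where(frac_left >= 0.5, "left", "right"), side)

    for i in range(n):
        left, right = (alps_ts[i], alps_cl[i]) if eff_side[i] == "left" else (alps_cl[i], alps_ts[i])
        records.append(
            SubjectRecord(
                id=f"G{i + 1:03d}",
                group="glioma",
                grade=str(grade[i]),
                idh=str(idh[i]),
                glioma_type=str(gtype[i]),
                age=float(age[i]),
                sex=str(sex[i]),
                tumor_side=str(side[i]),
                alps_tumor_side=float(alps_ts[i]),
                alps_contralateral=float(alps_cl[i]),
                alps_mean=float(alps_mean[i]),
                alps_left=float(left),
                alps_right=float(right),
                csf_volume_cm3=float(max(csf_vol[i], 0.0)),
                tumor_volume_cm3=float(tumor_vol[i]),
                ptbe_volume_cm3=float(ptbe_vol[i]),
                ki67_pct=float(ki67[i]),
                olig2_pct=float(olig2[i]),
            )
        )

    # ---- control group ----------------------------------------------------
    m = spec.n_control
    sex_c = _permuted_counts(rng, [("female", spec.control_n_female), ("male", m - spec.control_n_female)])
    age_c = rng.normal(spec.control_age_mean, spec.control_age_sd, m)
    alps_mean_c = rng.normal(spec.control_alps_mean, spec.control_alps_sd, m)
    csf_c = rng.normal(spec.control_csf_mean, spec.control_csf_sd, m)
    delta_c = rng.normal(0.0, spec.control_paired_sd, m)  # right - left, no shift
    for i in range(m):
        records.append(
            SubjectRecord(
                id=f"C{i + 1:03d}",
                group="control",
                grade=None,
                idh=None,
                glioma_type=None,
                age=float(age_c[i]),
                sex=str(sex_c[i]),
                tumor_side=None,
                alps_tumor_side=None,
                alps_contralateral=None,
                alps_mean=float(alps_mean_c[i]),
                alps_left=float(alps_mean_c[i] - 0.5 * delta_c[i]),
                alps_right=float(alps_mean_c[i] + 0.5 * delta_c[i]),
                csf_volume_cm3=float(max(csf_c[i], 0.0)),
                tumor_volume_cm3=None,
                ptbe_volume_cm3=None,
                ki67_pct=None,
                olig2_pct=None,
            )
        )
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def write_cohort_tsv(records: list[SubjectRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
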