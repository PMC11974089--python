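"""Group comparisons, correlations, and regression screening for cohort tables.

Implements the study's statistical battery:

- Shapiro-Wilk normality gate per group (parametric iff every group's
  p >= 0.05);
- two groups: pooled-variance Student t (Welch by flag) or the Wilcoxon
  rank-sum test (normal approximation with tie correction, no continuity
  correction);
- k >= 3 groups: one-way ANOVA with LSD post hoc (pairwise t on the
  pooled MSE, unadjusted — that is what "least significant difference"
  means) or Kruskal-Wallis with Dunn's post hoc z-tests (raw and
  Holm-adjusted p both reported);
- paired t for bilateral hemispheric differences;
- Pearson chi-square (no continuity correction) for categorical tables;
- Spearman rank-correlation matrix, pairwise-complete;
- two-stage regression: univariate screens, then one multivariable OLS
  over the candidates passing the entry threshold, with standardized
  coefficients (z-scored outcome and predictors).

All tests are two-tailed. Missing values are handled pairwise-complete
(controls lack tumor variables) and every result records its effective n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


# ---------------------------------------------------------------------------
# result containers

@dataclass
class PosthocRow:
    pair: tuple[str, str]
    statistic: float
    p: float
    p_adjusted: float | None = None
    adjustment: str | None = None


@dataclass
class ComparisonResult:
    variable: str
    groups: list[str]
    summaries: dict  # group -> "mean +- SD" or "median (IQR)" string
    gate: str
    test: str
    statistic: float
    p: float
    n_by_group: dict
    posthoc: list[PosthocRow] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


@dataclass
class RegressionRow:
    predictor: str
    b: float  # unstandardized coefficient
    beta: float  # standardized coefficient
    p: float
    stage: str  # univariate | multivariate
    n: int


@dataclass
class RegressionResult:
    outcome: str
    candidates: list[str]
    entry_alpha: float
    univariate: list[RegressionRow]
    entered: list[str]
    multivariate: list[RegressionRow]


@dataclass
class StatReport:
    comparisons: list[ComparisonResult]
    spearman: pd.DataFrame | None
    regression: RegressionResult | None
    paired: ComparisonResult | None


# ---------------------------------------------------------------------------
# helpers

def _split(values, labels) -> dict:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    keep = np.isfinite(values) & pd.notna(labels)
    values, labels = values[keep], labels[keep]
    return {str(g): values[labels == g] for g in pd.unique(labels)}


def _summary(x: np.ndarray, gate: str) -> str:
    if gate == PARAMETRIC:
        return f"{np.mean(x):.3f} ± {np.std(x, ddof=1):.3f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3f} ({q3 - q1:.3f})"


def normality_gate(groups: dict) -> str:
    """Shapiro-Wilk on each group; parametric iff all p >= 0.05.

    Groups with fewer than 3 values raise; a constant-valued group is
    treated as nonparametric (normality is untestable and the Gaussian
    model degenerate — documented convention).
    """
    for name, x in groups.items():
        if len(x) < 3:
            raise ValueError(f"group {name!r} has n={len(x)} < 3; normality untestable")
    for x in groups.values():
        if np.ptp(x) == 0:
            return NONPARAMETRIC
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(x).pvalue < 0.05:
                return NONPARAMETRIC
    return PARAMETRIC


# ---------------------------------------------------------------------------
# comparisons

def compare_two_groups(values, labels, gate: str | None = None, *, variable: str = "", welch: bool = False) -> ComparisonResult:
    groups = _split(values, labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(groups)}")
    if gate is None:
        gate = normality_gate(groups)
    (ga, xa), (gb, xb) = groups.items()
    if gate == PARAMETRIC:
        res = sps.ttest_ind(xa, xb, equal_var=not welch)
        test = "Welch t" if welch else "Student t (pooled)"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = _ranksum_z(xa, xb)
        test = "Wilcoxon rank-sum (normal approx., tie-corrected)"
    return ComparisonResult(
        variable=variable,
        groups=[ga, gb],
        summaries={g: _summary(x, gate) for g, x in groups.items()},
        gate=gate,
        test=test,
        statistic=stat,
        p=p,
        n_by_group={g: int(len(x)) for g, x in groups.items()},
    )


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rank-sum z with average ranks and tie correction, no continuity."""
    n1, n2 = len(x), len(y)
    allv = np.concatenate([x, y])
    ranks = sps.rankdata(allv)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(allv, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def compare_k_groups(values, labels, gate: str | None = None, *, variable: str = "") -> ComparisonResult:
    groups = _split(values, labels)
    if len(groups) < 3:
        return compare_two_groups(values, labels, gate, variable=variable)
    if gate is None:
        gate = normality_gate(groups)
    names = list(groups)
    xs = [groups[g] for g in names]
    if gate == PARAMETRIC:
        f, p = sps.f_oneway(*xs)
        posthoc = _lsd_posthoc(groups)
        test = "one-way ANOVA + LSD post hoc"
        stat = float(f)
    else:
        h, p = sps.kruskal(*xs)
        posthoc = _dunn_posthoc(groups)
        test = "Kruskal-Wallis (tie-corrected) + Dunn post hoc"
        stat = float(h)
    return ComparisonResult(
        variable=variable,
        groups=names,
        summaries={g: _summary(x, gate) for g, x in groups.items()},
        gate=gate,
        test=test,
        statistic=stat,
        p=float(p),
        n_by_group={g: int(len(x)) for g, x in groups.items()},
        posthoc=posthoc,
    )


def _lsd_posthoc(groups: dict) -> list[PosthocRow]:
    """Pairwise t-tests on the pooled within-group MSE, unadjusted."""
    names = list(groups)
    ns = {g: len(x) for g, x in groups.items()}
    k = len(names)
    n_total = sum(ns.values())
    mse = sum(np.sum((groups[g] - groups[g].mean()) ** 2) for g in names) / (n_total - k)
    df = n_total - k
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = names[i], names[j]
            se = np.sqrt(mse * (1.0 / ns[gi] + 1.0 / ns[gj]))
            t = (groups[gi].mean() - groups[gj].mean()) / se
            p = 2.0 * sps.t.sf(abs(t), df)
            rows.append(PosthocRow((gi, gj), float(t), float(p), None, "none (LSD)"))
    return rows


def _dunn_posthoc(groups: dict) -> list[PosthocRow]:
    """Dunn z-tests on mean ranks with tie correction; raw + Holm p."""
    names = list(groups)
    allv = np.concatenate([groups[g] for g in names])
    n = len(allv)
    ranks = sps.rankdata(allv)
    mean_ranks, sizes, pos = {}, {}, 0
    for g in names:
        m = len(groups[g])
        mean_ranks[g] = ranks[pos : pos + m].mean()
        sizes[g] = m
        pos += m
    _, counts = np.unique(allv, return_counts=True)
    tie_corr = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            se = np.sqrt((n * (n + 1) / 12.0 - tie_corr) * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            rows.append(PosthocRow((gi, gj), float(z), float(2.0 * sps.norm.sf(abs(z)))))
    adj = multipletests([r.p for r in rows], method="holm")[1]
    for r, pa in zip(rows, adj):
        r.p_adjusted, r.adjustment = float(pa), "holm"
    return rows


def paired_hemisphere_test(tumor_side, contralateral, *, variable: str = "ALPS") -> ComparisonResult:
    """Paired two-tailed t test on within-subject hemispheric differences."""
    a = np.asarray(tumor_side, dtype=float)
    b = np.asarray(contralateral, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("paired test needs at least 2 complete pairs")
    d = a - b
    if np.ptp(d) == 0 and d[0] == 0:
        stat, p = 0.0, 1.0
    elif np.ptp(d) == 0:
        # constant nonzero difference: zero-variance degenerate limit
        stat, p = float(np.sign(d[0]) * np.inf), 0.0
    else:
        res = sps.ttest_rel(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        variable=variable,
        groups=["tumor side", "contralateral"],
        summaries={
            "tumor side": f"{a.mean():.3f} ± {a.std(ddof=1):.3f}",
            "contralateral": f"{b.mean():.3f} ± {b.std(ddof=1):.3f}",
        },
        gate=PARAMETRIC,
        test="paired t",
        statistic=stat,
        p=p,
        n_by_group={"pairs": int(a.size)},
        extra={"mean_difference": float(d.mean())},
    )


def chi_square(table, *, variable: str = "") -> ComparisonResult:
    """Pearson chi-square without continuity correction; expected counts reported."""
    obs = np.asarray(table, dtype=float)
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    return ComparisonResult(
        variable=variable,
        groups=[f"row{i}" for i in range(obs.shape[0])],
        summaries={},
        gate="categorical",
        test="Pearson chi-square",
        statistic=float(chi2),
        p=float(p),
        n_by_group={"total": int(obs.sum())},
        extra={"dof": int(dof), "expected": expected.tolist()},
    )


# ---------------------------------------------------------------------------
# correlation and regression

def spearman_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise Spearman correlations (average ranks for ties, two-tailed
    t-approximation p), pairwise-complete observations.

    Returns a long-format frame with columns var1, var2, r, p, n.
    """
    rows = []
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            a, b = variables[i], variables[j]
            sub = table[[a, b]].dropna()
            r, p = sps.spearmanr(sub[a], sub[b])
            rows.append({"var1": a, "var2": b, "r": float(r), "p": float(p), "n": int(len(sub))})
    return pd.DataFrame(rows)


def _standardized_fit(y: np.ndarray, x: np.ndarray, names: list[str], stage: str) -> list[RegressionRow]:
    """OLS with intercept; returns standardized and raw coefficients."""
    sd_y = y.std(ddof=1)
    sd_x = x.std(axis=0, ddof=1)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    rows = []
    for k, name in enumerate(names):
        b = float(model.params[k + 1])
        rows.append(
            RegressionRow(
                predictor=name,
                b=b,
                beta=float(b * sd_x[k] / sd_y),
                p=float(model.pvalues[k + 1]),
                stage=stage,
                n=int(len(y)),
            )
        )
    return rows


def regression_screen(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    entry_alpha: float = 0.05,
) -> RegressionResult:
    """Univariate screens, then one multivariable OLS over the entrants.

    Candidates must be numeric or binary-codable; the study's grade factor
    is coded LGG=0 / HGG=1 (so a negative standardized coefficient means
    high grade -> lower outcome). Raises on a collinear multivariable
    design (condition number > 1e8).
    """
    df = table.copy()
    for col in [outcome] + candidates:
        if df[col].dtype == object or isinstance(df[col].dtype, pd.CategoricalDtype):
            df[col] = _binary_code(df[col], col)
        df[col] = pd.to_numeric(df[col])

    uni: list[RegressionRow] = []
    for cand in candidates:
        sub = df[[outcome, cand]].dropna()
        uni.extend(
            _standardized_fit(sub[outcome].to_numpy(float), sub[[cand]].to_numpy(float), [cand], "univariate")
        )

    entered = [row.predictor for row in uni if row.p < entry_alpha]
    multi: list[RegressionRow] = []
    if entered:
        sub = df[[outcome] + entered].dropna()
        x = sub[entered].to_numpy(float)
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        cond = np.linalg.cond(z)
        if cond > 1e8:
            corr = np.corrcoef(z, rowvar=False)
            bad = [
                (entered[i], entered[j])
                for i in range(len(entered))
                for j in range(i + 1, len(entered))
                if abs(corr[i, j]) > 0.999
            ]
            raise ValueError(f"collinear multivariable design (cond={cond:.3g}); collinear set: {bad}")
        multi = _standardized_fit(sub[outcome].to_numpy(float), x, entered, "multivariate")
    return RegressionResult(outcome, candidates, entry_alpha, uni, entered, multi)


_BINARY_CODES = {
    "LGG": 0.0,
    "HGG": 1.0,
    "male": 0.0,
    "female": 1.0,
    "wildtype": 0.0,
    "mutant": 1.0,
}


def _binary_code(series: pd.Series, name: str) -> pd.Series:
    vals = series.dropna().unique()
    unknown = [v for v in vals if v not in _BINARY_CODES]
    if unknown:
        raise ValueError(f"cannot numerically code column {name!r}: values {unknown}")
    return series.map(_BINARY_CODES)


# ---------------------------------------------------------------------------
# the full battery over a cohort table

ALPS_VOLUME_VARS = ["alps_mean", "tumor_volume_cm3", "ptbe_volume_cm3", "csf_volume_cm3"]


def full_report(df: pd.DataFrame, entry_alpha: float = 0.05) -> StatReport:
    """Run the complete comparison/correlation/regression battery.

    Mirrors the study layout: glioma vs control (ALPS, CSF volume), LGG vs
    HGG and IDH contrasts (ALPS and all volumes), glioma-type three-group
    comparison, the paired hemispheric test, the sex chi-square, the
    Spearman matrix over ALPS and volumes, and the two-stage regression of
    the ALPS index on grade, age and Olig-2.
    """
    comparisons: list[ComparisonResult] = []
    gli = df[df["group"] == "glioma"]

    for var in ("alps_mean", "csf_volume_cm3", "age"):
        comparisons.append(
            compare_two_groups(df[var], df["group"], variable=f"{var}: glioma vs control")
        )
    for var in ("alps_mean", "csf_volume_cm3", "tumor_volume_cm3", "ptbe_volume_cm3"):
        comparisons.append(
            compare_two_groups(gli[var], gli["grade"], variable=f"{var}: LGG vs HGG")
        )
        comparisons.append(
            compare_two_groups(gli[var], gli["idh"], variable=f"{var}: IDH")
        )
        comparisons.append(
            compare_k_groups(gli[var], gli["glioma_type"], variable=f"{var}: glioma type")
        )

    sex_table = pd.crosstab(df["group"], df["sex"]).to_numpy()
    comparisons.append(chi_square(sex_table, variable="sex: glioma vs control"))

    paired = paired_hemisphere_test(
        gli["alps_tumor_side"], gli["alps_contralateral"], variable="ALPS tumor side vs contralateral"
    )
    spearman = spearman_matrix(gli, ALPS_VOLUME_VARS)
    regression = regression_screen(gli, "alps_mean", ["grade", "age", "olig2_pct"], entry_alpha)
    return StatReport(comparisons, spearman, regression, paired)


def report_frames(report: StatReport) -> dict:
    """Flatten a StatReport into tidy DataFrames keyed by section."""
    comp = pd.DataFrame(
        [
            {
                "variable": c.variable,
                "test": c.test,
                "gate": c.gate,
                "statistic": c.statistic,
                "p": c.p,
                **{f"n_{g}": n for g, n in c.n_by_group.items()},
                **{f"summary_{g}": s for g, s in c.summaries.items()},
            }
            for c in report.comparisons + ([report.paired] if report.paired else [])
        ]
    )
    posthoc = pd.DataFrame(
        [
            {
                "variable": c.variable,
                "pair": " vs ".join(r.pair),
                "statistic": r.statistic,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "adjustment": r.adjustment,
            }
            for c in report.comparisons
            for r in c.posthoc
        ]
    )
    reg_rows = []
    if report.regression:
        for row in report.regression.univariate + report.regression.multivariate:
            reg_rows.append(
                {
                    "outcome": report.regression.outcome,
                    "stage": row.stage,
                    "predictor": row.predictor,
                    "b": row.b,
                    "beta": row.beta,
                    "p": row.p,
                    "n": row.n,
                }
            )
    return {
        "comparisons": comp,
        "posthoc": posthoc,
        "spearman": report.spearman if report.spearman is not None else pd.DataFrame(),
        "regression": pd.DataFrame(reg_rows),
    }
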