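# dtialps

Analysis pipeline for studying **glymphatic function in glioma** with
diffusion MRI: DTI-ALPS index computation, brain volumetrics, and the full
group-comparison / correlation / regression battery — exercised end to end
on synthetic DWI phantoms and simulated patient cohorts.

Gliomas disrupt the brain's perivascular fluid-exchange (glymphatic)
system. A noninvasive surrogate for this is **DTI-ALPS** (diffusion tensor
image analysis along the perivascular space): at the level of the body of
the lateral ventricles, medullary-vein perivascular spaces run left–right
(x), perpendicular to projection fibers (superior–inferior, z) and
association fibers (anterior–posterior, y). With scanner-frame diffusivity
means taken over small fiber-region VOIs,

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

an index near 1 means no preferential perivascular diffusion; lower values
in patients indicate glymphatic impairment. The package owns every
computational step of this analysis:

- `dtialps.phantom` — Stejskal–Tanner forward simulation (`S = S0·exp(−b·gᵀDg)`,
  Rician noise) on a lateral-ventricle slab with projection/association
  fiber bands, ventricles, and an optional tumor + peritumoral-edema (PTBE)
  shell; a perivascular factor α scales band Dxx to emulate impairment.
- `dtialps.tensorfit` — log-linear diffusion tensor estimation (OLS, or
  one-pass WLS with squared-predicted-signal weights), FA/MD/color maps.
- `dtialps.alps` — VOI placement and the ALPS index, per hemisphere
  (tumor-affected vs contralateral) and bilateral mean.
- `dtialps.volumetrics` — CSF / tumor / PTBE volumes (cm³) from label masks.
- `dtialps.cohort` — a simulated cohort of 112 glioma patients (35 LGG /
  77 HGG) and 56 controls carrying the study's published group means/SDs,
  medians/IQRs, paired hemispheric structure, Gaussian-copula rank
  correlations, and grade→ALPS effect.
- `dtialps.stats` — Shapiro–Wilk-gated t / Wilcoxon / ANOVA+LSD /
  Kruskal–Wallis+Dunn comparisons, paired t, chi-square, Spearman matrix,
  and the two-stage (univariate screen → multivariable OLS) regression
  with standardized β.
- `dtialps.pipeline`, `dtialps.cli` — a seeded, manifest-hashed end-to-end
  run (`dtialps run`), plus per-stage subcommands.

## Worked example

The numbered drivers under `analysis/` reproduce the study-style analysis
on simulated data and write tables under `results/`:

```sh
python analysis/01_phantom_alps.py     # phantom: alpha/SNR sweep of the index
python analysis/02_simulate_cohort.py  # one 168-subject cohort + summary
python analysis/03_volumetrics.py      # volumes via the label-mask path
python analysis/04_group_statistics.py # the full statistical battery
```

`01_phantom_alps.py` shows the index tracking simulated impairment
(noiseless bilateral index 1.333 at α=1.0 falling to 0.800 at α=0.6,
monotone at SNR 40 and 20 as well), and that unilateral impairment lowers
only the affected hemisphere:

```
unilateral alpha=0.7: tumor-side index 0.9333 < contralateral 1.3333
```

`04_group_statistics.py` (seed 1) prints, among other results:

```
alps_mean: glioma vs control: Student t (pooled), stat=-6.003, p=1.181e-08
csf_volume_cm3: glioma vs control: Student t (pooled), stat=4.450, p=1.571e-05
paired tumor-side vs contralateral ALPS: t=-3.356, p=0.001082, mean difference -0.0935
```

i.e. in a cohort simulated at the published parameters, glioma patients
show a lower ALPS index and a larger CSF volume than controls, and the
tumor-affected hemisphere a lower index than the contralateral one — the
study's headline pattern. The Spearman block shows the configured negative
ALPS↔tumor-volume and ALPS↔PTBE rank correlations; single-cohort values
scatter around the configured −0.353 / −0.266 with SD ≈ 0.09 at n = 112.

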