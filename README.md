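# chromaqbd

Quality-by-design (QbD) computations for chromatographic method
development, built around the worked case of an isocratic RP-HPLC assay
for the three curcuminoids of *Curcuma longa* — curcumin (CMN),
demethoxycurcumin (DMCMN) and bisdemethoxycurcumin (BDMCMN).

It is aimed at analytical scientists who develop and validate targeted
quantification methods and want the statistical machinery of that
workflow — designed experiments, response-surface models, multi-response
optimization, operable-region extraction, capability simulation, and
ICH-style validation statistics — as a scriptable, tested Python library
rather than a point-and-click package.

## What it computes

**Designs** (`chromaqbd.designs`). Two-level full factorials with center
points and the 12-run Plackett–Burman screening design, in coded units
`x = (X − (lo+hi)/2) / ((hi−lo)/2)` with seeded run-order randomization.

**Response-surface models** (`chromaqbd.rsm`). For each critical method
attribute (CMA: peak resolutions RS1/RS2, retention times, plate counts)
a least-squares polynomial in the coded factors (main effects +
two-factor interactions by default), with the classical ANOVA
decomposition — per-term SS, residual, lack-of-fit vs pure error from
replicate groups, a center-point curvature contrast — and the usual fit
statistics: R², adjusted R², CV% = 100·√MSE/ȳ, and the signal-to-noise
"adequate precision" (max ŷ − min ŷ)/√(p·MSE/n).

**Desirability optimization** (`chromaqbd.desirability`).
Derringer–Suich scoring: each response maps to d ∈ [0,1] through a goal
ramp, combined as D = (∏ dᵢ^{vᵢ})^{1/Σvᵢ}; D is maximized by exhaustive
grid scan plus coordinate-descent polish.

**Design space / MODR** (`chromaqbd.modr`). A factor-grid overlay marks
the points where every CMA prediction sits inside its specification
window; the Method Operable Design Region is extracted as the largest
all-feasible axis-aligned box (exact enumeration up to three factors).

**Monte Carlo capability** (`chromaqbd.monte_carlo`). Method parameters
are drawn from configurable distributions over the operable region,
pushed through the fitted models (optionally with residual model noise),
and each CMA is summarized by Cpk = min((USL−μ)/3σ, (μ−LSL)/3σ).

**Robustness** (`chromaqbd.robustness`). Plackett–Burman effect
estimates (mean at high − mean at low) with t tests from a
regression-residual, dummy-column or center-point error estimate.

**Validation** (`chromaqbd.validation`). Calibration lines, LOD = 3.3σ/s
and LOQ = 10σ/s, % recovery and % RSD, pooled/Welch two-sample t and
variance-ratio F method comparisons, and percent-degradation accounting
from stressed-vs-reference peak tables.

**Synthetic data** (`chromaqbd.synthetic`). A ground-truth generator for
all of the above: log-linear (linear-solvent-strength style) retention
in % organic, pH and temperature; plate counts linear in temperature and
solvent; resolutions from Rs = (√N̄/4)·((α−1)/α)·(k₂/(1+k₂)); calibration
curves and forced-degradation peak tables with known degradation extent.
Verbatim transcriptions of the published design, goal, window,
robustness, calibration and content tables ship as CSV fixtures.

## Worked example

```python
import chromaqbd as cq
from chromaqbd import synthetic, desirability, monte_carlo, validation

# 1. a triplicated 2^3 screening study (8 corners + 3 centers, n = 33)
table = synthetic.demo_response_table(n_center=3, n_replicates=3, seed=11)
models = {}
for cma in table.cma_names:
    m = cq.fit_response_model(table, cma)
    cq.anova_table(m, table)
    cq.fit_statistics(m, table)
    models[cma] = m
print(round(models["RS1"].stats["R2"], 3))          # 0.999
print(round(models["RS1"].stats["CV_pct"], 2))      # 0.24

# 2. multi-response optimization over the factor ranges
opt = desirability.optimize_desirability(
    models, synthetic.optimization_goals(), synthetic.screening_factors(), grid=21
)
print(round(opt.D, 3))                              # 0.769

# 3. capability of the operable region (uniform CMP draws, 10^5 each)
cfg = monte_carlo.MCConfig(
    distributions=[
        monte_carlo.CMPDistribution(f.name, "uniform", (f.low, f.high))
        for f in synthetic.modr_factors()
    ],
    n_draws=100_000, seed=1,
)
mc = monte_carlo.simulate_capability(models, synthetic.spec_windows(), cfg)
print(round(mc.per_cma["cpk"].min(), 2))            # 2.32

# 4. printed-table statistics: capsule assay comparison and sensitivity
c = validation.compare_methods(27.15, 0.35, 3, 27.62, 0.26, 3)
print(round(c.t, 2), round(c.t_crit, 2))            # 1.87 2.78
print(tuple(round(v, 3) for v in validation.lod_loq(0.335 / 3.3, 1.0)))
                                                    # (0.335, 1.015)
```

The model R² ≈ 0.999 and CV < 1% say the interaction model explains the
synthetic screening data almost completely; D ≈ 0.77 is the best joint
desirability the goals admit on this surface; a minimum Cpk ≈ 2.3 means
every CMA stays far inside its specification window anywhere in the
operable region; and t = 1.87 < 2.78 confirms the two assay methods
agree on the capsule curcumin content at the 95% level.

A `chromaqbd` console script exposes the same pipeline from the shell
(`design`, `simulate`, `fit`, `optimize`, `modr`, `mc`, `robustness`,
`validate`, `fixtures`); run `chromaqbd --help`.

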