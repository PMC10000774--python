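# Methods

This note records the statistical models the package implements, the
defaults it ships with and why, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer should know
about.

## Designs and coding

Factor settings are coded as x = (X − m)/h with m the range midpoint and
h the half-range, so −1/0/+1 are low/mid/high; decoding is the exact
linear inverse, and round-trips are exact to machine precision. The
two-level full factorial enumerates all 2^k corners in standard order,
appends the requested center points, and replicates every distinct row
when replicates are requested — replicates are kept as explicit rows
(rather than averaged) so that pure-error degrees of freedom survive
into the ANOVA; an analyst who wants run means can average before
loading. The 12-run Plackett–Burman plan is built from the textbook
cyclic generator row (+ + − + + + − − − + −) with the last row all
minus; the first k of the 11 mutually orthogonal columns carry the
factors, the remaining columns are retained as dummy columns for error
estimation. Randomization affects run order only, never level
assignment, so the same seed reproduces the same plan file byte for
byte.

A printed robustness plan from the literature is not guaranteed to be a
standard PB geometry (the packaged one duplicates one run and is not a
cyclic fraction), so printed plans are ingested as data through the CSV
reader rather than regenerated; the reader derives coded levels, center
flags and replicate indices from the natural settings.

## Response-surface models and ANOVA

On a two-level design pure quadratic terms are aliased with the
intercept, so the default model is intercept + main effects + all
two-factor interactions (the three-factor interaction is available).
Requesting an unestimable term fails with an error that names it.
Fitting is ordinary least squares (statsmodels OLS) on the coded model
matrix; coefficient standard errors, t statistics and 95% confidence
intervals come from the same fit.

The ANOVA uses sequential (Type I) single-degree-of-freedom sums of
squares via a QR factorization; on the orthogonal coded designs this
package generates, sequential and partial SS coincide. The residual is
split into pure error (within groups of rows with identical coded
settings) and lack of fit; when center points exist a one-df curvature
contrast n_f·n_c/(n_f+n_c)·(ȳ_f − ȳ_c)² is reported as an additional
informational row (it is a component of lack of fit and is not added
into the decomposition sum, so SS_model + SS_residual = SS_total always
holds; the suite checks it to 1e−8 relative). Lack of fit and curvature
are tested against pure error when replicate df exist, otherwise
curvature falls back to the residual MS and lack of fit is omitted with
a flag. Term and model F tests use the residual MS and upper-tail F
p-values; coefficient t tests are two-sided; no multiplicity correction
is applied.

Fit statistics follow the conventions of commercial DoE software:
CV% = 100·√MSE/ȳ, and "adequate precision" is the signal-to-noise ratio
(max ŷ − min ŷ)/√(p·MSE/n) over the design points with p the parameter
count — that formula is not universal, so it is stated here explicitly.

## Desirability

Individual desirabilities are the Derringer–Suich ramps: one-sided
ramps for maximize/minimize (clipped to [0,1], raised to the weight
exponent), a hard 0/1 indicator for in-range, a two-sided ramp peaking
at the target for target goals. One-sided "greater than x" goals use
the stated threshold as the ramp foot and the observed response maximum
as the saturation point, mirroring how DoE software builds ramps from
observed ranges; the ramp limits are configuration, not hard-coded.
The overall desirability is the importance-weighted geometric mean, so
any individual zero vetoes a candidate point. Importances default to 1.

The optimizer evaluates D exhaustively on a lattice (default 51 points
per factor; the worked examples use 21 for speed) and then polishes the
best cell by cyclic coordinate descent with bounded golden-section line
searches (tolerance 1e−8 in coded units, 200 sweep cap). Grid ties are
broken first-in-scan-order, making results deterministic for a given
grid. An everywhere-infeasible goal set reports D = 0 rather than
raising.

## Design space and MODR

A lattice point is feasible iff every CMA prediction lies inside its
specification window, with closed intervals (a prediction exactly at a
limit passes). The MODR is automated as the feasible axis-aligned box
containing the most lattice points: exact enumeration over per-axis
interval pairs (with a linear max-run scan on the last axis) for up to
three factors, and a seeded grow-from-feasible-seeds heuristic beyond
that. Maximizing the lattice-point count rather than natural volume
makes a single feasible point a legitimate degenerate MODR. The default
overlay grid is 21 points per axis for three factors. A manual box can
always be supplied instead — the published operable ranges ship as a
fixture for exactly that use.

## Monte Carlo capability

Method-parameter uncertainty defaults to uniform distributions over the
operable ranges — the least-assumption choice for a region in which any
operating point is claimed to be acceptable; normal and triangular
alternatives are available, truncated to the factor range by
resampling. Residual model noise (N(0, √MSE) per draw, per CMA)
defaults to on, in the style of capability tools that transmit model
error; switching it off gives pure parameter propagation. Cpk uses the
single finite term for one-sided windows. A zero sample SD (point-mass
inputs with noise off) reports Cpk = +inf as a sentinel. Histograms use
30 fixed-width bins over the observed range. The default draw count is
100,000, at which the suite requires agreement with the closed-form
normal Cpk within 2%.

## Robustness testing

Effects are classical two-level contrasts, mean(high) − mean(low) over
the non-center rows; center rows never enter contrasts and serve only a
curvature check. The default significance method fits the main-effects
regression on the two-level rows and uses its residual MS, with
Var(effect) = 4·MSE·(X'X)⁻¹ⱼⱼ — this works for any printed two-level
plan, including non-orthogonal ones where dummy-column assignment would
be ambiguous. For standard PB geometries the dummy-column method (RMS
of unassigned-column effects, df = number of dummies) and the
center-point pure-error method are available. On orthogonal plans the
effect equals exactly twice the coded regression slope and the t test
is exact, which is why the null-simulation type-I error lands at the
nominal α (the suite requires [0.03, 0.07] at α = 0.05 over 300 null
tables). α defaults to 0.05.

On the packaged printed robustness plan the responses are so low-noise
that most effects, although tiny in absolute terms (e.g. a pH effect of
−0.0012 resolution units), are statistically significant under this
method; practical robustness there is a judgment about effect size, not
p-values, and the package reports both.

## Validation statistics

LOD = 3.3σ/s and LOQ = 10σ/s share one σ and s, so LOQ/LOD = 10/3.3
identically. Recovery is 100·mean(found)/nominal; RSD uses the sample
SD. The method-comparison t test is pooled-variance by default (Welch
optional) with df = n₁+n₂−2; F puts the larger variance in the
numerator. The F-test degrees of freedom for the critical value are
exposed as an explicit parameter because report conventions vary — the
reference footnote value 6.39 corresponds to (4, 4) df even though two
groups of three imply (2, 2); the package reproduces either, and the
shipped comparison defaults to (n−1, n−1). Display rounding follows the
reference tables: 2 decimals for t/F, 3 for LOD/LOQ and contents.

Percent degradation is 100·(ΣA_parent,ref − ΣA_parent,stressed)/ΣA_parent,ref
with stressed parents matched to reference parents by retention time
within ±0.2 min (configurable); unmatched stressed peaks are reported
as degradants.

## Synthetic generator

Retention follows a linear-solvent-strength-style law, ln k linear in
% organic (−0.030 per %), pH (+0.05 per unit) and temperature (−0.010
per °C), with RT = t₀(1+k) and t₀ = 1 min; the signs reproduce the
qualitative behavior reported for such separations (retention rises
with pH, falls with organic fraction and temperature). Baseline ln k
values (1.35/1.48/1.61) put the three analytes at ≈ 4.9/5.4/6.0 min at
the reference point (54% ACN, pH 2.7, 33 °C), inside the 2–7 min
specification window, eluting bisdemethoxycurcumin first and curcumin
last — the order implied by the reference retention data; the order is
configurable because published sources disagree internally. Plate
counts are linear in temperature (+40/°C) and organic fraction
(−25/%), anchored near 4800/3970/4900 plates, and resolutions come from
the fundamental relation Rs = (√N̄/4)·((α−1)/α)·(k₂/(1+k₂)) on adjacent
pairs, giving Rs ≈ 1.65–1.70 at the reference point. Noise is
multiplicative Gaussian with 1% relative SD on retention times, 2% on
resolutions and 3% on plate counts — chosen once so that fitted models
on a triplicated screening study land in the quality bands such studies
report (CV% below 10, adequate precision above 4), as the suite
verifies over 200 seeds.

What the generator does not emulate: chromatogram traces (peak shapes,
baselines, integration), gradient elution, retention nonlinearity in
pH across pKa boundaries, inter-day or column-aging drift, and
correlated noise between CMAs. Tests passing on synthetic data
therefore demonstrate that the statistical machinery is correct and
calibrated under the stated noise model — not that any particular real
separation will meet its specifications.

Calibration simulation is a straight line with noise proportional to
signal (default 0.5% relative), with slopes near the reference
magnitudes; degradation simulation removes exactly the requested
fraction of total parent area (zero-sum per-peak jitter) and places the
degradant peaks uniformly before the first parent, as expected for the
more polar cleavage products, so the percent-degradation round trip is
exact.

## Problem sizes and determinism

Defaults used in tests and the reproduction script: 33-run triplicated
screening studies; 21-point optimization grids (51 is the library
default); 11–21 point overlay grids; 100,000 Monte Carlo draws;
200-replicate recovery/coverage simulations and 300-table null
calibrations. Every stochastic routine takes an explicit seed and is
bit-reproducible given it; confidence-interval coverage is required
within ±7 percentage points of nominal at these replication counts.

## Known limitations

- The exact MODR search is exponential in the factor count and is used
  only up to three factors; the heuristic beyond that is not guaranteed
  maximal.
- Sequential and partial SS differ on non-orthogonal imported plans;
  only sequential SS are reported.
- The desirability polish is local; with strongly multimodal D the
  grid resolution, not the polish, determines which basin is found.
- Effect/SE pairing for non-orthogonal printed plans mixes a contrast
  effect with a regression SE; they coincide exactly only on balanced
  orthogonal plans (a warning is raised for unbalanced columns).
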