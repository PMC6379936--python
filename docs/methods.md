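# Methods

This note records the models implemented in oggkit, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Burst-phase kinetics

Product formation is modelled as
`P(t) = A0·(1 − exp(−k1·t)) + k2·t`, the standard description of
pre-steady-state glycosylase assays: enzyme-bound substrate is excised in
a fast first turnover (exponential phase, rate `k1`), after which slow
product release limits further turnover (linear phase, rate `k2`). `A0`
is proportional to the concentration of catalytically engaged enzyme and
is capped by the substrate total (20 nM in the emulated design). The
1/10 labeled:unlabeled substrate mixing of the assay is treated as
transparent — the labeled fraction is an unbiased proxy for total
product — and is not modelled.

Fitting is bounded nonlinear least squares (scipy's trust-region
reflective) with the analytic Jacobian of the model. Bounds:
`A0 ∈ [0, substrate_total]`, `k1 ∈ (0, 100]` min⁻¹, `k2 ∈ [0, 10]`
nM·min⁻¹; they prevent the two phases from exchanging roles. Initial
guesses are deterministic: `k2` from the slope of the last third of
points, `A0` from the k2-corrected tail mean, `k1` from ln 2 over the
time to half-amplitude. A fit requires at least five distinct time
points (three parameters plus a noise scale, with a degree of freedom to
spare).

By default the replicate-averaged curve is fitted, matching how the
emulated study analysed its data; `per_replicate=True` fits each
replicate separately and reports across-replicate parameter means and
SDs. Standard errors come from the Jacobian-based covariance scaled by
residual variance; a seeded residual-resampling bootstrap
(`bootstrap_draws`) is available as a small-sample check. Both
uncertainties are reported because the provenance of published ± values
(fit SE vs replicate spread) is generally ambiguous.

Model adequacy is tested by the extra sum of squares: the 3-parameter
burst model against the 1-parameter line `P = k2·t`, F-distributed with
(2, n−3) degrees of freedom, default α = 0.01. When the line wins, the
burst quantities are reported *absent* (None), never as zeros with
spurious uncertainties. With noiseless data both residuals can be ~0; a
relative floor (10⁻¹² of the signal's sum of squares) then awards the
decision to the simpler model.

Relative activity between variants is `100·k1_variant/k1_reference`, with
first-order error propagation (relative errors in quadrature). With the
default ground-truth parameters this reproduces the ~16% residual
activity of the slowest variant relative to wild-type.

## Two-state thermal denaturation

The melt model is a ΔCp = 0 van't Hoff two-state equilibrium. In Kelvin,
`K(T) = exp[−(ΔH_vH/R)(1/T − 1/Tm)]`, `f_folded = 1/(1+K)`, with
R = 8.314 J·mol⁻¹·K⁻¹ and the °C↔K offset 273.15. A single melt cannot
constrain ΔCp, so the minimal model is used; `ΔH_vH` (kJ·mol⁻¹) sets the
transition sharpness. The observed ellipticity mixes two linear
baselines, giving a six-parameter fit (`Tm`, `ΔH_vH`, two intercepts, two
slopes). The parametric fit runs on raw data; Savitzky–Golay smoothing
(default window 11 points, order 3, polynomial endpoint extension) is
applied only before the derivative-based estimator. Bounds keep `Tm`
strictly inside the scanned range and `ΔH_vH ∈ [10, 5000]` kJ·mol⁻¹;
baseline initialisation uses the outer 15% of points on each side, and
the derivative peak initialises `Tm`.

The derivative method locates the maximum of |dθ/dT| with local quadratic
refinement. Two caveats are deliberate and documented:

- For a two-state sigmoid the derivative peak sits `4R²Tm³/ΔH²` *below*
  the thermodynamic midpoint (≈0.22 °C at ΔH = 200 kJ·mol⁻¹ and
  Tm ≈ 42 °C) even with flat baselines, and sloping baselines bias it
  further. It is therefore a cross-check and initialiser, never the
  reported Tm; disagreement beyond 2 °C is flagged on the fit.
- The Savitzky–Golay endpoint extension can fabricate steep derivatives
  in the first/last half-window of a noisy trace, so the peak search is
  restricted to the interior; a maximum at the boundary raises a
  no-transition error, as does a derivative with no clear peak (below
  1.5× the median, i.e. a featureless sloped line).

Replicate melts are each fitted; the reported value is the mean ± sample
SD of per-replicate Tm. Fraction denatured is computed against the fitted
baselines and flagged when it strays beyond [−0.05, 1.05] by more than
the configured allowance.

The equilibrium model assumes reversible unfolding. The activity data the
package is designed around suggest partially irreversible denaturation at
37 °C; the melt analysis ignores this, which is the standard (and here
documented) simplification.

## Thermolability and DNA protection

The scalar activity metric defaults to the fitted burst amplitude `A0`:
loss of folded enzyme removes catalytically engaged molecules, scaling
`A0` (and `k2`) while leaving the first-turnover rate constant of the
surviving molecules unchanged — the synthetic generator implements
exactly this, so the choice is testable. When any replicate on either
side of a comparison fails to support a burst (e.g. activity near
background), *all* replicates in the pair fall back to the mean product
at the latest time point, so the ratio always compares like with like;
the metric identity is recorded on every result.

Retention is challenged/control activity, the 4 °C pre-incubation being
the control (assumed lossless; the generator's denaturation rate at 4 °C
is negligible by construction). Values above 1.1 are flagged. Uncertainty
is a replicate-resampling bootstrap: each replicate is reduced to its
scalar metric once, then replicate metrics are resampled with replacement
(2000 draws, seeded) on each side independently and the ratio of means
recomputed. Resampling scalars rather than refitting inside each draw
keeps 2000 draws per cell in the milliseconds and matches the
experimental unit of replication. Percentile 95% intervals are reported
for retention (widened, if necessary, to contain the full-sample point
estimate, which percentile intervals at n = 3 can otherwise exclude).

The protection effect is `Δ = retention_with_DNA − retention_without`,
with draws differenced pairwise. The *decision* interval is
t-calibrated — bootstrap SE of Δ times the Student-t quantile at the
smallest cell's degrees of freedom — because percentile intervals
undercover badly at triplicate scale (a 3-replicate cell admits only 10
distinct resamples); measured across 40 simulated studies, the percentile
rule flagged a stable variant "protective" 23% of the time versus 5% for
the t-calibrated rule, with no loss of power on the genuinely protected
unstable variant. "Protective" means the interval excludes zero from
above. Identical inputs give Δ exactly 0 with a degenerate interval.

## Synthetic data generator

The generator emulates the study design its defaults encode: 20 nM
8oxoG:C duplex, 100 nM enzyme, quench points at
{0.5, 1, 2, 3, 5, 8, 12, 20, 30} min (the published grid is not printed;
this one resolves both phases for all five parameter sets), triplicates,
Gaussian product noise of SD 0.5 nM (chosen so Monte-Carlo parameter
scatter is comparable to the published ± values); melts on 10–95 °C at
0.5 °C steps with ΔH_vH = 200 kJ·mol⁻¹ (typical small-globular-protein
cooperativity; the data the package emulates do not constrain it) and
noise of 2% of the transition amplitude; native baseline −12000 + 20·T,
denatured −2000 + 5·T deg·cm²·dmol⁻¹ (helical protein relaxing to a
shallower denatured signal).

Ground truth for the five variants combines published kinetics
(A0, k1, k2) and melting midpoints (Tm 36.6–43.2 °C). Denaturation during
pre-incubation is the generator's own minimal model: first-order
irreversible loss at `k_den(T) = k_den_ref·exp(α(T − Tm))`, with shared
`k_den_ref = 0.025 min⁻¹` and `α = 0.7 °C⁻¹` chosen once so that 90 min
at 37 °C destroys ≈95% of the least stable variant (Tm 36.6 °C) and
<10% of wild-type, reproducing the qualitative activity pattern.
Competitor DNA multiplies the rate by `dna_protection = 0.05` (fully
bound limit at 1:1 stoichiometry — a ~20-fold stabilisation, "almost
complete" protection); no binding constant is modelled. Surviving
fraction f scales `A0` and `k2`, not `k1`.

Gel lanes are abstract band intensities with a shared per-lane log-normal
loading factor; ratio-based quantification is exactly invariant to it,
and generation∘quantification is the identity at zero noise. No label
chemistry (³²P vs Cy5), imaging PSF or electrophoretic mobility is
simulated. The R46Q variant is given the same noise as the others by
default (its larger real-data variance is configurable, not default).

The mechanistic ODE (E+S ⇌ ES → EP → E+P, LSODA, rtol 10⁻¹⁰) integrates
all five species so conservation is a genuine integrator check. With
enzyme in excess the observable [EP]+[P] plateaus at S₀ — a
single-turnover regime — so the closed-form limit in the fast-binding /
slow-release regime is (A0 = S₀, k1 = k_chem, k2 → 0); agreement is
within 2% of S₀ over the default grid. The sustained linear phase of real
assays (partially active enzyme, product rebinding) is deliberately not
mechanistically modelled.

Because the generator *is* the burst/two-state model plus Gaussian noise,
passing recovery tests demonstrates correctness and calibration of the
estimators under the stated noise model — not robustness to baseline
drift, aggregation, instrument artifacts or non-two-state unfolding in
real data.

## Problem sizes and determinism

Default study: 5 variants × (3 kinetics replicates + 3 melts + 4
pre-incubation conditions × 3 replicates); Monte-Carlo validation uses
200 seeded studies per kinetics row and 100 per melt; bootstrap 2000
draws per panel cell. One seed drives a `SeedSequence` that spawns every
child stream, so a study regenerates byte-identically; all CSV output
uses fixed `%.10g` formatting.

## Known limitations

- Tm from a single melt conflates ΔH_vH with baseline curvature when
  baselines are strongly nonlinear; only linear baselines are modelled.
- The equilibrium two-state melt and the irreversible thermolability
  model are thermodynamically inconsistent with each other by design;
  each matches how its respective measurement is conventionally analysed.
- Retention intervals at n = 3 are honest but wide; the panel reports
  replicate counts so downstream users can weight decisions accordingly.
- No plotting; results are JSON and text tables.
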