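# oggkit

Quantitative analysis of **hOGG1** (human 8-oxoguanine DNA glycosylase-1)
variant biochemistry: burst-phase excision kinetics, CD thermal
denaturation, and thermolability with competitor-DNA protection. The
package is aimed at DNA-repair biochemists who run quench time-course
glycosylase assays and CD melts and want a reproducible, tested pipeline
from raw tables to rate constants, melting temperatures and
activity-retention statistics — plus a synthetic-data generator that
emulates the whole study design for validation and power analysis.

## The models

**Excision kinetics.** Product formation in the 8oxoG:C excision assay
(20 nM duplex substrate, 100 nM enzyme, alkali quench) is biphasic:

    P(t) = A0 · (1 − e^(−k1·t)) + k2·t

where the burst amplitude `A0` (nM) counts actively engaged enzyme, `k1`
(min⁻¹) is the first-turnover excision rate and `k2` (nM·min⁻¹) the slow
steady-state rate limited by product release. Fitting is bounded
trust-region least squares with an analytic Jacobian; an
extra-sum-of-squares F-test guards against fitting a burst to burstless
data, and a mechanistic ODE simulation (E+S ⇌ ES → EP → E+P) provides an
independent check that the closed form is the correct fast-binding /
slow-release limit.

**Thermal denaturation.** The 222 nm molar ellipticity of a melt
(10–95 °C) is modelled as a two-state, ΔCp = 0 van't Hoff equilibrium
between linear native and denatured baselines:

    K(T) = exp[−(ΔH_vH/R)(1/T − 1/Tm)],   θ(T) = f·θ_N(T) + (1−f)·θ_D(T),
    f = 1/(1+K)

The six-parameter fit returns `Tm`, `ΔH_vH` and both baselines; a
smoothed-derivative peak locator (Savitzky–Golay) cross-checks every fit.

**Thermolability.** Activity retained after a 90-min pre-incubation at
37 °C relative to the 4 °C control is the ratio of burst amplitudes, with
replicate-resampling bootstrap intervals; the protective effect of
stoichiometric undamaged DNA is the retention difference with vs without
competitor, with a t-calibrated decision interval.

## Worked example

```python
from oggkit import aggregate_replicates, fit_burst, gen_time_course
from oggkit.synthetic import default_variants

spec = default_variants()["Wild-type"]
replicates = gen_time_course(spec, noise_sd=0.5, n_reps=3, seed=42)
fit = fit_burst(aggregate_replicates(replicates))
print(fit.A0, fit.k1, fit.k2)
```

Running `python examples/burst_kinetics_fit.py` (which does exactly this)
prints:

```
model chosen        : burst
burst amplitude A0  : 14.22 ± 0.09 nM   (truth 14.2)
burst rate k1       : 1.415 ± 0.032 min^-1 (truth 1.4)
linear rate k2      : 0.085 ± 0.006 nM/min (truth 0.09)
```

i.e. from a noisy simulated triplicate the fit recovers the generating
parameters within their standard errors: ~14 nM of the 20 nM substrate is
turned over in the burst, at 1.4 min⁻¹, followed by a ~0.09 nM·min⁻¹
steady state. The other scripts in `examples/` demonstrate Tm extraction
(`melt_tm_extraction.py`), the full retention/protection panel
(`thermolability_panel.py`), gel-densitometry quantification
(`gel_densitometry_roundtrip.py`) and the ODE cross-check
(`mechanistic_oracle.py`).

A thin CLI wraps the same functions for shell use:

```bash
oggkit simulate --seed 7 --outdir study
oggkit fit-kinetics --input study/kinetics.csv --outdir results
oggkit fit-melt --input study/melts.csv --outdir results
oggkit thermolability --input study/preincubation_panel.csv --outdir results
```

Every run writes its resolved configuration and seed next to its outputs.

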