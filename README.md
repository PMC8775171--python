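# pulsedigest

Kinetic modelling of *in vitro* macronutrient digestion and texture
softening in cooked pulses (chickpea, pea, black bean), for food scientists
studying how the intact cotyledon cell wall modulates starch and protein
hydrolysis.

When pulses are hydrothermally cooked to their residual-hardness plateau
and mechanically disintegrated, the characteristic microstructure is the
individual cotyledon cell (ICC): gelatinised starch and protein
encapsulated by an intact cell wall. This package implements the
quantitative pipeline that links those structures to digestion behaviour:

* **Assay conversions** — DNS reducing-sugar readings to digested starch
  (maltose equivalents × 0.95 / total starch × 100) and OPA free-amino
  readings to digested soluble / readily bioaccessible protein
  ((NH₂ − NH₂,initial)/NH₂,total × 100), with OLS standard curves.
* **Kinetic models** — the fractional conversion model
  C(t) = C_f + (C_i − C_f)·e^(−kt) for digestion and hardness decay, and
  the lag-phase logistic
  C(t) = C_f / (1 + exp[4·k_max/C_f·(λ − t) + 2]) for cell-wall-delayed
  starch digestion; both are scikit-learn-style regressors
  (`FractionalConversionModel`, `LagLogisticModel`) fitted by bounded
  trust-region least squares with Latin-hypercube multi-start, plus
  analytic initial reaction rates (tangent slope at t = 0), corrected-AIC +
  lag-significance model discrimination, and normalised starch–protein
  digestion correlation.
* **Joint confidence regions** — SSE-contour regions
  SSE(θ) ≤ SSE(θ̂)·(1 + p/(n−p)·F(p, n−p, 1−α)) for parameter pairs such
  as (k, C_f), with polygon overlap testing between samples.
* **Texture alignment** — softening kinetics from 25-seed hardness
  batches, % hardness reduction, and the earliest cook time reaching the
  42 ± 3 N residual-hardness plateau.
* **Particle sizes** — ICC yield as the volume fraction in the 76–133 µm
  window of a binned volumetric PSD, volume-weighted mean size, modality.
* **Composition** — fiber-rich residue (FRR) by difference and the
  starch/protein, starch/FRR and seed-coat/cotyledon ratios.
* **Synthetic data** — generators for every input (digestion tubes, assay
  plates, seed hardness, multimodal log-normal PSDs) with presets carrying
  the three pulses' parameter values, so the whole pipeline runs and is
  tested without laboratory data.

## Worked example

Simulate a black-bean starch digestion course at the default study
conditions (sampling at 0–180 min, duplicate tubes, 2 %-digested noise),
let model discrimination decide between the two kinetic models, and fit
the softening profile:

```python
import pulsedigest as pdg
from pulsedigest.synthetic import (
    generate_digestion_timecourse, generate_hardness_measurements,
)
from pulsedigest.texture import (
    fit_hardness_profile, hardness_reduction_percent, plateau_alignment_time,
)

tc = generate_digestion_timecourse("BB", "starch", seed=7)
decision = pdg.discriminate_models(tc)
fit = decision["fits"][decision["choice"]]
print(f"chosen model: {decision['choice']}")
for name, value in fit.params.items():
    print(f"  {name} = {value:.3f} +/- {fit.standard_errors[name]:.3f}")
print(f"  initial rate = {pdg.initial_reaction_rate(fit):.2f} %/min")

profile = generate_hardness_measurements("BB", seed=7)
hfit = fit_hardness_profile(profile)
print(f"softening: k = {hfit.params['k']:.4f} 1/min, "
      f"residual = {hfit.params['Cf']:.1f} N, "
      f"reduction = {hardness_reduction_percent(hfit):.0f}%, "
      f"align at {plateau_alignment_time(hfit, sampling_interval=profile.sampling_interval):.0f} min")
```

Output:

```
chosen model: logistic
  Cf = 99.775 +/- 0.741
  kmax = 1.313 +/- 0.028
  lambda = 11.943 +/- 0.798
  initial rate = 0.33 %/min
softening: k = 0.0435 1/min, residual = 40.7 N, reduction = 71%, align at 85 min
```

The discrimination correctly detects the black bean's cell-wall lag phase
(λ ≈ 12 min here; true value 11 min) and rejects the lag-free fractional
conversion model; the low initial rate (0.33 %/min) is the kinetic
signature of that lag. The softening fit recovers the slow black-bean
softening rate (truth 0.046 min⁻¹) and a ~70 % hardness reduction to the
residual plateau, reached on this cook-time schedule at 85 min.

A `pulsedigest` command-line tool exposes the same stages
(`simulate`, `quantify`, `fit`, `jcr`, `texture`, `psd`, `report`); the
`report` subcommand runs the whole config-driven pipeline and writes a
deterministic report bundle (fits as JSON, tables as CSV, run log).

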