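# Methods

## Scientific setting

Pulses cooked to their residual-hardness plateau and gently disintegrated
break along the middle lamella into individual cotyledon cells (ICC):
intact cell walls encapsulating gelatinised starch and protein. The cell
wall acts as a physical barrier to digestive enzymes, so digestion
kinetics of hardness-aligned pulses isolate the effect of that barrier
from the confound of different cooking extents. The package quantifies
each link in that argument: texture decay → alignment time, particle
sizes → ICC yield, assay readings → digested-%, digested-% → kinetic
parameters → rates, regions and correlations.

## Kinetic models

**Fractional conversion** (first-order approach to a plateau),

    C(t) = Cf + (Ci − Cf)·exp(−k·t),

describes hardness decay during cooking (Ci initial hardness N, Cf
residual hardness N, k min⁻¹ softening rate) and starch/protein digestion
(values in % digested). It is monotone between Ci and Cf with initial
rate k·(Cf − Ci).

**Lag-phase logistic**,

    C(t) = Cf / (1 + exp[4·kmax/Cf·(λ − t) + 2]),

parameterises a sigmoid by its plateau Cf (%), the tangent slope at the
inflection kmax (% min⁻¹) and the lag duration λ (min) — the time-axis
intercept of that tangent. At t = λ the value is Cf/(1+e²) ≈ 0.119·Cf.
It captures the delayed onset of starch digestion behind an intact cell
wall; with λ → 0 it does not reduce to the fractional conversion model
(the two are separate empirical families, hence the explicit
discrimination procedure below).

### Fitting

Parameters are estimated by nonlinear least squares over *individual*
observations (tubes, duplicate assay readings, single seeds) — never
per-time means — so replicate scatter propagates into the parameter
covariance. The optimiser is scipy's bounded trust-region reflective
least squares with analytic Jacobians; bounds are k, kmax > 0, λ ≥ 0, and
Cf deliberately unbounded above (plateaus slightly above 100 % digested
are legitimate estimates given assay calibration error, and clamping
would bias them). Starting values are data-driven (first/last
observations for Ci/Cf; k from a log-linearisation of the first two
thirds of the curve; λ from the first crossing of Cf/(1+e²)), refined by
a 10-point Latin-hypercube multi-start over wide ranges around them; the
best SSE wins. Fitting is deterministic given data and settings (the
multi-start sampler is seeded).

Standard errors come from the Jacobian-based covariance
σ̂²·(JᵀJ)⁻¹ with σ̂² = SSE/(n−p); R²_adj = 1 − (1−R²)(n−1)/(n−p−1).
For starch digestion the default fixes Ci = 0 (the oral phase uses no
amylase, so no starch is digested at t = 0); for protein and hardness Ci
is estimated, because gastric proteolysis solubilises protein before the
small-intestinal phase begins and raw seeds have unknown hardness. Which
convention was used is recorded in every fit.

### Model discrimination

Both models are fitted; the logistic is selected only when (a) the
estimated λ is positive with its 95 % t-interval excluding 0 and (b) its
corrected AIC (AICc with the noise variance counted as a parameter,
n = observations) beats the fractional conversion fit. Otherwise the
fractional conversion model is kept — "no meaningful lag estimate" is an
explicit, traceable outcome, returned with both fits and the decision
diagnostics.

### Initial rates and normalised correlation

Initial reaction rates are analytic tangent slopes at t = 0: k·(Cf − Ci)
for fractional conversion and 4·kmax·e^(u₀)/(1+e^(u₀))² with
u₀ = 4·kmax·λ/Cf + 2 for the logistic (both are verified against central
finite differences in the tests). The starch–protein interdependency is
summarised by evaluating both fitted curves on a common grid, normalising
each by its own plateau, and reporting the Pearson correlation of the
paired trajectory.

## Joint confidence regions

Marginal intervals ignore the strong (k, Cf) correlation of nonlinear
fits, so sample comparison uses the SSE-ratio joint confidence region

    SSE(θ) ≤ SSE(θ̂)·(1 + p/(n−p)·F(p, dfd, 1−α)),  p = 2.

The default denominator degrees of freedom are dfd = n−p (the
conventional Beale region, exact for linear models); dfd = n−1 is
available via `f_convention="n-1"` for compatibility with the alternative
printed convention — for the study's n the numerical difference is small.
The region boundary is extracted as the threshold contour of the SSE
surface on a 201 × 201 grid spanning ±6 SE per parameter, auto-doubled
until the contour closes around the point estimate. Parameters outside
the pair are fixed at their estimates by default (matching the 2-D
presentation); profiled SSE (re-optimising nuisance parameters per grid
point) is available and can only enlarge the region. Overlap between two
samples' regions is a shapely polygon intersection, reported as a
fraction of the smaller region's area so "do they overlap and by how
much" is explicit rather than visual. Coverage checks evaluate the SSE
inequality directly at the true parameter point, which is the exact
membership test the contour approximates.

## Texture alignment

The softening fit yields hardness reduction (Ci − Cf)/Ci·100 and the
plateau alignment time t = ln((Ci − Cf)/tol)/k — the earliest time at
which predicted hardness is within `tol` of the residual plateau. The
default tolerance is 3 N, the spread of the residual-hardness band
(42 ± 3 N); alignment times are rounded *up* to the profile's sampling
interval because cook times are chosen on a discrete schedule.

## Particle sizes

ICC yield sums bin volume-% over bins whose geometric centre
√(low·high) lies in the 76–133 µm window. Geometric centres match the
log-spaced binning of diffraction instruments; boundary bins are counted
whole rather than split — a stated convention, testable and monotone in
the window. The volume-weighted mean is Σ(centre·volume)/100. Modes are
local maxima after a 3-bin moving average, kept at ≥ 5 % prominence of
the global maximum; the threshold is a default, since unimodal vs
multimodal calls are otherwise qualitative.

## Composition

FRR (fiber-rich residue) is the remainder
100 − (moisture + protein + starch + lipid + ash), computed at full
precision (ratios are rounded to 2 decimals only for reporting).
Dry-matter vs as-is basis is carried as metadata without automatic
conversion — converting would require dry-matter factors that are not
part of the inputs. The seed-coat/cotyledon ratio is w/(1−w) for
seed-coat mass fraction w.

## Synthetic data: what it emulates, and what not

The generators reproduce the sampling structure of the experiments:

* digestion courses on the grid {0, 5, 10, 15, 30, 60, 90, 120, 180} min
  with duplicate tubes and additive Gaussian noise, default SD 2
  %-digested units (replicate noise magnitudes are shown only as error
  bars in the study figures, so the default is a stated choice, not a
  fitted one);
* assay plates constructed by inverting the concentration formulas and
  the standard curve, choosing the smallest dilution that keeps readings
  under the calibration ceiling — so quantification is the generator's
  exact inverse at zero noise;
* hardness batches of 25 seeds per cook time with mean-proportional
  scatter (default CV 10 %), reproducing the smaller absolute spread
  observed at the plateau;
* PSDs as deterministic mixtures of analytic log-normal modes placed on
  log-spaced bins (free material ≈ 30 µm, ICC at each pulse's mean cell
  size, seed-coat clusters ≈ 300 µm).

Presets CP/PE/BB carry the reported point estimates as ground truth.
Values never reported are package choices: raw hardness Ci ≈ 135–145 N
(the scale of the softening figures), chickpea/pea softening rates
0.095/0.085 min⁻¹ (complete softening by 30 min, vs the black bean's
reported 0.046 min⁻¹ reaching plateau at 60 min), black-bean logistic
(Cf 100 %, kmax 1.3 % min⁻¹, λ 11 min; kmax from the closely matching
Bambara-groundnut ICC comparison), and gastric-baseline soluble protein
of 25/37/30 % for CP/PE/BB.

What passing tests therefore show: the estimators are unbiased and
calibrated *under Gaussian, homoscedastic, independent noise on the true
model family*. Real digestion data may have time-correlated errors
(shared enzyme batches), heteroscedastic assay error, and model
misspecification; none of those are emulated, so parameter SEs and JCR
coverage on real data should be read as approximations.

## Numerical choices and edge cases

* exp arguments are clipped at ±700 so far-from-optimum multi-start and
  grid probes cannot overflow.
* Covariances use a pseudo-inverse of JᵀJ and are symmetrised; diagonal
  entries are floored at 0 before square roots.
* Negative digested-protein percentages (readings below the gastric
  baseline) are returned with a warning, not rejected — they are
  legitimate baseline noise at early times.
* Absorbances outside the calibration range extrapolate with a warning:
  the single-reactor design leaves no re-dilution path.
* Fits require > p observations and ≥ 5 distinct times; order of
  observations never affects the result.
* Region contours that fail to close raise after 8 grid doublings rather
  than returning a truncated polygon.

## Problem sizes

The statistical suites use 500 simulated courses for fractional
conversion recovery and joint-region coverage, 200 for logistic lag
recovery and hardness-rate recovery, and 100 per class for model
discrimination — sizes at which Monte-Carlo error is comfortably inside
the asserted tolerances (e.g. coverage SE at n = 500 is ≈ 0.01 against a
±0.03 band) while the full suite runs in about a minute.

## Known limitations

* The two kinetic families are non-nested; AICc comparison is standard
  but heuristic, and the lag CI uses the Wald approximation.
* Fixed-at-estimate nuisance handling understates JCR area when the
  nuisance parameter is strongly correlated with the pair (profiling is
  provided but slower).
* PSD window membership by bin centre makes yields depend slightly on the
  instrument's binning; no bin splitting is attempted.
* No mechanistic (Michaelis–Menten) digestion modelling and no inversion
  of raw diffraction patterns — both out of scope by design.
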