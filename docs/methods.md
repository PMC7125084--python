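# Methods

`rhizocohere` implements the quantitative chain of reasoning by which
root hairs of *Arabidopsis thaliana* are shown to strengthen root–substrate
cohesion and slow concentrated-flow soil erosion.  Five analysis stages sit
on a common synthetic-data layer; each stage is summarised below with its
model, assumptions, tunable parameters and numerical choices.

## 1. Centrifuge detachment mechanics (`centrifuge`)

Seedlings grown on a gel plate are spun in a hanging-bucket centrifuge with
stepwise 1-minute speed increments.  The rotor speed at setting *n* is
720·√n RPM (settings 1–5 in the assay, so 720, 1018, 1247, 1440, 1611 RPM),
giving an angular velocity ω = 2π/60·720·√n rad s⁻¹.  Balancing moments
about the bucket pivot bounds the bucket's deviation from perpendicular
swing-out by tan θ < g/(0.07·ω²); at the slowest setting θ < 1.41°, so the
plate is treated as exactly perpendicular and each seedling experiences the
peeling force

    Fc = Ms · radius · ω²        (radius = 0.07 m)

proportional to its aerial tissue mass *Ms*.  At setting 1 this is already
≈ 41 g of centripetal acceleration.  Detachment outcomes form
right-censored survival data on the force scale: a seedling still attached
after the fastest spin is censored at the force it survived, which is
mass-specific.  `detachment_curve` uses the Kaplan–Meier estimator
(lifelines) on per-seedling forces; tied forces drop the curve once.
Proportional-hazards regression on the exported event tables is
deliberately out of scope — `export_event_table` produces the
analysis-ready rows (force, event flag, genotype, plate, spin count) that
standard survival tooling consumes.

Parameters: `gravity` defaults to 9.81 m s⁻² and is configurable; the
moment-arm coefficient and the attachment radius are both 0.07 m but are
held as separate fields since they play different mechanical roles.

## 2. Uprooting trace analysis (`uprooting`)

A vertically pulled plant responds elastically, f(x) = k(x)·x, up to the
peak displacement x_p, after which damage accumulates and the force falls,
f(x) = f(x_p) + h(x−x_p)·(x−x_p) with h < 0, reaching zero at the
uprooting displacement x_u.  The latent moduli k and h are never estimated;
peak force and total energy (the area under the trace) are the macroscopic
summaries, alongside the magnitudes of discrete force drops (individual
root or bond failures).

Numerical choices:

* **Noise threshold** — the load cell is accurate above 0.05 N; that value
  is the default analysis floor with 0.1 and 0.035 N exposed for
  sensitivity analysis.
* **Energy** — trapezoidal integration from zero to the uprooting point,
  defined as the *last* downward crossing of the threshold (sub-threshold
  tails are below the sensor floor and are dropped; on noise-free synthetic
  traces a vanishing threshold recovers the closed-form area to <0.1%).
* **Drops** — peak-to-trough declines on the (optionally moving-median
  smoothed, default off) load sequence, filtered by `min_drop`.  The
  terminal decline is excluded when it ends below the threshold, because
  that decline is the pull-out event itself rather than an incremental
  failure.
* **Per-root normalisation** — metrics are divided by total root length
  (dry mass × specific root length), the printed per-metre-of-root units;
  RLD follows as length / container volume.

## 3. Empirical erosion models (`erosion`)

Each flume run captures sediment for 5 s at 10 s spacing (≤ 120 s total)
over a 0.25 × 0.25 m box on a 28° slope under 1 l s⁻¹ of flow.  Per-run
detachment rate is the arithmetic mean of interval rates
(mass / area / duration); the alternative total-mass/total-time reading
gives the same value for equal durations.  Rates are normalised by the
bare-soil rate *extrapolated to RLD 0* from an A₀·exp(b·RLD) fit in which
bare control boxes enter at RLD 0 — not by the bare-box mean alone.

Model forms are chosen per genotype, not by automatic selection: pure
exponential exp(b·RLD) for the haired lines (forced to 1 at RLD 0 after
normalisation), and for the hairless line a piecewise form — exponential
below the 19 km m⁻³ breakpoint, constant (the mean ratio) above it, not
constrained continuous.  Fits are untransformed least squares
(scipy `curve_fit`); a log-ratio fit is available through the
decay-to-plateau form.  Standard errors are asymptotic, with a
heteroscedasticity-robust (sandwich) covariance for the exponential
coefficient because interval noise is multiplicative and a homoscedastic
covariance understates the sampling spread of b by roughly 1.6×.

**Monte-Carlo bands.**  Each parameter is redrawn from a normal centred on
its estimate with sd equal to its standard error (10,000 draws by default,
seeded); per-grid-point 2.5/97.5 percentiles form the 95% band.  Plateau
draws are clipped to [0, 1] and exponent draws to b ≤ 0, the model's
physical range.  Two genotypes are flagged significantly different
(P < 0.05) at grid points where each point curve falls outside the other's
band.  The band's empirical coverage is validated in the standard sense:
across replicate synthetic campaigns the fitted band contains the
generating curve at every grid point in ≥ 90% of cases.

## 4. Cohesion back-calculation (`cohesion`)

With the detachment rate measured, the EUROSEM detachment-efficiency
coefficient is the only unknown:

    β = ASD / (B_D · v_s · C_TC)

evaluated in the CGS units the law was calibrated in (ASD in g cm⁻² s⁻¹,
B_D in g cm⁻³, v_s in cm s⁻¹); the package is SI elsewhere and converts at
this boundary.  The denominator reading — bulk density × settling velocity
× transport capacity as a plain product — is a documented interpretation of
an ambiguously typeset source expression; every factor can be overridden
independently.  The transport-capacity term C_TC is a required input: the
assay does not determine it.

Settling velocity is √(4·d₅₀·(ρ_s−ρ_w)·g / (3·C_D·ρ_w)) with the
intermediate-Reynolds drag law C_D = 24/Re + 3/√Re + 0.34 (no specific law
is prescribed by the source; alternatives can be passed as a fixed C_D).
Without a supplied C_D the velocity is iterated to the self-consistent
fixed point v → Re(v) → C_D → v (tolerance 10⁻⁸, ≤ 100 iterations); for
the 16 μm grains this sits within 5% of Stokes' law.

Cohesion follows from C = −ln(β/0.79)/0.85 kPa.  β > 0.79 would imply
negative cohesion; such values return 0 kPa with a warning (a physical
floor that keeps downstream fits defined).  Root reinforcement is rooted
minus bare cohesion, and its growth with RLD is fitted by the
origin-anchored logarithmic model a·ln(RLD+1) via linear least squares in
the transformed predictor.

## 5. Mechanistic erosion model (`mechanistic`)

The mechanistic model predicts relative detachment from first principles:

* **Bed shear** τ = 3gQd₅₀²·sin(28°)/(2VkW) ≈ 21.6 Pa at the default flow
  (Q = 10⁻³ m³ s⁻¹, V = 1 m s⁻¹, k = 0.2273 μm², W = 0.36 m), consistent
  with the 13–24 Pa operating range over measured surface velocities.
* **Kite root volume** — each root system occupies two coaxial cones
  sharing a base of diameter 0.1 m (vertical extent D = 0.1 m),
  V = π·spread²·D/12 ≈ 2.6×10⁻⁴ m³.  The depth of maximum spread d only
  splits this volume between the cones and does not change the total — a
  recorded limitation of the cone-pair idealisation.  True root length
  density RLD_T divides total root length by the root-occupied volume,
  capped at the fully rooted slab.
* **Root-hair enhancement** γ(x) = M_max·tanh(M1·x/M_max) in mm⁻¹:
  initial slope M1, ceiling M_max = M1/M2.  The tanh argument uses RLD_T
  on the m m⁻³ scale (RLD_T in km m⁻³ × 1000).  This scale is forced by
  internal consistency of the calibrated parameter magnitudes
  (M1 ~ 5×10⁻³, M_max ~ 100): it places saturation at RLD_T ≈ M_max/M1 ≈
  25 km m⁻³, exactly where hairless-line erosion stops improving, whereas
  a km m⁻³ argument would leave γ purely linear over the whole observed
  range and M_max unidentifiable.
* **Heterogeneous Coulomb cohesion** — local cohesion is
  c(x) = c_bare·(1 + γ·ρ(x)) with the reinforced depth ρ interpolating
  sinusoidally between r (midway between plants) and R = 50 mm (the
  maximum erosion depth); erosion occurs where effective shear τ + μN
  exceeds c(x).  μN defaults to 0 (surface erosion).  The predicted
  relative detachment is the eroded fraction of one spatial period,

      F = 1 − arccos(w)/π,  w = clamp((u − (R+r)/2)/((R−r)/2), −1, 1),
      u = (τ_eff/c_bare − 1)/γ,

  which is independent of the period length.  This aggregation from the
  exceedance field to a detachment ratio is the package's reference
  interpretation (the source describes the criterion but not the
  aggregation); it reproduces the observed curve shapes qualitatively and
  is exactly testable against a spatial root-finding oracle.
* **Effective stress ratio** — the comparison τ vs c happens on one
  declared scale (Pa).  The default c_bare = 6.93×10⁻³ Pa is a calibrated
  model-scale quantity, chosen once so the saturated hairless curve
  (M_max = 88, r = 32.5 mm) plateaus at the observed 0.268 relative
  detachment; it is *not* a measured soil cohesion, and the absolute
  τ/c_bare ratio absorbs the unmodelled stress-concentration physics.
* **Calibration** — `calibrate_M` minimises the maximum relative error
  (the published accuracy figure; RMSE selectable) between model and
  observed (RLD, ratio) points over (M1, M_max), with near-zero
  observations floored at 0.01 in the denominator.  The search is a
  deterministic 40×40 log-grid scan polished by Nelder–Mead restarts from
  the best eight cells; noiseless self-generated curves are recovered to
  machine precision, and the genotype ordering of M_max
  (wild type > hair overproducer > hairless) is preserved.

With the default geometry the model's wild-type curve falls from 1 to 0
over roughly RLD 8–15 km m⁻³ — steeper than the empirical
exp(−0.095·RLD).  This is reported as a model-discrepancy diagnostic of
the reference interpretation rather than hidden by refitting; the
calibration targets in the test-suite are therefore self-generated curves,
which is also how the parameter table's identifiability is established.

## Synthetic data (`synth`)

The generators produce inputs with the statistical structure the analysis
assumes, under the study conditions:

* **Detachment cohorts** — aerial masses lognormal (median 20 mg, a
  placeholder scale: the true seedling-mass distribution is not
  published); latent detachment forces from a Weibull baseline
  (scale 0.04 N, shape 1.5, chosen so roughly a third of wild-type
  seedlings survive the fastest spin) with the genotype hazard ratio
  acting on the cumulative hazard (HR 6.369 hairless, 0.553 hair
  overproducer).  Each seedling detaches at the first setting whose
  mass-specific force reaches its latent force, else is censored.
* **Uprooting traces** — the piecewise elastic/damage baseline with
  drop-and-recover notches planted on the loading branch (a declining
  baseline would conflate a peak-to-trough measurement with the planted
  magnitude) and additive Gaussian sensor noise.  The closed forms
  peak = k₀x_p and E = ½k₀x_p·x_u make every extraction testable.
* **Erosion runs** — box RLD placed within the genotype's observed range
  (3–56, 8–48, 5–34 km m⁻³) according to its planting density
  (9–100 plants per box), expected relative detachment from the
  genotype's empirical model, and mean-one lognormal interval noise
  (σ = 0.3, matching the visible scatter of positive rates whose variance
  grows with the mean).  Three bare control boxes are appended.
* **Root populations** — truncated-normal SRL per genotype and substrate
  (e.g. wild type 0.63 ± 0.04 m mg⁻¹ in clay), lognormal dry masses.

A single seed fans out through fixed `SeedSequence` spawn keys (1 cohorts,
2 traces, 3 erosion, 4 roots), so generators are pure functions of
(parameters, seed) and mutually independent.

What the generators do **not** emulate: spatial correlation between
neighbouring interval captures, within-box RLD heterogeneity, plate-level
batch effects in the centrifuge assay, and any real covariance between
aerial mass and adhesion strength.  Passing tests therefore demonstrate
correctness of the estimators under the assumed noise structure, not
robustness to violations of it.

## Problem sizes

The test-suite and the reproduction script run the full campaigns at the
experimental sizes (18/17/27 flume boxes, ~88-seedling cohorts, 500-seedling
ordering checks) and reduced Monte-Carlo depths where depth is
irrelevant to the property being checked (1000-draw bands in the coverage
study, 100-replicate nested simulations); the analysis drivers use the full
10,000-draw bands.

## Known limitations

* The spatial-fraction aggregation and the effective stress ratio are
  interpretive choices; calibrated (M1, M2) values are comparable within
  this package but not bit-comparable with other implementations.
* The exponential extrapolation used for bare-rate normalisation is mildly
  misspecified for plateau-type genotypes, biasing their normalised
  plateau upward by a few percent (visible in the analysis drivers).
* Cox regression, image-based phenotyping and rainfall-event modelling are
  intentionally absent; event tables and fitted models are exported in
  formats those tools consume.
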