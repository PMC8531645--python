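# Methods

`contusim` re-creates, at desk scale, a surrogate-based uncertainty and
sensitivity analysis of controlled cortical impact (CCI) experiments on
porcine brain, together with the downstream evaluation of four tissue-level
injury metrics as predictors of cerebral contusion (CC). This note records
the models, the numerical choices, and what the synthetic ground truth does
and does not represent.

## The stand-in simulator

The original analysis rests on an explicit-dynamics finite-element (FE)
model of a porcine brain hemisphere indented by a rigid probe. Running such
a model is out of reach for a reusable analysis pipeline that needs ~10^5
evaluations, so `contusim.standin` replaces it with a documented
closed-form input–output map that plays the role of the ground-truth
simulator everywhere downstream. It maps the seven experiment/model
parameters

| symbol | meaning | range | marginal |
| --- | --- | --- | --- |
| `d_probe` | probe diameter (mm) | {5, 10, 15, 20} | discrete |
| `shape` | tip: 0 = cylindrical (flat), 1 = hemispherical | {0, 1} | discrete |
| `v_ind` | indentation velocity (m/s) | [0.4, 4] | uniform |
| `d_ind` | indentation depth (mm) | [1.1, 12.6] | uniform |
| `theta` | probe inclination (deg) | [−15, 15] | uniform |
| `mu_f` | DAM–probe friction (–) | [0.07, 0.26] | truncated normal, mean 0.163 |
| `t_m` | DAM (dura–arachnoid mater) thickness (mm) | [0.413, 1.058] | truncated normal, mean 0.736 |

to the four region-of-interest (ROI) injury metrics — the 95th percentiles
over the impacted region of peak maximum principal strain (MPS), its rate
(MPSR, 1/s), their product (MPSXSR, 1/s) and maximum shear strain (MSS):

```
MPS    = k_shape · c1 · (d_ind / 12.6) · (d_probe / 10)^γ_D · (1 + c2 · v_ind / 4)
MSS    = c_shear · MPS
t_c    = d_ind / (1000 · v_ind)                 # contact time, s
MPSR   = c3 · MPS · Γ(t_c + t0) / (t_c + t0)
MPSXSR = MPS · MPSR
```

where `Γ(t) = 1 − g1(1 − e^{−t/τ1}) − g2(1 − e^{−t/τ2})` is the brain's
quasi-linear viscoelastic (Prony) reduced relaxation function with the
porcine indentation-derived constants (g1 = 0.451, g2 = 0.301, τ1 = 0.021 s,
τ2 = 0.199 s), and `k_shape` is 1 for a hemispherical tip and `k_flat ≥ 1`
for a flat one.

The functional form encodes the qualitative structure of the FE response
that the pipeline has to reproduce: strain metrics quasi-linear and
strictly increasing in depth; rate metrics dominated by velocity, with a
depth response that saturates near the 12.6 mm upper bound (as depth grows,
the contact time grows proportionally, so `Γ(t_c)/t_c` plateaus — the
viscoelastic relaxation is exactly the mechanism that produces the
plateau); a modest power-law diameter effect; flat tips uniformly more
severe than hemispherical ones; and — by construction, in the default
`null_mode` — **exactly** zero dependence on inclination, friction and DAM
thickness. A `weak()` variant gives those three inputs relative effects of
order 10⁻³ for estimator-robustness experiments.

Two identities hold exactly in the stand-in and are stand-in properties,
not FE facts: `MPSXSR = MPS · MPSR` (which also sidesteps the ambiguity of
whether the percentile of a product or the product of percentiles is meant)
and `MSS = c_shear · MPS`.

### Calibration of the constants

The constants were fixed once, before any downstream analysis, and are not
fitting targets:

* `c_shear = 0.22 / 0.16 = 1.375`, the ratio of the published 50%-risk MSS
  and MPS thresholds;
* `c1 = 0.38`, `c3 = 4.0`, `t0 = 1 ms`, `k_flat = 1.15`: order-of-magnitude
  anchoring so that MPS and MPSR at severe experimental settings land near
  the published threshold scales (≈0.2–0.5 and ≈200 1/s). This is a
  calibration of scale, not a reproduction of FE values;
* `γ_D = 0.18` and `c2 = 0.7` were chosen by a closed-form variance budget:
  for a product of independent factors the first-order Sobol index ordering
  equals the ordering of the factors' relative variances, which here are
  depth 0.235 ≫ velocity 0.0173 > diameter 0.0084 > tip shape 0.0049 ≫ 0.
  That reproduces the qualitative importance structure of the reference
  analysis (depth first for strain metrics, velocity first for rate
  metrics, diameter third everywhere, shape fourth, the last three null)
  while keeping the diameter effect modest and quasi-linear.

The probe dwell time (50–200 ms in the experiments) does not alter peak
metrics in the stand-in and is ignored.

An auxiliary generator, `emulate_element_field`, scatters synthetic element
centroids around the impact point and draws per-element peak values whose
in-ROI 95th percentile recovers the scalar metrics to ~1%, with
exponentially attenuated values outside the 40 mm ROI. It exists so the
ROI-percentile reduction (`roi_percentile95`) can be exercised on
field-like data. Percentiles use the linear-interpolation (type-7)
convention throughout the package.

## Parameter space and sampling

All samplers share one unit-hypercube transform: uniform marginals are
affine; discrete marginals bin the unit coordinate into equal-probability
cells; normal marginals use the inverse CDF of a normal truncated at the
table bounds with the stated experimental mean and `sd = (upper−lower)/6`,
so the bounds sit near ±3σ and essentially all mass is in range. (The
stated means 0.163 and 0.736 sit a hair off the interval midpoints; the
printed values are adopted as-is.) Parameters are sampled independently.

* **Sobol designs** (surrogate training): unscrambled base-2 sequence,
  skipping the all-zeros leading point — bit-reproducible without a seed.
* **Latin hypercube** (sensitivity): one point per marginal stratum,
  seeded.
* **Monte Carlo** (uncertainty sweeps): i.i.d. marginal draws, optionally
  with one parameter pinned at a level.

## Surrogate ensemble

The surrogate is a weighted ensemble of six fully connected networks,
7:256:128:64:32:16:4, Softplus hidden activations and a rectified output
layer (predictions are non-negative by construction), trained full-batch
with Adam (learning rate 10⁻³) on the Huber loss (threshold d = 0.1) of
[0,1]-normalized outputs plus an L2 weight penalty. Inputs are min–max
normalized with the *fixed* table bounds (design-independent); output
normalization is frozen from the training targets. The 80-point Sobol
design splits deterministically: the last tenth of the design order is the
validation set (72 train / 8 validation).

Choices the reference description leaves open, fixed here after measuring
convergence on the 72-point training problem: L2 coefficient 10⁻⁶ (10⁻⁴
visibly underfits the rate metrics), at most 10,000 epochs, learning-rate
halving after 200 epochs without training-loss improvement (floor 10⁻⁵),
early stopping on the validation Huber loss with patience 2000 and
restoration of the best-validation weights. Training is pure numpy and
deterministic per seed.

Member output heads can occasionally collapse (a rectified output unit
dying for one metric on an unlucky initialization); output biases start at
0.5 to make that rare, and the ensemble weighting absorbs the rest: weights
live on the probability simplex and minimize the validation MSE (solved
with SLSQP, with a vanishing pull toward uniform weights to break exact
ties), so a collapsed member receives ~zero weight and the ensemble can
never do worse on validation than its best member.

Error reporting follows the normalized convention: per output, observed
values are min–max scaled to [0,1] and the absolute errors on that scale
yield nMAE, nRMSE and the 95th-percentile absolute error. The sample-size
study (10/20/40/80-point designs, 5-fold cross-validation) reports both
fold roles and selects the smallest size with all held-out errors below 4%.

## Uncertainty sweeps

The conditional Monte Carlo plan fixes each parameter in turn: 2 shape
levels + 4 diameters + 10 equally spaced levels (bounds inclusive) for each
of the five remaining parameters = 56 sweeps of 10,000 samples each. Each
sweep records the median and the 5th–95th percentile band per metric. The
body text and figure caption of the reference disagree on 95% vs 90%
intervals; the 90% interval (5th–95th percentiles) is used. All levels of
one swept parameter share their co-sample stream (common random numbers),
so a null parameter produces an exactly flat sweep and level-to-level
differences are not sampling noise; streams are spawned per parameter from
the master seed, so any sweep is recomputable in isolation.

## Sensitivity indices

Both global indicators are estimated from a single 10,000-point LHS design
("given data"), partitioned into M = 48 equal-count classes by the input's
quantile ranks (≈ n/200, standard given-data practice; levels themselves
for the two discrete inputs):

* **Borgonovo δ**: half the expected L1 distance between the output
  density and the class-conditional densities. Densities are binned kernel
  estimates — a 512-bin histogram on a common grid (pooled range padded by
  3 bandwidths) smoothed by a Gaussian kernel with Silverman's robust
  bandwidth `0.9·min(sd, IQR/1.34)·n^{−1/5}` — integrated by the
  trapezoidal rule.
* **First-order Sobol S1**: between-class variance of class means over
  total variance.

Both raw estimators are positively biased under independence (finite
classes never reproduce the marginal; E[S1] ≈ (M−1)/n ≈ 0.005 at these
settings — the size of the null bound itself). A null calibration is
therefore subtracted: the median estimate over 50 random permutations of
the output against the fixed partition; corrected estimates are clamped at
zero and flagged. Confidence intervals come from a 100-resample pair
bootstrap; the half-width of the central 95% interval is reported and, being
shift-invariant, applies to the corrected estimate. δ is exactly invariant
under monotone output transforms in the continuum; the KDE leaves a
bandwidth-dependent residual of a few percent, which the tests bound at
0.05.

Rankings sort each output's indicator descending, breaking ties by the
canonical parameter order.

## Injury-risk evaluation

The 14 in-vivo CCI cases (depth, velocity, binary cortical damage) ship as
a fixture table. Each case is evaluated at its depth/velocity with the
nominal probe (10 mm, hemispherical, 0°, friction 0.163, thickness
0.736 mm). Per metric:

* **Exact Wilcoxon rank-sum**: mid-ranks on the pooled values, full
  enumeration of group labelings (feasible up to combined n = 25);
  two-sided p is the null probability of a rank-sum deviation at least as
  large as observed.
* **Logistic risk curve** `p(X) = 1/(1+exp(−(b0 + b1·X)))` fitted by IRLS
  on standardized X (the reference prints the exponent as `−b0 + b1·X`;
  the standard sign convention is used, and the 50%-risk threshold is
  `−b0/b1`). Complete separation is detected structurally (disjoint class
  supports) and coefficients are then capped at |b| = 50 on standardized
  X and flagged; a constant predictor yields the no-information fit with
  an undefined threshold. The duplicate-input pair with opposite outcomes
  makes complete separation impossible on the real case table.
* **LOOCV**: 14 folds of 13; accuracy/sensitivity/specificity of the
  held-out predictions at the fixed 0.5 probability cutoff; testing AUC
  from the pooled held-out probabilities; training AUC mean/sd/best/worst
  across folds. AUC uses the Mann–Whitney formulation (ties half credit).

## Curve rating

Force–time curves are compared with a two-method rating: a corridor score
(inner/outer corridors at 5% / 50% of the reference peak, linear
transition, time-averaged) and a cross-correlation score combining
amplitude, shape and phase sub-scores with equal 1/3 weights (phase from
the best alignment shift within 20% of the evaluation interval, shape from
the correlation coefficient at that shift, amplitude from the ratio of L2
magnitudes after alignment; all transitions linear, kV = kP = kG = 1). The
overall rating is the equal-weight combination G1 = G2 = 0.5. Only the
combination weights, sub-weights and linear transitions are fixed by the
protocol this mirrors; corridor geometry, the phase window and the
activity-threshold evaluation interval (5% of peak) are package defaults,
configurable. The experimental force curve of the original validation
exists only as a figure and is not shipped; tests use synthetic pulse
pairs with known distortions.

## What the synthetic conditions do and do not show

Passing tests demonstrate that the statistical machinery — design
generation, surrogate training, uncertainty propagation, given-data
sensitivity estimation with honest null calibration, exact small-sample
inference, risk-curve cross-validation, curve rating — behaves correctly
on a ground truth whose structure is known. They do not certify FE-level
numbers: the published δ/S1 magnitudes, the injury thresholds
(0.16 / 245 s⁻¹ / 45 s⁻¹ / 0.22) and the rating sub-scores (0.880 / 0.773)
depend on the FE model and the experimental force curve and are outside
what a stand-in can reproduce. What is reproducible — and is asserted — is
the structure: the 56-sweep plan, the <4% surrogate error bar at 80
samples, the null bounds δ < 0.05 and S1 < 0.005, the importance rankings,
the equal-weight rating combination arithmetic, and the structural
consequences of the duplicate-input cases (identical predictions, forced
LOOCV misclassification, no complete separation).

Problem sizes used by the shipped analyses: 80-point training design,
10,000-sample sweeps and LHS sensitivity designs, 48 partitions, 100
bootstrap resamples, 50 null permutations — the same sizes the reference
analysis states, all adjustable through the configs.

## Known limitations

* The stand-in is multiplicative and smooth; it has no depth×velocity
  interaction (the reference defers that too) and no spatial output.
* The δ estimator's monotone-transform invariance is approximate (KDE
  bandwidth bias ~ few percent).
* Exact Wilcoxon enumeration is limited to combined n ≤ 25.
* The truncated-normal parameterization (sd = range/6) is a convention;
  only the means are stated by the source material.
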