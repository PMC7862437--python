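# Methods

## Scientific setting

`ddmexplore` models the first free choice of horizon-style two-armed bandit
games. Each game opens with four instructed plays that fix what the subject
has observed — an unequal \[1 3\] or equal \[2 2\] sampling of the two
machines — after which the subject makes 1 (horizon 1) or 6 (horizon 6) free
choices. Contrasting the *first* free choice between horizons isolates two
exploration strategies: **directed exploration** (an information bonus added
to the value of the less-sampled option) and **random exploration**
(decision noise that occasionally flips the choice). The package's central
question is mechanistic: when random exploration increases with horizon, is
that because the brain represents reward with a lower signal-to-noise ratio,
or because it demands less evidence before committing?

## Models

### Logistic choice model

For observed mean-reward difference ΔR = R_left − R_right (points) and
information difference ΔI ∈ {−1, 0, +1},

p(left) = 1 / (1 + exp(−(ΔR + A·ΔI + B) / (√2·σ)))

with information bonus *A* (points; shared across information conditions
within a horizon and only active in the unequal condition), spatial bias *B*
(points; per horizon × condition) and decision-noise SD σ (points; per
horizon × condition). Fitting is maximum a posteriori with an exponential
prior on σ (length scale 20 points, i.e. density ∝ exp(−σ/20) with mean 20)
and a zero-mean Gaussian prior (SD 20 points) on *A*. *B* carries no prior,
only a ±100-point optimizer bound for stability.

### Response-time regression

RT = β₀ + β_R·a·ΔR + β_I·a·ΔI, with the action a = +1 (left) / −1 (right).
Fit per subject × horizon × information condition by ordinary least squares
(statsmodels). In the equal condition a·ΔI never varies; the regressor is
dropped and β_I reported as NaN with a rank-deficiency flag.

### Condition-dependent drift-diffusion model

The decision variable follows dX = μ dt + c dW between absorbing boundaries
±β, starting at X(0) = αβ, with non-decision time T₀ and the diffusion
scale fixed at c = 1 (only the ratio of signal to noise is identifiable, so
the drift is read as a signal-to-noise ratio). Per trial,

- μ = c₀^μ + c_R^μ·ΔR + c_I^μ·ΔI  (drift)
- β = c₀^β + c_R^β·ΔR + c_I^β·ΔI  (threshold; trials resolving to β ≤ 0 are
  undefined and signalled)
- α = 2·L(c₀^α + c_R^α·ΔR + c_I^α·ΔI) − 1, L the logistic function, so the
  bias stays in \[−1, 1\].

Ten parameters (9 coefficients + T₀) are fit per subject per horizon by
maximizing the sum of log first-passage densities at the observed boundary
and response time.

### Boundary orientation and coefficient signs

"Left" is defined as the boundary whose hitting probability is the closed
form p_left = 1/(1+exp(2βμ)) − (1−exp(−2αβμ))/(exp(2βμ)−exp(−2βμ)), which
*decreases* in μ. Internally the left first-passage density is therefore
the lower-boundary Wiener density with drift +μ, separation 2β and relative
start (1+α)/2. Under this orientation reward-seeking behavior fits a
*negative* c_R^μ; all mirror symmetries hold, and every scientific quantity
(σ predictions, horizon ratios, contrasts) depends only on magnitudes and
ratios, never on the orientation. Consequently the equivalent logistic
noise is reported as a magnitude:

σ = |1 / (2√2 · c_R^μ · c₀^β)|  (threshold independent of ΔR, ΔI)

and analogously |1/(2√2·c₀^μ·c_R^β)| when instead the drift is condition-
independent.

The mean response time uses the standard unconditional first-passage
moment: RT = T₀ + (β/μ)tanh(βμ) + (β/μ)·2(1−exp(−2αβμ))/(exp(2βμ)−exp(−2βμ))
− αβ/μ. The final term is −x₀/μ (= −αβ/μ); this is the form the Monte-Carlo
simulator verifies. At α = 0 it reduces to T₀ + (β/μ)tanh(βμ), and as μ → 0
to T₀ + β²(1−α²).

## Numerical choices

- **First-passage densities**: the small-time / large-time series pair in
  the normalized (boundary-separation a = 2β, relative start w) form, with
  per-evaluation truncation-order selection at error tolerance 1e-6
  (Navarro–Fuss-style bounds). Branches are chosen per element; evaluation
  is vectorized over trials.
- **Taylor branches**: |βμ| < 1e-5 switches the choice probability to
  (1−α)/2 − βμ(1−α²)/2 and the mean decision time to β²(1−α²)(1−2αβμ/3),
  avoiding 0/0. For |βμ| > 50 the mean RT uses its drift-dominated
  asymptote.
- **Density floor**: likelihood evaluations clamp densities at 1e-29 so an
  impossible datum (rt ≤ T₀, or an invalid resolved threshold during
  search) contributes a finite penalty; floor hits are counted and reported
  as boundary violations rather than rejecting the step, so the optimizer
  can traverse near-boundary regions.
- **Path simulator**: Euler–Maruyama with step 1e-4 s (configurable) and a
  20 s cap. Each step also samples the Brownian-bridge probability of an
  intra-step boundary crossing (computed only within 5√dt of a boundary,
  where it is non-negligible); this removes the O(√dt) boundary bias of
  naive discrete crossing checks, which at dt = 1e-4 would otherwise be of
  the same order as the Monte-Carlo error bands used for validation. The
  simulator is a forward model and validation oracle only — it never enters
  the likelihood.
- **Optimization**: bounded L-BFGS-B, 10 starts (1 default + 9 dispersed
  from a seeded generator), best objective wins, ties to first found.
  Bounds: slopes ±2 per point, c₀^β ∈ (0, 5], pre-link bias coefficients
  ±5, T₀ ∈ \[0, min observed rt\] (the likelihood is zero beyond it).
  The logistic MAP fit uses the same scheme with bounds A, B ∈ ±100 and
  σ ∈ \[1e-3, 200\].

## Exclusion rules

Trials with rt < 0.1 s or rt > 3 s are removed — anticipatory responses and
lapses respectively, the conventional cuts for this task class. Subjects
must retain ≥ 131 trials in *both* horizon conditions.
Both operators are idempotent and order-preserving, and removal counts are
reported per subject × horizon.

## Sensitivity analysis

Because fitted cohorts sit in the regime c₀^α ≈ c_R^β ≈ c_I^β ≈ 0, the
diffusion model approximates the logistic model with σ = 1/(2√2·|c_R^μ|·c₀^β).
The analysis therefore reports, per subject, the horizon ratios
c_R^μ(h6)/c_R^μ(h1) and c₀^β(h6)/c₀^β(h1), whose product equals the
predicted σ(h1)/σ(h6) — exactly, by construction, on the predicted noise;
approximately on the independently fitted logistic σ. Cohort summaries use
the median of per-subject ratios (means are also emitted and labeled);
the dominant contributor is the coefficient with the larger |log median
ratio|. Horizon contrasts are two-sided paired t-tests with Bonferroni
correction for 10 comparisons (the correction factor is fixed at 10
regardless of how many rows a caller inspects). Correlations between
predicted and fitted σ are Pearson (Spearman emitted as a robustness
column).

## Synthetic study conditions

The generator's defaults define the package's study conditions:

- Rewards: Gaussian, SD 8 points, truncated to \[1, 100\] and rounded to
  integers. Truncation is implemented by rejection sampling (round, then
  resample if outside range): "truncated" names a distribution, and
  clipping would inflate mass at 1 and 100. Round-then-clip is available as
  a config option for comparison. One machine's mean is 40 or 60; the other
  sits 4, 8, 12, 20 or 30 points above or below; sides, gap sign and the
  instructed order are uniform.
- Horizon-1 coefficients: c_R^μ = −0.07, c_I^μ = −0.21 (information bonus
  ≈ 3 points), c₀^β = 0.85, T₀ = 0.25 s, all bias and threshold-slope
  coefficients 0. The implied logistic noise is ≈ 5.9 points and mean RTs
  run ≈ 0.6–1.1 s, matching the scale of first-free-choice behavior in
  this task class.
- Horizon-6 coefficients: c_R^μ scaled by 0.645 and c₀^β by 0.933 —
  horizon-effect ratios matching the effect sizes reported for this task
  class, so random exploration rises and the drift change dominates — and
  the information bonus raised to ≈ 12 points (directed exploration rises).
- Recovery-harness cohorts additionally disperse c_R^μ, c_I^μ and c₀^β
  across subjects by lognormal factors (log-sd 0.3, shared across horizons
  so generating ratios are preserved exactly) and draw T₀ uniformly in
  \[0.2, 0.35\] s. The remaining coefficients stay at 0 — the population
  in which the sensitivity analysis's approximation holds.

What the generator does *not* emulate: learning or strategy drift across
free choices 2–6 (only the first free choice is emitted), lapses and
attention failures, inter-trial parameter variability (the "full" DDM's
drift/start-point variability), and any reward-magnitude effects beyond the
linear ΔR terms. Passing tests therefore certify the machinery —
likelihoods, optimizers, exclusions, the analysis algebra — under the
model's own assumptions, not that human data obey those assumptions.

## Problem sizes

Validation suites use a 5×5×5 (μ, β, α) grid for density checks; 10⁵ paths
at dt = 1e-4 per parameter set for the Monte-Carlo oracle; and recovery
cohorts of 20 synthetic subjects × 160 trials per horizon (40 games per
horizon × condition cell), mirroring the ~131-trial inclusion floor.

## Known limitations

- c_I^μ recovery at 160 trials per horizon is the weakest of the focal
  parameters (only the ~80 unequal trials inform it, and it trades off
  against the ΔI-linked bias coefficient); its generating-vs-recovered
  correlation hovers near 0.75–0.8 where c_R^μ and c₀^β reach ≈ 0.9–0.99.
  Verified to be maximum-likelihood variance, not an optimizer artifact:
  refitting from the generating truth reaches the same optimum.
- T₀ estimates are bounded above by the fastest observed response and are
  slightly biased upward at these trial counts.
- The threshold's linear dependence on ΔR and ΔI can resolve to β ≤ 0 for
  extreme inputs; such trials are signalled (fitting) or resampled
  (generation), and the |ΔR|-threshold variant that would remove the
  asymmetry is an extension point, not implemented.
- The pipeline fits each subject independently; no hierarchical pooling.
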