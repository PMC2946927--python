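# Methods

## The analysis

The object of study is the sequence of inter-spike intervals (ISIs)
x₁, x₂, … of one unit, treated as a time series indexed by spike count,
not by clock time.  All scales below are non-dimensional ISI counts; this
makes units with different firing rates directly comparable, at the cost
that a given s maps to a different clock duration for each unit
(s/mean-rate seconds).

1. **Profile.**  Y(i) = Σ_{j≤i} x_j.  For constant-rate firing the profile
   is a straight line; rate drifts curve it.
2. **Detrending.**  At scale s the profile is divided into windows of
   length 2s with stride s (50% overlap).  A polynomial of order 3
   (configurable 1–5) is least-squares fitted to the profile against the
   window-local index and subtracted.  Cubic is the default because
   raising the order further does not materially change the outcome on
   cascade-like data, while order ≥ 1 is needed to remove rate trends.
   The residual y* carries the stochastic fluctuation at that scale.
3. **Increments.**  ΔY(i) = y*(i+s) − y*(i) for i in the first half of
   each window, so each index contributes exactly once.  A tail segment
   shorter than one window is dropped.  An alternative reading — using the
   residual itself as the fluctuation — is available via
   `detrended_increments` followed by custom post-processing, but the
   increment form is the default and the one all downstream statistics
   use: the fluctuation of interest is the one *cumulated over s events*.
4. **Standardization.**  σ_s is the standard deviation of the pooled
   increments at that scale (global per scale, not per window);
   standardized fluctuations ΔY/σ_s are dimensionless with unit sample SD.

### Non-Gaussianity parameter

The standardized fluctuation PDF is modeled as Castaing's log-normal
mixture: x = σ·z with z standard normal and ln σ ~ N(ln σ₀, λ²)
independent.  We fix ln σ₀ = −λ², the unique choice that makes the mixture
variance exactly 1, so standardized data introduce no extra free
parameter.  The mixture's absolute moments are
E|x|^q = m_q·exp(λ²q(q−2)/2) with m_q the Gaussian reference moment; the
moment estimator inverts this at one q:

    λ̂² = [2/(q(q−2))] · ln( ⟨|x|^q⟩ / m_q ).

Defaults: q = 0.25, bracketed by q = 1.0.  Low orders weight the bulk of
the distribution rather than the extreme tail, making the estimator usable
on heavy-tailed data; the model predicts the same λ² at every q, so
disagreement between the two orders is itself a diagnostic of
non-log-normality.  Both the mixture density (by adaptive quadrature over
ln σ) and the closed-form moment identity are validated against each other
in the test suite before the estimator relies on them.

Finite Gaussian samples produce slightly negative λ̂²; these are returned
unclipped, because clipping at zero would bias every null comparison
upward.

**Uncertainty.**  Standard errors come from a bootstrap over the
fluctuation values.  When window bookkeeping is available the bootstrap
resamples whole windows (moving-block), since values inside one detrending
window are strongly dependent and an iid bootstrap would understate the
error; otherwise it falls back to iid resampling.  Default 200 replicates.

### Magnitude correlation

Local energy e_k = (ΔY_k/σ_s)², indexed by the global ISI position of the
increment.  C(l)/C(0) is the lag-l autocorrelation of ln e (global mean
and variance), so it is invariant to any positive rescaling of the
energies.  Exact zero energies are floored at the smallest positive float
before the log.  Pairs are formed across window boundaries; the error band
for "no correlation" is 1/√n_pairs.

Two caveats shape the defaults.  Within one window (lags < 2s) increments
share a polynomial fit and overlap, which induces correlation even for
memoryless data; conclusions about the process should use l ≳ s.  For the
same reason `scale_collapse` compares curves only at lags at or above the
largest scale in the set, interpolating in log-lag and reporting the
maximum across-scale range of C(l)/C(0) — small values mean the curves
collapse, the cascade signature.

### Population operations

* `superpose` merges the units of one tetrode into a single-tetrode train;
  exact timestamp ties are kept (ordered by unit label and nudged by one
  float ulp so the merged train stays strictly increasing).
* `paired_state_test` applies a per-scale two-sided paired t-test to
  unit-level λ̂² values (awake − asleep).  P-values are reported per scale
  without correction — one test per scale is the convention the analysis
  follows — alongside a Holm-adjusted column for family-wise control.
* `overdivision_check` splits a train into two children with sequential
  uniform(0, d) cut gaps, alternating blocks.  Child ISIs spanning a
  removed block are excluded before analysis — the same rule used at
  sleep/wake epoch boundaries — because those gaps are artifacts of the
  division; keeping them lets a handful of d/2-sized intervals dominate
  σ_s and swamp the statistic.  The check verifies (i) the parent's λ̂²
  lies between the children's ± 3 bootstrap SE, and (ii) the q-moment
  mixture identity ⟨|x|^q⟩_parent ≈ ½(⟨|x|^q⟩_c1 + ⟨|x|^q⟩_c2), with all
  three samples standardized by the parent's σ_s (the identity only holds
  in a common unit system) and SEs taken over per-window means.

## Synthetic generators

The generators exist to give the analysis known ground truth, and double
as the surrogate machinery.

* **Poisson / renewal.**  iid ISIs (exponential, gamma, or Pareto with
  density tail x^(−α), α > 1 so the mean exists).  Renewal trains have
  zero ISI autocorrelation: any λ² they show comes from the marginal
  distribution shape alone and must decay toward 0 as s grows (CLT).
* **Dyadic log-normal cascade.**  A binary tree of `depth` levels over
  2^depth slots; each node draws an independent Gaussian log-weight with
  variance `level_var`, and a slot's log-amplitude is the sum along its
  root path.  ISIs are mean_isi·exp(h_i)·|1 + ε ξ_i| normalized to the
  target sample mean; ε = 0.1 keeps the ISI marginal unimodal while the
  absolute value enforces positivity.  Summing over s ISIs integrates out
  the ⌊log₂ s⌋ finest levels, so λ²(s) decreases by `level_var` per octave
  — the recovery tests exploit this as an exact ground truth.  The
  construction rule is the same at every level, which is why the magnitude
  correlation is scale-invariant.
* **Shuffle surrogate.**  A uniform random permutation of the ISIs;
  preserves the marginal multiset exactly, destroys all ordering.
* **Splitter / thinner.**  `split_train` implements the artificial
  over-division above; `thin_train` randomly assigns each spike to one of
  k child units, modeling neighboring neurons driven by one shared rate
  modulation (their superposition reproduces the parent exactly).

What the generators do *not* emulate: refractoriness, bursting,
non-stationary mean rates across behavioural states, measurement jitter,
and genuinely continuous (non-dyadic) cascades.  A passing test suite
therefore shows the statistics behave correctly on processes with known
structure; it does not certify any particular biological claim about real
recordings.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| scale grid | 10 log-spaced, 4–582 | ISIs | covers CLT onset to multi-minute scales at typical cortical rates |
| detrend order | 3 | — | removes rate trends; higher orders change little |
| q | 0.25 (bracket 1.0) | — | tail-robust; bracketing flags non-log-normality |
| bootstrap | 200 blocks | — | SE stable to ~5% |
| min series length | 1000 ISIs | — | shortest record that supports the grid's lower half |
| cascade ε | 0.1 | — | unimodal ISI marginal, cascade magnitudes intact |
| split d | 500–2000 | s | over-division cut scale of the consistency check |

Problem sizes in the validation runs (tests and `scripts/acceptance.py`)
are chosen so each statistical check has comfortable power at desk scale:
10⁶ samples for estimator recovery, 10⁵ events for baselines, 2¹⁴ events
for slope recovery, 2¹⁷ for magnitude-correlation collapse, 2¹⁸ per
tetrode for population logic, 2¹⁴ for the over-division check, and
1000–2000 cohort simulations for test calibration.

## Numerical notes and edge cases

* A profile that is exactly polynomial of the detrending order (e.g.
  constant-rate firing) leaves only rounding noise; σ_s below 10⁻⁹ of the
  profile magnitude raises a degenerate-series error rather than returning
  amplified noise.
* A 2s-point window must exceed order+1 points, so cubic detrending needs
  s ≥ 3; s = 2 requires order 1.
* Quadrature of the mixture density integrates over ln σ within ±10
  mixture SDs and fails loudly (with diagnostics) rather than silently
  returning an inaccurate tail value.
* Scales a series is too short for are skipped with machine-parseable log
  warnings; an analysis with no usable scale raises.
* Epoch splitting excludes boundary-spanning ISIs rather than bridging
  them (state segments are not contiguous in time); the flag is recorded
  in output metadata.
* All generators and analyses are pure functions of (parameters, seed);
  the pipeline derives named substreams (simulate / shuffle / bootstrap /
  split) from one root seed so components are independently reproducible.

## Known limitations

* λ̂² at the largest scales rests on few windows; its block-bootstrap SE
  is itself noisy there.  Treat single-unit values above s ≈ n/20 with
  care.
* The moment estimator assumes the log-normal mixture form; for strongly
  non-log-normal alternatives (e.g. pure heavy-tailed renewal data at
  small s) different q give different λ̂², which is informative but means
  "the" λ² is model-relative.
* Scale is ISI count, so comparisons across units mix clock durations;
  the package deliberately does not offer clock-time windowing.
* The tail diagnostic (`isi_tail_diagnostics`) is a least-squares
  comparison of log-linear vs log-log fits on a binned histogram — a
  screening tool, not a rigorous power-law test.
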