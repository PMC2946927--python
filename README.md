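# spikecascade

Multiscale non-Gaussianity analysis of neuronal inter-spike-interval (ISI)
fluctuations.

A neuron embedded in a network can retain activity correlations over time
scales far longer than its own membrane time constant.  One signature of
such long memory is that ISI fluctuations, aggregated over more and more
spikes, fail to converge to a Gaussian at the rate the central limit
theorem predicts.  `spikecascade` quantifies this failure and tests whether
its structure matches a multiplicative cascade — the hierarchical process
behind intermittency in turbulence and heartbeat variability — using only
spike times as input.  It is aimed at electrophysiologists and theorists
analyzing long (thousands of spikes) single-unit or tetrode recordings, and
at modelers who need calibrated synthetic spike trains with known
multiscale structure.

## Method

For an ISI series x_i, form the profile Y(i) = Σ_{j≤i} x_j.  At each
non-dimensional scale s (a number of ISIs), divide the profile into
half-overlapping windows of length 2s, subtract a least-squares cubic
polynomial in each window, and collect the lag-s increments of the
residual,

    ΔY_s(i) = y*(i + s) − y*(i),

standardized by their pooled standard deviation σ_s.  The distribution of
ΔY_s/σ_s is summarized with Castaing's equation: a log-normally weighted
superposition of zero-mean Gaussians of width σ, whose log-variance λ²
measures non-Gaussianity (λ² = 0 is exactly Gaussian).  Under this model
the absolute moments satisfy

    E|x|^q = m_q · exp(λ² q(q−2)/2),   m_q = 2^{q/2} Γ((q+1)/2)/√π,

which is inverted at a low moment order (q = 0.25, bracketed with q = 1.0)
to give a tail-robust estimator λ̂²(s).  Companion statistics:

* **magnitude correlation** C(l)/C(0): the lag correlation of ln e_k with
  local energy e_k = (ΔY_k/σ_s)²; it vanishes for uncorrelated amplitudes
  and is approximately scale-independent for multiplicative cascades;
* **surrogates**: ISI shuffling preserves the marginal distribution while
  destroying temporal order, separating distribution-shape from
  correlation contributions to λ²;
* **population tools**: superposed single-tetrode trains, per-scale paired
  awake/asleep t-tests across units, and an over-division (spike-sorting
  split) consistency check;
* **generators**: Poisson, renewal (exponential / gamma / power-law-tail
  ISIs), and a dyadic log-normal multiplicative cascade whose per-octave
  λ² decrement equals the generator's `level_var`, giving a known ground
  truth.

## Worked example

```python
import numpy as np
import spikecascade as sc

isi = sc.gen_cascade_isi(sc.CascadeParams(depth=14, level_var=0.05),
                         16384, seed=42)
lc = sc.lambda_curve(isi, q=0.25, n_boot=100, seed=43)
shuf = sc.lambda_curve(sc.shuffle_isi(isi, seed=44), q=0.25,
                       n_boot=100, seed=45)
print("scale  lambda2  se      shuffled")
for i in range(len(lc)):
    print(f"{lc.scales[i]:5d}  {lc.lambda2[i]:.3f}    "
          f"{lc.se[i]:.3f}   {shuf.lambda2[i]:.3f}")
m = (lc.scales >= 8) & (lc.scales <= 512)
slope = np.polyfit(np.log2(lc.scales[m]), lc.lambda2[m], 1)[0]
print(f"slope per octave: {slope:.3f}  (generator level_var = 0.05)")
```

prints

```
scale  lambda2  se      shuffled
    4  0.507    0.019   0.226
    7  0.446    0.020   0.147
   12  0.417    0.025   0.108
   21  0.355    0.034   0.062
   37  0.344    0.035   0.034
   64  0.262    0.042   0.017
  111  0.319    0.062   0.016
  192  0.268    0.083   0.003
  335  0.155    0.082   -0.016
  582  0.213    0.121   -0.016
slope per octave: -0.044  (generator level_var = 0.05)
```

The original cascade series keeps substantial non-Gaussianity across the
whole scale range, decaying roughly linearly in log₂ s with a slope that
recovers the cascade's per-level log-variance (0.05 per octave).  The
shuffled surrogate collapses toward the Gaussian value λ² ≈ 0 beyond a few
tens of ISIs: the persistence is carried by the temporal ordering, not by
the marginal ISI distribution.  Small negative λ̂² values are ordinary
finite-sample fluctuation around the Gaussian null and are deliberately
not clipped.

A config-driven run producing CSV tables, figures, and a provenance
manifest:

```sh
spikecascade run config.yaml
```

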