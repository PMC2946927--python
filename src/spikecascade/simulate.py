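"""Synthetic spike trains and ISI series with controlled multiscale structure.

Three generator families are provided:

* memoryless Poisson trains (exponential iid ISIs) — the null reference for
  the non-Gaussianity analysis;
* renewal trains with exponential, gamma, or power-law-tailed ISI marginals —
  non-Gaussianity from the distribution shape alone, with zero ISI
  autocorrelation;
* a discrete dyadic log-normal multiplicative cascade over the ISI
  log-amplitudes — non-Gaussianity that decays logarithmically with scale
  and carries scale-invariant magnitude correlations.

Surrogate operations (ISI shuffling, random over-division splitting,
spike thinning) implement the controls used alongside the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ParameterError
from .io import ISISeries, SpikeTrain


@dataclass(frozen=True)
class CascadeParams:
    """Dyadic log-normal cascade parameters.

    depth
        Number of cascade levels; the tree has 2**depth leaf slots.
    level_var
        Variance of the Gaussian log-weight drawn at each level
        (dimensionless).  This is the ground-truth per-octave decrement of
        lambda^2(s), enabling recovery tests.
    mean_isi
        Target sample-mean ISI in seconds.
    noise_eps
        Amplitude of the iid multiplicative noise |1 + eps*xi| applied on
        top of the cascade magnitudes; keeps the ISI marginal unimodal
        while preserving the cascade structure.
    """

    depth: int
    level_var: float
    mean_isi: float = 1.0
    multiplier_dist: str = "gaussian"
    noise_eps: float = 0.1

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError("cascade depth must be >= 1")
        if not self.level_var > 0:
            raise ParameterError("level_var must be > 0")
        if not self.mean_isi > 0:
            raise ParameterError("mean_isi must be > 0")
        if self.multiplier_dist != "gaussian":
            raise ParameterError(
                f"unsupported multiplier_dist {self.multiplier_dist!r}"
            )


@dataclass(frozen=True)
class RenewalParams:
    """iid ISI distribution family for renewal-train generation."""

    family: str  # exponential | gamma | powerlaw_tail
    rate: float | None = None
    shape: float | None = None
    scale: float | None = None
    alpha: float | None = None   # power-law exponent of the density tail
    cutoff: float | None = None  # power-law onset x_min (seconds)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family == "exponential":
            if self.rate is None or not self.rate > 0:
                raise ParameterError("exponential family needs rate > 0")
        elif self.family == "gamma":
            if not (self.shape and self.shape > 0 and self.scale and self.scale > 0):
                raise ParameterError("gamma family needs shape > 0 and scale > 0")
        elif self.family == "powerlaw_tail":
            if self.alpha is None or self.alpha <= 1:
                raise ParameterError(
                    "power-law exponent alpha must exceed 1 (finite mean)"
                )
            if self.cutoff is None or not self.cutoff > 0:
                raise ParameterError("powerlaw_tail needs cutoff > 0")
        else:
            raise ParameterError(f"unknown renewal family {self.family!r}")


def gen_poisson(rate: float, n_events: int, seed: int | np.random.Generator) -> SpikeTrain:
    """Homogeneous Poisson spike train with ``n_events`` spikes.

    ISIs are iid exponential with mean 1/rate; the first spike is at t=0
    plus one exponential draw.
    """
    if not rate > 0:
        raise ParameterError("rate must be > 0")
    if n_events < 2:
        raise ParameterError("need n_events >= 2")
    rng = np.random.default_rng(seed)
    isis = rng.exponential(1.0 / rate, size=n_events)
    return SpikeTrain(
        times=np.cumsum(isis),
        unit_id="poisson",
        meta={"model": "poisson", "rate": rate},
    )


def gen_renewal(params: RenewalParams, n_events: int, seed: int | np.random.Generator) -> ISISeries:
    """iid ISI draws from the requested family.

    For ``powerlaw_tail`` the ISI is Pareto: density ~ x**(-alpha) for
    x > cutoff, so the survival function decays as x**-(alpha-1).
    """
    if n_events < 1:
        raise ParameterError("need n_events >= 1")
    rng = np.random.default_rng(seed)
    if params.family == "exponential":
        values = rng.exponential(1.0 / params.rate, size=n_events)
    elif params.family == "gamma":
        values = rng.gamma(params.shape, params.scale, size=n_events)
    else:  # powerlaw_tail
        # inverse-CDF Pareto draw: S(x) = (x/cutoff)^-(alpha-1)
        u = rng.random(n_events)
        values = params.cutoff * u ** (-1.0 / (params.alpha - 1.0))
    return ISISeries(
        values=values,
        source={"model": "renewal", "family": params.family},
    )


def gen_cascade_isi(
    params: CascadeParams,
    n_events: int,
    seed: int | np.random.Generator,
) -> ISISeries:
    """ISI series whose log-amplitudes carry a dyadic multiplicative cascade.

    A binary tree of ``depth`` levels is built over ``2**depth`` slots; every
    node carries an independent Gaussian log-weight of variance
    ``level_var``, and a slot's log-amplitude h_i is the sum of the weights
    on its root path.  ISIs are

        ISI_i = mean_isi * exp(h_i) * |1 + eps * xi_i| / normalization,

    with xi_i iid standard normal, and the normalization fixing the sample
    mean to ``mean_isi``.  The absolute value enforces ISI positivity.

    ``n_events`` beyond the leaf count is rejected (increase depth);
    fewer events truncate the leaf sequence.
    """
    n_slots = 2 ** params.depth
    if n_events > n_slots:
        raise ParameterError(
            f"n_events={n_events} exceeds 2**depth={n_slots} slots; "
            f"use depth >= {int(np.ceil(np.log2(n_events)))}"
        )
    rng = np.random.default_rng(seed)
    sd = np.sqrt(params.level_var)
    h = np.zeros(1)
    for _ in range(params.depth):
        # each node splits in two; children add their own log-weight
        h = np.repeat(h, 2) + rng.normal(0.0, sd, size=2 * h.size)
    h = h[:n_events]
    xi = rng.normal(size=n_events)
    raw = np.exp(h) * np.abs(1.0 + params.noise_eps * xi)
    # guard: |1+eps*xi| can be exactly 0 only on a null set; floor anyway
    raw = np.maximum(raw, np.finfo(float).tiny)
    values = params.mean_isi * raw / raw.mean()
    return ISISeries(
        values=values,
        source={
            "model": "cascade",
            "depth": params.depth,
            "level_var": params.level_var,
            "mean_isi": params.mean_isi,
            "noise_eps": params.noise_eps,
        },
    )


def shuffle_isi(series: ISISeries, seed: int | np.random.Generator) -> ISISeries:
    """Uniform random permutation of the ISIs (surrogate control).

    Preserves the ISI multiset exactly while destroying all temporal
    correlations.
    """
    if len(series) < 2:
        raise ParameterError("need >= 2 ISIs to shuffle")
    rng = np.random.default_rng(seed)
    return ISISeries(
        values=rng.permutation(series.values),
        source={**series.source, "surrogate": "shuffled"},
    )


def split_train(
    train: SpikeTrain, d: float, seed: int | np.random.Generator
) -> tuple[SpikeTrain, SpikeTrain]:
    """Artificial over-division of one train into two child trains.

    Cut points are placed sequentially from the start of the train with
    uniform(0, d) gaps; alternating blocks go to child 1 and child 2.  Every
    spike lands in exactly one child and within-child order is preserved.
    """
    if not d > 0:
        raise ParameterError("cut-scale d must be > 0")
    rng = np.random.default_rng(seed)
    t0, t1 = train.times[0], train.times[-1]
    cuts = []
    t = t0
    while True:
        t = t + rng.uniform(0.0, d)
        if t >= t1:
            break
        cuts.append(t)
    cuts = np.asarray(cuts)
    block = np.searchsorted(cuts, train.times, side="right")
    mask1 = block % 2 == 0
    children = []
    for tag, mask in (("child1", mask1), ("child2", ~mask1)):
        children.append(
            SpikeTrain(
                times=train.times[mask],
                unit_id=f"{train.unit_id}:{tag}",
                tetrode_id=train.tetrode_id,
                meta={
                    **train.meta,
                    "split_d": d,
                    "split_rule": "uniform(0,d) inter-cut gaps",
                    "cut_points": cuts,
                },
            )
        )
    return children[0], children[1]


def thin_train(
    train: SpikeTrain, k: int, seed: int | np.random.Generator
) -> list[SpikeTrain]:
    """Randomly assign each spike to one of ``k`` child units.

    Models a population of units sharing a common rate modulation: the
    superposition of the children reproduces the parent exactly, while each
    child is an independently thinned copy carrying the same slow
    modulation.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    rng = np.random.default_rng(seed)
    owner = rng.integers(0, k, size=len(train))
    return [
        SpikeTrain(
            times=train.times[owner == j],
            unit_id=f"{train.unit_id}:thin{j}",
            tetrode_id=train.tetrode_id,
            meta={**train.meta, "thinned_from": train.unit_id, "k": k},
        )
        for j in range(k)
    ]
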