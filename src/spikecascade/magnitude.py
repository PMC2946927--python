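"""Local energy of ISI fluctuations and its log (magnitude) correlation.

The local energy at scale s is the squared standardized fluctuation,
e_k = (dY_k / sigma_s)^2.  The magnitude correlation C(l) is the lag-l
autocorrelation of ln e_k, normalized by its lag-0 value; it vanishes when
fluctuation amplitudes are uncorrelated and is approximately independent of
scale for multiplicative cascades, whose hierarchical construction rule is
the same at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import DegenerateSeriesError, ParameterError
from .fluctuation import FluctuationSet

#: Default non-dimensional lag grid (ISI counts), log-spaced.
DEFAULT_LAGS = tuple(
    int(v) for v in np.unique(np.rint(np.geomspace(1, 1024, 21)).astype(int))
)


@dataclass(frozen=True)
class MagnitudeCorrelation:
    """Normalized lag correlation of log local energy at one scale."""

    scale_s: int
    lags: np.ndarray
    corr: np.ndarray       # C(l)/C(0)
    n_pairs: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("lags", "corr", "n_pairs"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(np.diff(self.lags) <= 0):
            raise ParameterError("lags must be sorted and distinct")
        if np.any(np.abs(self.corr) > 1 + 1e-9):
            raise ParameterError("|corr| must not exceed 1")

    def null_band(self, z: float = 1.0) -> np.ndarray:
        """z / sqrt(n_pairs): the no-correlation noise band per lag."""
        return z / np.sqrt(np.maximum(self.n_pairs, 1))


def local_energy(fluct: FluctuationSet) -> tuple[np.ndarray, np.ndarray]:
    """(position, e) pairs with e_k the squared standardized fluctuation.

    Positions are global ISI indices, so lags computed from them are
    non-dimensional ISI counts and extend across window boundaries.  Exact
    zeros are floored at the machine-tiny value so the logarithm downstream
    is finite.
    """
    if len(fluct) == 0:
        raise ParameterError("empty fluctuation set")
    e = fluct.standardized ** 2
    n_zero = int(np.sum(e == 0.0))
    if n_zero:
        e = np.maximum(e, np.finfo(float).tiny)
    order = np.argsort(fluct.position, kind="stable")
    return fluct.position[order], e[order]


def magnitude_corr(
    energy: tuple[np.ndarray, np.ndarray] | FluctuationSet,
    lags: list[int] | None = None,
    scale_s: int | None = None,
) -> MagnitudeCorrelation:
    """Lag correlation of ln e over all position pairs at each lag.

    The estimator is the standard autocovariance of centered ln e divided by
    its lag-0 value (so C(0)/C(0) = 1), using the global mean and variance;
    this is invariant to rescaling the energies by any positive constant.
    """
    if isinstance(energy, FluctuationSet):
        if scale_s is None:
            scale_s = energy.scale_s
        pos, e = local_energy(energy)
    else:
        pos, e = energy
        pos = np.asarray(pos)
        e = np.asarray(e, dtype=float)
    if scale_s is None:
        raise ParameterError("scale_s required with raw energy input")
    if e.size < 100:
        raise ParameterError(f"need >= 100 energy values, got {e.size}")
    if lags is None:
        lags = [l for l in DEFAULT_LAGS if l < pos[-1] - pos[0]]
    lne = np.log(e)
    var = np.var(lne)
    if var == 0 or not np.isfinite(var):
        raise DegenerateSeriesError("zero variance of log energy")
    lnec = lne - lne.mean()
    # positions are contiguous global ISI indices when windows tile the
    # series; map position -> value for pairing across window boundaries
    pmin = int(pos[0])
    idx_of = {}
    dense = np.all(np.diff(pos) == 1)
    if not dense:
        idx_of = {int(p): i for i, p in enumerate(pos)}
    out_l, out_c, out_n = [], [], []
    for l in sorted(set(int(v) for v in lags)):
        if l < 0:
            raise ParameterError("lags must be non-negative")
        if dense:
            n = e.size - l
            if n < 2:
                continue
            c = float(np.mean(lnec[:-l or None] * lnec[l:])) / var
        else:
            i1, i2 = [], []
            for i, p in enumerate(pos):
                j = idx_of.get(int(p) + l)
                if j is not None:
                    i1.append(i)
                    i2.append(j)
            n = len(i1)
            if n < 2:
                continue
            c = float(np.mean(lnec[i1] * lnec[i2])) / var
        out_l.append(l)
        out_c.append(min(max(c, -1.0), 1.0) if abs(c) <= 1 + 1e-9 else c)
        out_n.append(n)
    return MagnitudeCorrelation(
        scale_s=int(scale_s),
        lags=np.asarray(out_l),
        corr=np.asarray(out_c),
        n_pairs=np.asarray(out_n),
    )


def scale_collapse(curves: list[MagnitudeCorrelation]) -> dict:
    """How well C(l)/C(0) curves at different scales collapse onto one.

    Curves are interpolated in log-lag onto the intersection of their
    supports, restricted to lags at or above the largest scale compared:
    below its own scale s, C(l) reflects the overlap of increments within a
    detrending window rather than the process, so the scaling regime starts
    at l ~ s.  The statistic is the maximum over lags of the range (max -
    min) across scales; small values indicate scale invariance of the
    magnitude correlation.
    """
    if len(curves) < 2:
        raise ParameterError("need >= 2 curves to assess collapse")
    lo = max(float(c.lags[c.lags > 0][0]) for c in curves)
    lo = max(lo, float(max(c.scale_s for c in curves)))
    hi = min(float(c.lags[-1]) for c in curves)
    if not lo < hi:
        raise ParameterError("curves have disjoint positive-lag supports")
    grid = np.geomspace(lo, hi, 25)
    table = np.empty((len(curves), grid.size))
    for i, c in enumerate(curves):
        mask = c.lags > 0
        table[i] = np.interp(
            np.log(grid), np.log(c.lags[mask].astype(float)), c.corr[mask]
        )
    ranges = table.max(axis=0) - table.min(axis=0)
    return {
        "statistic": float(ranges.max()),
        "lags": grid,
        "range": ranges,
        "curves": table,
        "scales": [c.scale_s for c in curves],
    }
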