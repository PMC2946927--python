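"""Profile construction and polynomially detrended multiscale fluctuations.

The ISI series x_i is cumulated into the profile Y(i) = sum_{j<=i} x_j, a
random-walk representation of the spike train.  At each scale s (measured in
number of ISIs, non-dimensional), the profile is divided into
half-overlapping windows of length 2s; a least-squares polynomial (cubic by
default) is fitted within each window and subtracted, and the lag-s
increments of the residual,

    dY(i) = y*(i + s) - y*(i),

taken over the first half of each window so that every index contributes
once, form the scale-s fluctuation sample.  Standardization divides by the
standard deviation sigma_s of the pooled increments at that scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import (
    DegenerateSeriesError,
    InsufficientDataError,
    ParameterError,
)
from .io import ISISeries

logger = logging.getLogger(__name__)

#: Default scale grid: log-spaced ISI counts.
DEFAULT_S_MIN = 4
DEFAULT_S_MAX = 582
DEFAULT_N_SCALES = 10

#: Minimum pooled increment count for downstream lambda^2 estimation.
MIN_FLUCT_VALUES = 50


@dataclass(frozen=True)
class Profile:
    """Cumulative ISI sum Y(i); strictly increasing by ISI positivity."""

    y: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if y.size == 0:
            raise InsufficientDataError("empty profile")
        if y.size > 1 and not np.all(np.diff(y) > 0):
            raise ParameterError("profile must be strictly increasing")

    def __len__(self) -> int:
        return int(self.y.size)


@dataclass(frozen=True)
class FluctuationSet:
    """Detrended lag-s increments at one scale.

    raw
        Increments dY in seconds.
    standardized
        raw / sigma_s (dimensionless, unit sample SD).
    sigma_s
        Pooled standard deviation of raw at this scale.
    segment_index
        Window id of each value (for block bootstrap).
    position
        Global ISI index at the start of each increment (for lag
        correlations across windows).
    """

    scale_s: int
    raw: np.ndarray
    standardized: np.ndarray
    sigma_s: float
    segment_index: np.ndarray
    position: np.ndarray

    def __len__(self) -> int:
        return int(self.raw.size)


def cumulate(series: ISISeries) -> Profile:
    """Profile Y(i) = sum_{j<=i} x_j of an ISI series."""
    if len(series) == 0:
        raise InsufficientDataError("cannot cumulate an empty ISI series")
    return Profile(y=np.cumsum(series.values))


def make_scales(
    s_min: int = DEFAULT_S_MIN,
    s_max: int = DEFAULT_S_MAX,
    k: int = DEFAULT_N_SCALES,
) -> list[int]:
    """k log-spaced integer scales from s_min to s_max, deduplicated.

    Endpoints are always included.
    """
    if not (2 <= s_min < s_max):
        raise ParameterError(f"need 2 <= s_min < s_max, got ({s_min}, {s_max})")
    if k < 2:
        raise ParameterError("need at least 2 scales")
    grid = np.unique(
        np.rint(np.geomspace(s_min, s_max, k)).astype(int)
    )
    scales = sorted(set(grid.tolist()) | {s_min, s_max})
    if len(scales) < 2:
        raise ParameterError("scale grid degenerated to fewer than 2 scales")
    return scales


def detrended_increments(
    profile: Profile, s: int, order: int = 3
) -> FluctuationSet:
    """Scale-s fluctuations of the profile after windowed detrending.

    Windows have length 2s with stride s (50% overlap); within each window a
    polynomial of the given order is fitted to the profile against the
    window-local index (scale lives in ISI counts, not clock time) and
    subtracted.  The lag-s increments of the residual over the first half of
    the window are pooled across windows; an incomplete tail window is
    dropped.
    """
    if s < 2:
        raise ParameterError("scale must be >= 2")
    if order < 1:
        raise ParameterError("detrending order must be >= 1")
    if 2 * s < order + 2:
        raise ParameterError(
            f"window of 2s={2 * s} points cannot leave residual degrees of "
            f"freedom after an order-{order} fit; lower the order"
        )
    n = len(profile)
    w = 2 * s
    if n < w + 1:
        raise InsufficientDataError(
            f"profile of length {n} too short for one window at scale {s}"
        )
    n_windows = (n - w) // s + 1
    x = np.arange(w, dtype=float)
    # Vandermonde shared across windows: one lstsq per scale, all windows at once
    V = np.vander(x, order + 1, increasing=True)
    starts = np.arange(n_windows) * s
    Y = profile.y[starts[:, None] + np.arange(w)]          # (n_windows, 2s)
    coef, *_ = np.linalg.lstsq(V, Y.T, rcond=None)
    resid = Y - (V @ coef).T
    raw = (resid[:, s:] - resid[:, :s]).ravel()            # dY over first half
    seg = np.repeat(np.arange(n_windows), s)
    pos = (starts[:, None] + np.arange(s)).ravel()
    sigma = float(np.std(raw))
    # a polynomial profile leaves only rounding noise: relative tolerance
    if sigma <= 1e-9 * float(np.max(np.abs(Y))) or not np.isfinite(sigma):
        raise DegenerateSeriesError(
            f"zero fluctuation variance at scale {s} (profile is a "
            f"polynomial of degree <= {order})"
        )
    return FluctuationSet(
        scale_s=int(s),
        raw=raw,
        standardized=(raw - 0.0) / sigma,
        sigma_s=sigma,
        segment_index=seg,
        position=pos,
    )


def fluctuation_field(
    series: ISISeries,
    scales: list[int] | None = None,
    order: int = 3,
) -> list[FluctuationSet]:
    """Detrended increments at every usable scale of a grid.

    Scales the series is too short for are skipped with a logged warning.
    """
    if scales is None:
        scales = make_scales()
    profile = cumulate(series)
    out = []
    for s in sorted(set(int(v) for v in scales)):
        try:
            fs = detrended_increments(profile, s, order=order)
        except InsufficientDataError:
            logger.warning(
                "scale_skipped reason=too_short scale=%d n=%d", s, len(profile)
            )
            continue
        if len(fs) < MIN_FLUCT_VALUES:
            logger.warning(
                "scale_skipped reason=too_few_values scale=%d n_values=%d",
                s, len(fs),
            )
            continue
        out.append(fs)
    if not out:
        raise InsufficientDataError(
            f"series of {len(series)} ISIs admits no usable scale"
        )
    return out
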