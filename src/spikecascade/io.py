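"""Spike-time and epoch I/O, ISI extraction, state splitting, superposition.

Spike times are seconds, double precision.  Two text formats are supported:
``plain`` (one timestamp per line, a single unit) and ``csv`` (header
``time,unit_id[,tetrode_id]``).  Epoch files are CSV with header
``start,end,state`` where state is ``awake`` or ``asleep``.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import (
    ConfigError,
    InsufficientDataError,
    ParameterError,
    ParseError,
)

VALID_STATES = ("awake", "asleep")

#: Downstream multiscale estimation is unreliable on short records; analyses
#: of real recordings conventionally require on the order of a thousand
#: firing events per state.
MIN_ANALYSIS_LENGTH = 1000


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike timestamps of one unit.

    Attributes
    ----------
    times : np.ndarray
        Strictly increasing, finite, non-negative timestamps in seconds.
    unit_id : str
        Opaque unit label.
    tetrode_id : str or None
        Opaque tetrode (electrode group) label.
    meta : dict
        Free-form provenance.
    """

    times: np.ndarray
    unit_id: str = "0"
    tetrode_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ParameterError("spike times must be a 1-D array")
        if t.size and not np.all(np.isfinite(t)):
            raise ParameterError("spike times must be finite")
        if t.size and t[0] < 0:
            raise ParameterError("spike times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ParameterError(
                f"spike times of unit {self.unit_id!r} must be strictly "
                "increasing (duplicates within a unit are rejected)"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0


@dataclass(frozen=True)
class EpochSet:
    """Non-overlapping behavioural-state intervals, sorted by start."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self):
        ivs = tuple(
            (float(a), float(b), str(s)) for a, b, s in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        prev_end = -np.inf
        for a, b, s in ivs:
            if not (a < b):
                raise ParameterError(f"epoch start {a} must precede end {b}")
            if s not in VALID_STATES:
                raise ParameterError(f"unknown state {s!r}")
            if a < prev_end:
                raise ParameterError("epochs must be sorted and non-overlapping")
            prev_end = b

    def select(self, state: str) -> list[tuple[float, float]]:
        if state not in VALID_STATES:
            raise ParameterError(f"unknown state {state!r}")
        return [(a, b) for a, b, s in self.intervals if s == state]

    @classmethod
    def from_csv(cls, source) -> "EpochSet":
        df = pd.read_csv(source)
        missing = {"start", "end", "state"} - set(df.columns)
        if missing:
            raise ConfigError(f"epoch CSV missing columns {sorted(missing)}")
        df = df.sort_values("start")
        return cls(tuple(zip(df["start"], df["end"], df["state"])))


@dataclass(frozen=True)
class ISISeries:
    """Ordered positive inter-spike intervals, with provenance."""

    values: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ParameterError("ISI values must be a 1-D array")
        if v.size and (not np.all(np.isfinite(v)) or np.any(v <= 0)):
            raise ParameterError("ISIs must be finite and strictly positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if len(self) else float("nan")


def _parse_plain(lines: Iterable[str]) -> np.ndarray:
    times = []
    for lineno, raw in enumerate(lines):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        for tok in line.split():
            try:
                t = float(tok)
            except ValueError:
                raise ParseError(f"cannot parse {tok!r} as a time", lineno)
            if not np.isfinite(t):
                raise ParseError(f"non-finite time {tok!r}", lineno)
            if t < 0:
                raise ParseError(f"negative time {t}", lineno)
            times.append(t)
    return np.asarray(times, dtype=float)


def read_spike_times(source, format: str = "plain") -> list[SpikeTrain]:
    """Read spike trains from a path or text stream.

    ``plain``: one float per line (whitespace-separated floats accepted),
    producing a single train.  ``csv``: columns ``time,unit_id`` and optional
    ``tetrode_id``; one train per distinct unit, each sorted by time.
    Duplicate timestamps within a unit are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r") as fh:
            return read_spike_times(fh, format=format)

    if format == "plain":
        times = _parse_plain(source)
        order = np.argsort(times, kind="stable")
        return [SpikeTrain(times=times[order])]
    if format == "csv":
        df = pd.read_csv(source)
        if "time" not in df.columns or "unit_id" not in df.columns:
            raise ConfigError("spike CSV requires columns time,unit_id")
        bad = ~np.isfinite(df["time"].to_numpy(dtype=float))
        if bad.any():
            # +1 for the header line: errors report 0-based file lines
            raise ParseError("non-finite time", int(np.flatnonzero(bad)[0]) + 1)
        if (df["time"] < 0).any():
            lineno = int(np.flatnonzero((df["time"] < 0).to_numpy())[0]) + 1
            raise ParseError("negative time", lineno)
        trains = []
        for unit_id, grp in df.groupby("unit_id", sort=True):
            grp = grp.sort_values("time", kind="stable")
            tet = None
            if "tetrode_id" in grp.columns:
                tets = grp["tetrode_id"].unique()
                tet = str(tets[0]) if len(tets) else None
            trains.append(
                SpikeTrain(
                    times=grp["time"].to_numpy(dtype=float),
                    unit_id=str(unit_id),
                    tetrode_id=tet,
                )
            )
        return trains
    raise ConfigError(f"unknown spike file format {format!r}")


def write_spike_times(trains: Sequence[SpikeTrain], sink, format: str | None = None) -> None:
    """Write trains so that a read round-trips to the printed precision.

    A single anonymous train is written ``plain``; otherwise CSV.  Pass
    ``format`` to force either.  Timestamps are printed with 12 significant
    digits.
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            write_spike_times(trains, fh, format=format)
        return
    if format is None:
        format = "plain" if len(trains) == 1 else "csv"
    if format == "plain":
        if len(trains) != 1:
            raise ConfigError("plain format holds exactly one train")
        for t in trains[0].times:
            sink.write(f"{t:.12g}\n")
    elif format == "csv":
        has_tet = any(tr.tetrode_id is not None for tr in trains)
        cols = "time,unit_id" + (",tetrode_id" if has_tet else "")
        sink.write(cols + "\n")
        for tr in trains:
            tet = f",{tr.tetrode_id}" if has_tet else ""
            for t in tr.times:
                sink.write(f"{t:.12g},{tr.unit_id}{tet}\n")
    else:
        raise ConfigError(f"unknown spike file format {format!r}")


def to_isi(train: SpikeTrain) -> ISISeries:
    """Differences of consecutive spike times; requires at least two spikes."""
    if len(train) < 2:
        raise InsufficientDataError(
            f"need >= 2 spikes to form ISIs, got {len(train)}"
        )
    return ISISeries(
        values=np.diff(train.times),
        source={"unit_id": train.unit_id, "tetrode_id": train.tetrode_id},
    )


def split_by_state(
    train: SpikeTrain,
    epochs: EpochSet,
    state: str,
    concatenate: bool = True,
) -> ISISeries | list[ISISeries]:
    """ISIs of a train restricted to the epochs of one behavioural state.

    ISIs are computed within each matching epoch independently; an interval
    spanning an epoch boundary is excluded rather than bridged, because state
    segments are non-contiguous in recording time.  With ``concatenate=False``
    a list with one series per contributing epoch is returned.
    """
    segs = []
    for a, b in epochs.select(state):
        inside = train.times[(train.times >= a) & (train.times <= b)]
        if inside.size >= 2:
            segs.append(np.diff(inside))
    src = {
        "unit_id": train.unit_id,
        "tetrode_id": train.tetrode_id,
        "state": state,
        "epoch_rule": "boundary-ISIs-excluded",
    }
    if not segs:
        warnings.warn(
            f"no epoch of state {state!r} contains >= 2 spikes of unit "
            f"{train.unit_id!r}; returning empty series"
        )
        empty = ISISeries(values=np.empty(0), source=src)
        return empty if concatenate else []
    if concatenate:
        return ISISeries(values=np.concatenate(segs), source=src)
    return [
        ISISeries(values=s, source={**src, "epoch_index": i})
        for i, s in enumerate(segs)
    ]


def superpose(trains: Sequence[SpikeTrain]) -> SpikeTrain:
    """Merge several units into a single-tetrode spike train.

    Exact timestamp ties across units are kept, ordered by unit label, and
    then perturbed by the smallest representable step so the merged train
    remains strictly increasing.
    """
    if not trains:
        raise ParameterError("superpose needs at least one train")
    if len(trains) == 1:
        return trains[0]
    labels = np.concatenate(
        [np.full(len(tr), str(tr.unit_id)) for tr in trains]
    )
    times = np.concatenate([tr.times for tr in trains])
    order = np.lexsort((labels, times))
    merged = times[order]
    # ties across units: nudge forward so 'strictly increasing' holds while
    # the spike count and the deterministic unit-label order are preserved
    for i in range(1, merged.size):
        if merged[i] <= merged[i - 1]:
            merged[i] = np.nextafter(merged[i - 1], np.inf)
    tets = {tr.tetrode_id for tr in trains if tr.tetrode_id is not None}
    tet = tets.pop() if len(tets) == 1 else None
    return SpikeTrain(
        times=merged,
        unit_id="+".join(str(tr.unit_id) for tr in trains),
        tetrode_id=tet,
        meta={"superposed_units": [str(tr.unit_id) for tr in trains]},
    )
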