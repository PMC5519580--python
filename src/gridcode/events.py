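"""Grid-event tables: reading, validation, writing and estimation/test partitioning.

A *grid event* is a modeled epoch (typically a period of translational
movement in a virtual environment) with a direction — the grid event angle
``alpha``, in degrees relative to a nominal 0° reference. The event table is
the unit of experimental design for hexadirectional analysis: every
downstream model (orientation-estimation GLM and magnitude GLM) is built
from a subset of these events, so the table also carries the
estimation/test partition labels.

File dialect: tab-separated values with a header row
``run onset duration angle_deg [set]``. Onsets are seconds from each run's
first acquired volume (0-based time); angles are degrees in ``[0, 360)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridEvent",
    "GridEventTable",
    "PartitionScheme",
    "read_event_table",
    "write_event_table",
    "partition_events",
    "SET_LABELS",
]

#: Valid values of the ``set`` column / ``set_label`` field.
SET_LABELS = ("estimation", "test", "excluded", "auto")

_COLUMNS = ["run", "onset", "duration", "angle_deg", "set"]


class EventTableError(ValueError):
    """Malformed or invalid grid-event table."""


@dataclass(frozen=True)
class GridEvent:
    """One timed, directed event.

    Parameters
    ----------
    run : int
        1-based index of the scanning run the event belongs to.
    onset : float
        Seconds from the run's first acquired volume (non-negative).
    duration : float
        Event duration in seconds (positive).
    angle : float
        Grid event angle in degrees, in ``[0, 360)``.
    set_label : str
        Partition membership: ``estimation``, ``test``, ``excluded`` or
        ``auto`` (not yet assigned).
    """

    run: int
    onset: float
    duration: float
    angle: float
    set_label: str = "auto"

    def __post_init__(self) -> None:
        if self.run < 1 or int(self.run) != self.run:
            raise EventTableError(f"run must be a positive integer, got {self.run!r}")
        if self.onset < 0:
            raise EventTableError(f"onset must be non-negative, got {self.onset!r}")
        if not self.duration > 0:
            raise EventTableError(f"duration must be positive, got {self.duration!r}")
        if not (0.0 <= self.angle < 360.0):
            raise EventTableError(
                f"angle must lie in [0, 360), got {self.angle!r}"
            )
        if self.set_label not in SET_LABELS:
            raise EventTableError(
                f"set_label must be one of {SET_LABELS}, got {self.set_label!r}"
            )


@dataclass
class GridEventTable:
    """Ordered collection of :class:`GridEvent` with run timing metadata.

    Events are kept sorted by ``(run, onset)``; two events in the same run
    must not overlap in time, and every event must finish before its run
    ends.
    """

    events: list[GridEvent]
    run_lengths: dict[int, float]
    tr: float
    #: Declared rotational sense of the angle convention (metadata only;
    #: no computation depends on it).
    angle_sense: str = "counterclockwise"

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise EventTableError(f"tr must be positive, got {self.tr!r}")
        self.run_lengths = {int(r): float(L) for r, L in self.run_lengths.items()}
        self.events = sorted(self.events, key=lambda e: (e.run, e.onset))
        self._validate()

    def _validate(self) -> None:
        for ev in self.events:
            if ev.run not in self.run_lengths:
                raise EventTableError(
                    f"event at onset {ev.onset} refers to run {ev.run}, "
                    f"but only runs {sorted(self.run_lengths)} were supplied"
                )
            if ev.onset + ev.duration > self.run_lengths[ev.run] + 1e-9:
                raise EventTableError(
                    f"event (run {ev.run}, onset {ev.onset}) extends past the "
                    f"run length of {self.run_lengths[ev.run]} s"
                )
        for prev, nxt in zip(self.events, self.events[1:]):
            if prev.run == nxt.run and nxt.onset < prev.onset + prev.duration - 1e-9:
                raise EventTableError(
                    f"overlapping events in run {prev.run}: onset {prev.onset} "
                    f"(duration {prev.duration}) overlaps onset {nxt.onset}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def runs(self) -> list[int]:
        return sorted(self.run_lengths)

    def __len__(self) -> int:
        return len(self.events)

    def subset(self, *, run: int | None = None, set_label: str | None = None) -> "GridEventTable":
        """Return a copy restricted to one run and/or one partition label."""
        evs = [
            e
            for e in self.events
            if (run is None or e.run == run)
            and (set_label is None or e.set_label == set_label)
        ]
        lengths = dict(self.run_lengths) if run is None else {run: self.run_lengths[run]}
        return GridEventTable(evs, lengths, self.tr, self.angle_sense)

    def angles(self) -> np.ndarray:
        return np.array([e.angle for e in self.events], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": [e.run for e in self.events],
                "onset": [e.onset for e in self.events],
                "duration": [e.duration for e in self.events],
                "angle_deg": [e.angle for e in self.events],
                "set": [e.set_label for e in self.events],
            }
        )

    def with_labels(self, labels: Sequence[str]) -> "GridEventTable":
        if len(labels) != len(self.events):
            raise EventTableError("label count does not match event count")
        evs = [replace(e, set_label=lab) for e, lab in zip(self.events, labels)]
        return GridEventTable(evs, dict(self.run_lengths), self.tr, self.angle_sense)


@dataclass(frozen=True)
class PartitionScheme:
    """How to split events into the estimation and the test set.

    ``kind`` is one of ``odd_even_runs`` (odd runs vs. even runs),
    ``temporal_bins`` (``n_bins`` equal time windows per run, alternating),
    ``odd_even_events`` (alternate events within each run), ``half_runs``
    (first vs. second half of each run by onset) or ``user_defined``
    (labels already present in the table).

    ``estimation_first`` selects which half/parity becomes the estimation
    set; flipping it exactly exchanges the two label sets.
    """

    kind: str
    n_bins: int = 2
    estimation_first: bool = True

    _KINDS = ("odd_even_runs", "temporal_bins", "odd_even_events", "half_runs", "user_defined")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise EventTableError(f"unknown partition kind {self.kind!r}; choose from {self._KINDS}")
        if self.kind == "temporal_bins":
            if self.n_bins < 2 or self.n_bins % 2 != 0:
                raise EventTableError(
                    f"temporal_bins requires an even n_bins >= 2, got {self.n_bins}"
                )


# -- I/O --------------------------------------------------------------------


def read_event_table(
    path, tr: float, run_lengths: dict[int, float] | Sequence[float]
) -> GridEventTable:
    """Read a grid-event TSV file and validate it.

    Parameters
    ----------
    path : str or path-like or file object
        TSV file with header columns ``run onset duration angle_deg`` and an
        optional ``set`` column. When the ``set`` column is absent every
        event gets ``set_label='auto'``.
    tr : float
        Repetition time in seconds.
    run_lengths : mapping or sequence
        Seconds per run; a plain sequence is interpreted as runs 1..n.
    """
    if not isinstance(run_lengths, dict):
        run_lengths = {i + 1: float(L) for i, L in enumerate(run_lengths)}
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise EventTableError(f"could not parse event table {path}: {exc}") from exc
    required = ["run", "onset", "duration", "angle_deg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EventTableError(f"event table is missing columns {missing}")
    if "set" not in df.columns:
        df["set"] = "auto"
    events = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            events.append(
                GridEvent(
                    run=int(row["run"]),
                    onset=float(row["onset"]),
                    duration=float(row["duration"]),
                    angle=float(row["angle_deg"]),
                    set_label=str(row["set"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise EventTableError(f"line {line}: {exc}") from exc
    return GridEventTable(events, run_lengths, tr)


def write_event_table(table: GridEventTable, path) -> None:
    """Write the table in the same TSV dialect :func:`read_event_table` reads."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False)


# -- partitioning ------------------------------------------------------------


def partition_events(table: GridEventTable, scheme: PartitionScheme) -> GridEventTable:
    """Assign every event to the estimation or the test set.

    The labeling is deterministic given the scheme. Events already labeled
    ``excluded`` keep that label under every scheme. If any event carries a
    non-``auto`` label and the scheme is not ``user_defined`` the call is
    refused as ambiguous.
    """
    preset = [e for e in table.events if e.set_label not in ("auto", "excluded")]
    if scheme.kind != "user_defined" and preset:
        raise EventTableError(
            f"{len(preset)} events already carry estimation/test labels; use "
            "kind='user_defined' to keep them or reset labels to 'auto'"
        )
    if scheme.kind == "user_defined":
        bad = [e for e in table.events if e.set_label == "auto"]
        if bad:
            raise EventTableError(
                f"user_defined partitioning requires explicit labels, but "
                f"{len(bad)} events are still 'auto'"
            )
        return table.with_labels([e.set_label for e in table.events])

    est, test = ("estimation", "test") if scheme.estimation_first else ("test", "estimation")
    labels: list[str] = []

    if scheme.kind == "odd_even_runs":
        for e in table.events:
            labels.append(est if e.run % 2 == 1 else test)
    elif scheme.kind == "odd_even_events":
        counters: dict[int, int] = {}
        for e in table.events:
            counters[e.run] = counters.get(e.run, 0) + 1
            labels.append(est if counters[e.run] % 2 == 1 else test)
    elif scheme.kind == "half_runs":
        for e in table.events:
            mid = table.run_lengths[e.run] / 2.0
            labels.append(est if e.onset < mid else test)
    elif scheme.kind == "temporal_bins":
        for run in table.runs:
            n_run = sum(1 for e in table.events if e.run == run)
            if 0 < n_run < scheme.n_bins:
                raise EventTableError(
                    f"run {run} has {n_run} events, fewer than n_bins={scheme.n_bins}"
                )
        for e in table.events:
            width = table.run_lengths[e.run] / scheme.n_bins
            b = min(int(e.onset // width), scheme.n_bins - 1)
            labels.append(est if b % 2 == 0 else test)
    else:  # pragma: no cover - guarded by PartitionScheme
        raise EventTableError(f"unhandled scheme {scheme.kind}")

    # excluded events stay excluded regardless of scheme
    labels = [
        "excluded" if e.set_label == "excluded" else lab
        for e, lab in zip(table.events, labels)
    ]
    return table.with_labels(labels)
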