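"""RFID event logs and their reduction to discretized location series.

The raw Eco-HAB record is a stream of antenna crossings: ``(time, antenna,
mouse)``.  Each mouse's position is reconstructed on a regular 2-s grid by
interpolating between consecutive crossings: while a mouse is inside a
tunnel its location is taken to be the compartment it is about to enter,
and two reads of the same antenna closer than the grid resolution are
treated as a single visit (the mouse sniffed the tunnel entrance and
returned, a known artifact of the hardware).

Event logs are plain TSV with columns ``time_s`` (float seconds since the
start of the experiment), ``antenna`` (string id) and ``mouse`` (string id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .topology import HabitatTopology, TopologyError

__all__ = [
    "LocationMatrix",
    "ActivityProfile",
    "read_events",
    "write_events",
    "build_location_series",
    "select_window",
    "activity_profile",
    "find_inactive_mice",
    "parse_clock",
]

SECONDS_PER_DAY = 86400.0

#: wall-clock seconds-after-midnight used as the day boundary (light-phase
#: onset for the standard 13:00-01:00 dark phase).
DEFAULT_DAY_START_S = 3600.0

EVENT_COLUMNS = ("time_s", "antenna", "mouse")


def parse_clock(clock: str | float) -> float:
    """Convert ``"HH:MM"`` (or ``"HH:MM:SS"``) to seconds after midnight."""
    if isinstance(clock, (int, float)):
        return float(clock)
    parts = [int(p) for p in clock.split(":")]
    while len(parts) < 3:
        parts.append(0)
    h, m, s = parts
    return h * 3600.0 + m * 60.0 + s


@dataclass
class LocationMatrix:
    """Per-mouse compartment labels on a regular time grid.

    Attributes
    ----------
    sigma : (N, T) int8 array
        Compartment label in ``{1..q}``; undefined (0) where ``valid`` is
        False.
    valid : (N, T) bool array
        False before a mouse's first antenna event (location unknowable).
    time_s : (T,) float array
        Bin start times, seconds since experiment start.  Uniform step
        ``resolution`` within a day; windowed matrices jump across days.
    mouse_ids : list of str
    t0_clock_s : float
        Wall-clock seconds-after-midnight at experiment time 0.
    resolution : float
        Bin width in seconds (2.0 for the standard analysis).
    q : int
        Number of compartments.
    """

    sigma: np.ndarray
    valid: np.ndarray
    time_s: np.ndarray
    mouse_ids: list[str]
    t0_clock_s: float = parse_clock("13:00")
    resolution: float = 2.0
    q: int = 4
    day_start_clock_s: float = DEFAULT_DAY_START_S

    @property
    def n_mice(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_bins(self) -> int:
        return self.sigma.shape[1]

    @property
    def clock(self) -> np.ndarray:
        """Wall-clock seconds-after-midnight for each bin."""
        return (self.time_s + self.t0_clock_s) % SECONDS_PER_DAY

    @property
    def day_index(self) -> np.ndarray:
        """Day number of each bin, counted from the first recorded day.

        Day boundaries fall at the light-phase onset so an analysis window
        inside the dark phase never straddles two days.
        """
        absolute = self.time_s + self.t0_clock_s - self.day_start_clock_s
        days = np.floor(absolute / SECONDS_PER_DAY).astype(np.int64)
        return days - days.min() if days.size else days

    def restrict_bins(self, keep: np.ndarray) -> "LocationMatrix":
        return replace(
            self,
            sigma=self.sigma[:, keep],
            valid=self.valid[:, keep],
            time_s=self.time_s[keep],
        )

    def restrict_mice(self, keep) -> "LocationMatrix":
        """Keep a subset of mice, given ids or an index/boolean array."""
        if len(keep) and isinstance(next(iter(keep)), str):
            idx = np.array([self.mouse_ids.index(m) for m in keep])
        else:
            idx = np.asarray(keep)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
        return replace(
            self,
            sigma=self.sigma[idx],
            valid=self.valid[idx],
            mouse_ids=[self.mouse_ids[i] for i in idx],
        )

    def mask_mice(self, mouse_ids) -> "LocationMatrix":
        """Return a copy with the given mice marked fully invalid."""
        valid = self.valid.copy()
        for m in mouse_ids:
            valid[self.mouse_ids.index(m)] = False
        return replace(self, valid=valid)

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            sigma=self.sigma,
            valid=self.valid,
            time_s=self.time_s,
            mouse_ids=np.array(self.mouse_ids),
            meta=np.array(
                [self.t0_clock_s, self.resolution, float(self.q), self.day_start_clock_s]
            ),
        )

    @classmethod
    def from_npz(cls, path) -> "LocationMatrix":
        d = np.load(path, allow_pickle=False)
        t0, res, q, day0 = d["meta"]
        return cls(
            sigma=d["sigma"],
            valid=d["valid"],
            time_s=d["time_s"],
            mouse_ids=[str(m) for m in d["mouse_ids"]],
            t0_clock_s=float(t0),
            resolution=float(res),
            q=int(q),
            day_start_clock_s=float(day0),
        )


@dataclass
class ActivityProfile:
    """Antenna-crossing counts per mouse, day and analysis window."""

    phi: np.ndarray  # (N, D) counts
    mouse_ids: list[str]

    @property
    def mouse_mean(self) -> np.ndarray:
        """Mean daily activity per mouse (phi tilde)."""
        return self.phi.mean(axis=1)

    @property
    def day_mean(self) -> np.ndarray:
        """Mean activity over mice for each day (phi bar)."""
        return self.phi.mean(axis=0)

    @property
    def mouse_sd(self) -> float:
        """Mouse-to-mouse variability of mean activity."""
        return float(self.mouse_mean.std(ddof=1))

    @property
    def day_sd(self) -> float:
        """Day-to-day variability of the cohort-mean activity."""
        return float(self.day_mean.std(ddof=1))


class EventFormatError(ValueError):
    """Raised when an event log lacks the required columns."""


def read_events(path, topology: HabitatTopology, *, sep: str = "\t",
                columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Parse a delimited event log into a time-sorted event table.

    ``columns`` maps the canonical names ``time_s``/``antenna``/``mouse``
    to the names used in the file, for logs in other dialects.
    """
    df = pd.read_csv(path, sep=sep, dtype={"antenna": str, "mouse": str})
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventFormatError(f"event log missing columns {missing}")
    df = df[list(EVENT_COLUMNS)].copy()
    df["antenna"] = df["antenna"].astype(str)
    df["mouse"] = df["mouse"].astype(str)
    unknown = set(df["antenna"]) - set(topology.antennas)
    if unknown:
        raise TopologyError(f"antennas not in topology: {sorted(unknown)}")
    # stable sort: simultaneous reads keep file order (tie order is not
    # specified by the hardware; we do not guess)
    return df.sort_values("time_s", kind="stable", ignore_index=True)


def write_events(events: pd.DataFrame, path, *, sep: str = "\t") -> None:
    events[list(EVENT_COLUMNS)].to_csv(path, sep=sep, index=False)


def collapse_antenna_artifacts(times: np.ndarray, antennas: np.ndarray,
                               min_sep: float = 2.0):
    """Drop repeat reads of the same antenna closer than ``min_sep`` seconds.

    Applied per mouse.  Crossings recorded at the two paired antennas of a
    tunnel are always kept, however close: only same-antenna repeats are
    sniff-and-return artifacts.
    """
    keep = np.ones(len(times), dtype=bool)
    last_t = None
    last_a = None
    for k in range(len(times)):
        if last_t is not None and antennas[k] == last_a and times[k] - last_t < min_sep:
            keep[k] = False
            continue
        last_t, last_a = times[k], antennas[k]
    return times[keep], antennas[keep]


def _segment_labels(antennas: np.ndarray, topology: HabitatTopology) -> np.ndarray:
    """Compartment occupied from each event until the next one.

    Between the two antennas of one tunnel the mouse is in the tunnel and
    is assigned the compartment it will enter; otherwise the compartment is
    the one shared by the two antenna ends (deduced from the next event on
    a mismatch, which only occurs with missed reads).
    """
    n = len(antennas)
    labels = np.empty(n, dtype=np.int8)
    for k in range(n):
        a1 = antennas[k]
        if k == n - 1:
            labels[k] = topology.antenna_compartment(a1)
            continue
        a2 = antennas[k + 1]
        tun1 = topology.antenna_tunnel(a1)
        tun2 = topology.antenna_tunnel(a2)
        if tun1 == tun2 and a1 != a2:
            # full tunnel traversal: location is the destination compartment
            labels[k] = topology.antenna_compartment(a2)
        elif topology.antenna_compartment(a1) == topology.antenna_compartment(a2):
            labels[k] = topology.antenna_compartment(a1)
        else:
            labels[k] = topology.antenna_compartment(a2)
    return labels


def build_location_series(events: pd.DataFrame, topology: HabitatTopology,
                          resolution: float = 2.0, *,
                          t_start: float = 0.0, t_end: float | None = None,
                          t0_clock_s: float | str = "13:00",
                          mouse_ids: list[str] | None = None) -> LocationMatrix:
    """Discretize antenna events into a :class:`LocationMatrix`.

    Each bin samples the reconstructed location at its start time.  Bins
    before a mouse's first (artifact-collapsed) event are masked invalid.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if mouse_ids is None:
        mouse_ids = sorted(events["mouse"].unique())
    if t_end is None:
        t_end = float(events["time_s"].max()) + resolution
    n_bins = int(np.ceil((t_end - t_start) / resolution))
    time_s = t_start + resolution * np.arange(n_bins)
    q = topology.n_compartments

    sigma = np.zeros((len(mouse_ids), n_bins), dtype=np.int8)
    valid = np.zeros((len(mouse_ids), n_bins), dtype=bool)
    grouped = dict(iter(events.groupby("mouse", sort=False)))
    for i, mouse in enumerate(mouse_ids):
        g = grouped.get(mouse)
        if g is None or not len(g):
            warnings.warn(f"mouse {mouse!r} has no antenna events; fully masked")
            continue
        times, ants = collapse_antenna_artifacts(
            g["time_s"].to_numpy(float), g["antenna"].to_numpy(), min_sep=resolution
        )
        labels = _segment_labels(ants, topology)
        seg = np.searchsorted(times, time_s, side="right") - 1
        ok = seg >= 0
        sigma[i, ok] = labels[seg[ok]]
        valid[i] = ok
    return LocationMatrix(
        sigma=sigma, valid=valid, time_s=time_s, mouse_ids=list(mouse_ids),
        t0_clock_s=parse_clock(t0_clock_s), resolution=resolution, q=q,
    )


def select_window(loc: LocationMatrix, start: str | float = "13:00",
                  end: str | float = "19:00") -> LocationMatrix:
    """Restrict to a daily wall-clock window (default the active 6 hours)."""
    s, e = parse_clock(start), parse_clock(end)
    if e <= s:
        raise ValueError(f"empty or inverted window {start!r}-{end!r}")
    clock = loc.clock
    keep = (clock >= s) & (clock < e)
    if not keep.any():
        raise ValueError("window selects no bins")
    return loc.restrict_bins(keep)


def activity_profile(events: pd.DataFrame, windows, *,
                     mouse_ids: list[str] | None = None,
                     resolution: float = 2.0) -> ActivityProfile:
    """Antenna-crossing counts per mouse and per daily window.

    ``windows`` is a sequence of ``(t_start, t_end)`` intervals in seconds
    since experiment start, one per day.  Counts are taken after collapsing
    same-antenna sniff artifacts, so they measure genuine passes.
    """
    if mouse_ids is None:
        mouse_ids = sorted(events["mouse"].unique())
    phi = np.zeros((len(mouse_ids), len(windows)), dtype=np.int64)
    grouped = dict(iter(events.groupby("mouse", sort=False)))
    for i, mouse in enumerate(mouse_ids):
        g = grouped.get(mouse)
        if g is None or not len(g):
            continue
        times, _ = collapse_antenna_artifacts(
            g["time_s"].to_numpy(float), g["antenna"].to_numpy(), min_sep=resolution
        )
        for d, (t0, t1) in enumerate(windows):
            phi[i, d] = int(np.count_nonzero((times >= t0) & (times < t1)))
    return ActivityProfile(phi=phi, mouse_ids=list(mouse_ids))


def find_inactive_mice(loc: LocationMatrix) -> set[str]:
    """Mice failing to visit all compartments on at least one day.

    A mouse whose daily trajectory does not cover the full habitat is
    considered inactive for the whole recording; the caller masks it.  For
    paired before/after designs, mask the union of the two phases' inactive
    sets in both phases.
    """
    days = loc.day_index
    flagged: set[str] = set()
    all_comp = set(range(1, loc.q + 1))
    for d in np.unique(days):
        in_day = days == d
        for i, mouse in enumerate(loc.mouse_ids):
            ok = loc.valid[i] & in_day
            if set(np.unique(loc.sigma[i, ok])) != all_comp:
                flagged.add(mouse)
    return flagged
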