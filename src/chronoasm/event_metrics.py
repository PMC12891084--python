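"""Epileptiform-discharge (ED) event detection, hourly rates, and efficacy.

An ED event is a network-level excursion of the fast variable into the
large-amplitude oscillatory branch.  Detection uses hysteresis on the
node-max ``|z|^2``: an event opens when any node exceeds the upper threshold
and closes when every node has fallen below the lower one, which suppresses
chatter from noise riding on a discharge.  Events are attributed to their
onset time throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "EventList",
    "Histogram24",
    "EfficacyResult",
    "detect_events",
    "hourly_histogram",
    "mean_hourly_rate",
    "efficacy",
]

SECONDS_PER_DAY = 86400.0
SECONDS_PER_HOUR = 3600.0


@dataclass
class EventList:
    """Detected events as parallel onset/offset arrays (seconds)."""

    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.onsets.shape != self.offsets.shape:
            raise ValueError("onsets and offsets must have equal length")
        if len(self.onsets) > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.offsets <= self.onsets):
            raise ValueError("every offset must exceed its onset")
        if len(self.onsets) > 1 and np.any(self.onsets[1:] < self.offsets[:-1]):
            raise ValueError("events must not overlap")

    def __len__(self) -> int:
        return len(self.onsets)

    def in_window(self, start: float, end: float) -> "EventList":
        m = (self.onsets >= start) & (self.onsets < end)
        return EventList(self.onsets[m], self.offsets[m])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"onset_s": self.onsets, "offset_s": self.offsets})


@dataclass
class Histogram24:
    """Events per clock-hour bin, averaged over the days of the window."""

    counts: np.ndarray  # 24 non-negative rates
    n_days: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (24,):
            raise ValueError("counts must have length 24")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")

    @property
    def bin_centers_h(self) -> np.ndarray:
        return np.arange(24) + 0.5

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"hour": np.arange(24), "rate": self.counts})


@dataclass
class EfficacyResult:
    """Percentage reduction in mean hourly ED rate for one dosing condition."""

    drug: str
    mode: str  # "QD" or "BID"
    phase_h: float
    f: float
    reduction_pct: float

    def __post_init__(self) -> None:
        if self.reduction_pct > 100.0:
            raise ValueError("reduction cannot exceed 100%")


def detect_events(
    amp2: np.ndarray,
    dt: float,
    upper: float = 1.0,
    lower: float = 0.5,
    t0: float = 0.0,
) -> EventList:
    """Hysteresis detection of network-level events on an amplitude stream.

    ``amp2`` is ``|z|^2`` with shape (n_samples,) or (n_samples, n_nodes); the
    node-max stream is thresholded.  Uses sample spacing ``dt`` (so it should
    be fed the full-resolution stream — decimation alters event boundaries).
    An event still open at the end of the stream is closed at the final time.
    """
    if not (upper > lower > 0):
        raise ValueError("thresholds must satisfy upper > lower > 0")
    if dt <= 0:
        raise ValueError("dt must be positive (monotone time axis)")
    amp2 = np.asarray(amp2, dtype=float)
    amax = amp2 if amp2.ndim == 1 else amp2.max(axis=1)

    # collapse to a {-1, 0, +1} crossing signal, then scan its sign changes
    sig = np.zeros(len(amax), dtype=np.int8)
    sig[amax > upper] = 1
    sig[amax < lower] = -1
    nz = np.flatnonzero(sig)
    onsets, offsets = [], []
    state = -1  # start in background
    for i in nz:
        v = sig[i]
        if v == 1 and state == -1:
            onsets.append(t0 + i * dt)
            state = 1
        elif v == -1 and state == 1:
            offsets.append(t0 + i * dt)
            state = -1
    if state == 1:
        offsets.append(t0 + len(amax) * dt)
    return EventList(np.array(onsets), np.array(offsets))


def hourly_histogram(events: EventList, start: float, end: float) -> Histogram24:
    """Day-averaged clock-hour histogram of event onsets in [start, end).

    The window must be a whole, positive number of days so every clock hour is
    covered equally.
    """
    span = end - start
    if span < SECONDS_PER_DAY:
        raise ValueError("window must cover at least 24 h")
    n_days = span / SECONDS_PER_DAY
    if abs(n_days - round(n_days)) > 1e-9:
        raise ValueError("window must be a whole number of days")
    n_days = round(n_days)
    sel = events.in_window(start, end)
    hours = (sel.onsets // SECONDS_PER_HOUR).astype(int) % 24
    counts = np.bincount(hours, minlength=24).astype(float)
    return Histogram24(counts=counts / n_days, n_days=n_days)


def mean_hourly_rate(events: EventList, window: Tuple[float, float]) -> float:
    """Event onsets per hour over the window (start, end) in seconds."""
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    n = len(events.in_window(start, end))
    return n / ((end - start) / SECONDS_PER_HOUR)


def efficacy(medicated_rate: float, baseline_rate: float) -> float:
    """Percentage reduction of the medicated rate relative to baseline.

    Negative values represent worsening; values are capped above by 100%.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive (efficacy undefined)")
    return 100.0 * (1.0 - medicated_rate / baseline_rate)
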