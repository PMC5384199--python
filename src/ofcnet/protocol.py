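"""Session timeline of the observational fear conditioning (OFC) assay.

The assay has two phases recorded back to back: a 5-min habituation in which
observer and demonstrator sit in adjacent chambers, followed by a 4-min
conditioning phase in which a 2-s foot shock is delivered to the demonstrator
every 12 s.  LFP analysis windows are carved out of this timeline:

* conditioning — one window per shock cycle, starting after the shock plus a
  1-s guard and ending one guard before the next shock.  With the default
  parameters this yields twenty 8-s windows.
* habituation — 10-s tiles covering the phase.

All times are seconds from recording start; intervals are half-open
``[start, end)``.  Discretization to sample indices uses ``floor(t * fs)``
for both edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SessionProtocol",
    "EpochSet",
    "conditioning_epochs",
    "habituation_epochs",
    "quarter_partition",
]


@dataclass(frozen=True)
class SessionProtocol:
    """Timing of the OFC session and the epoching parameters.

    Parameters
    ----------
    habituation_duration : float
        Length of the habituation phase in seconds (default 300 = 5 min).
    conditioning_duration : float
        Length of the conditioning phase in seconds (default 240 = 4 min).
    shock_period : float
        Interval between successive shock onsets, seconds (default 12).
    shock_duration : float
        Duration of each foot shock, seconds (default 2).
    guard : float
        Margin excluded at each end of the inter-shock window to avoid
        shock-artifact contamination, seconds (default 1).
    hab_window : float
        Length of each habituation analysis window, seconds (default 10).
    first_shock_at : float
        Latency of the first shock onset from conditioning start (default 0).
    """

    habituation_duration: float = 300.0
    conditioning_duration: float = 240.0
    shock_period: float = 12.0
    shock_duration: float = 2.0
    guard: float = 1.0
    hab_window: float = 10.0
    first_shock_at: float = 0.0

    def __post_init__(self) -> None:
        if self.habituation_duration <= 0 or self.conditioning_duration <= 0:
            raise ValueError("phase durations must be positive")
        if self.shock_period <= self.shock_duration + 2 * self.guard:
            raise ValueError(
                "shock_period must exceed shock_duration + 2*guard; "
                f"got period={self.shock_period}, shock={self.shock_duration}, "
                f"guard={self.guard} (analysis window would be empty)"
            )
        n = self.conditioning_duration / self.shock_period
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "conditioning_duration must be a positive multiple of shock_period"
            )

    @property
    def cond_window(self) -> float:
        """Guard-trimmed analysis window per shock cycle, seconds."""
        return self.shock_period - self.shock_duration - 2 * self.guard

    @property
    def n_cycles(self) -> int:
        return int(round(self.conditioning_duration / self.shock_period))

    @property
    def conditioning_start(self) -> float:
        """Recording time at which the conditioning phase begins."""
        return self.habituation_duration

    @property
    def total_duration(self) -> float:
        return self.habituation_duration + self.conditioning_duration

    def shock_intervals(self) -> list[tuple[float, float]]:
        """Absolute ``[onset, onset + duration)`` of every shock."""
        t0 = self.conditioning_start + self.first_shock_at
        return [
            (t0 + k * self.shock_period, t0 + k * self.shock_period + self.shock_duration)
            for k in range(self.n_cycles)
        ]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SessionProtocol":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class EpochSet:
    """A labeled list of equal-length, sorted, non-overlapping intervals.

    Intervals are in seconds relative to recording start, half-open.
    """

    phase: str
    intervals: tuple[tuple[float, float], ...]
    window: float

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end in self.intervals:
            if not (end > start):
                raise ValueError(f"empty interval [{start}, {end})")
            if abs((end - start) - self.window) > 1e-9:
                raise ValueError("all intervals must have the common window length")
            if start < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.intervals)

    def sample_slices(self, fs: float) -> list[slice]:
        """Discretize to sample-index slices: floor(t*fs) at both edges."""
        return [
            slice(int(math.floor(s * fs)), int(math.floor(e * fs)))
            for s, e in self.intervals
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(self.phase, s, e) for s, e in self.intervals],
            columns=["phase", "start", "end"],
        )


def conditioning_epochs(p: SessionProtocol) -> EpochSet:
    """Guard-trimmed analysis windows, one per shock cycle.

    Cycle *k* contributes ``[k*period + shock + guard, (k+1)*period - guard)``
    relative to conditioning start.  Defaults give twenty 8-s windows.
    """
    if p.cond_window <= 0:
        raise ValueError("guard-trimmed window length is not positive")
    t0 = p.conditioning_start + p.first_shock_at
    intervals = tuple(
        (
            t0 + k * p.shock_period + p.shock_duration + p.guard,
            t0 + (k + 1) * p.shock_period - p.guard,
        )
        for k in range(p.n_cycles)
    )
    return EpochSet(phase="conditioning", intervals=intervals, window=p.cond_window)


def habituation_epochs(p: SessionProtocol, n_windows: int | None = None) -> EpochSet:
    """Non-overlapping ``hab_window``-length tiles over the habituation phase.

    By default the whole phase is tiled (floor(duration/window) full tiles,
    remainder dropped); ``n_windows`` restricts to the first *n* tiles.
    """
    if p.hab_window > p.habituation_duration:
        raise ValueError("hab_window exceeds habituation duration")
    n_full = int(math.floor(p.habituation_duration / p.hab_window + 1e-9))
    if n_windows is not None:
        if n_windows < 1 or n_windows > n_full:
            raise ValueError(f"n_windows must be in [1, {n_full}]")
        n_full = n_windows
    intervals = tuple(
        (k * p.hab_window, (k + 1) * p.hab_window) for k in range(n_full)
    )
    return EpochSet(phase="habituation", intervals=intervals, window=p.hab_window)


def quarter_partition(p: SessionProtocol, epochs: EpochSet) -> list[EpochSet]:
    """Split conditioning epochs into four quarters by shock-cycle index.

    Quarters align to cycle boundaries; with 20 epochs each quarter holds 5.
    If the epoch count is not divisible by 4 the last quarter carries the
    remainder and a warning is logged.
    """
    if epochs.phase != "conditioning":
        raise ValueError("quarter partition applies to conditioning epochs")
    n = len(epochs)
    if n < 4:
        raise ValueError("need at least 4 epochs to form quarters")
    per = n // 4
    if n % 4 != 0:
        logger.warning(
            "epoch count %d not divisible by 4; last quarter carries %d epochs",
            n,
            per + n % 4,
        )
    out = []
    for q in range(4):
        lo = q * per
        hi = (q + 1) * per if q < 3 else n
        out.append(
            EpochSet(
                phase=f"{epochs.phase}_q{q + 1}",
                intervals=epochs.intervals[lo:hi],
                window=epochs.window,
            )
        )
    return out


def epochs_clear_of_shocks(p: SessionProtocol, epochs: EpochSet) -> bool:
    """True iff no epoch intersects any shock interval padded by the guard."""
    shocks = p.shock_intervals()
    for s, e in epochs:
        for a, b in shocks:
            if s < b + p.guard and a - p.guard < e:
                return False
    return True
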