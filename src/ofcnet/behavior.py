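"""Freezing and locomotion scoring.

Freezing is the absence of movement (other than respiration/sniffing)
lasting *longer than* 1 s — the 1-s boundary is read strictly, so an
immobility run of exactly 1.0 s does not count as a bout.  Per-animal
freezing totals can be screened for outliers with the >2-SD rule, and
open-field locomotion is summarized as distance travelled per 5-min bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MovementTrace",
    "FreezingSummary",
    "score_freezing",
    "exclude_outliers",
    "bin_locomotion",
]


@dataclass(frozen=True)
class MovementTrace:
    """Uniformly sampled immobility trace.

    ``immobile`` is boolean per sample; a continuous activity score can be
    binarized with :meth:`from_activity` (threshold is a user choice, not
    inferred).  Timestamps are ``i / fs`` seconds from trace start.
    """

    immobile: np.ndarray
    fs: float
    phase: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.immobile, dtype=bool)
        if arr.ndim != 1:
            raise ValueError("trace must be 1-D")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "immobile", arr)

    @property
    def duration(self) -> float:
        return self.immobile.size / self.fs

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.immobile.size) / self.fs

    @classmethod
    def from_activity(cls, activity: np.ndarray, fs: float, threshold: float,
                      phase: str = "") -> "MovementTrace":
        """Binarize a continuous activity score: immobile iff activity < threshold."""
        return cls(immobile=np.asarray(activity, dtype=float) < threshold, fs=fs, phase=phase)

    @classmethod
    def from_csv(cls, path, fs: float | None = None, threshold: float | None = None,
                 phase: str = "") -> "MovementTrace":
        """Read a (time, value) CSV; value is immobility flag or activity score."""
        frame = pd.read_csv(path)
        t = frame.iloc[:, 0].to_numpy(dtype=float)
        v = frame.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
            raise ValueError("trace timestamps must be strictly increasing and uniform")
        fs = fs or 1.0 / dt.mean()
        if threshold is not None:
            return cls.from_activity(v, fs, threshold, phase)
        return cls(immobile=v > 0.5, fs=fs, phase=phase)


@dataclass(frozen=True)
class FreezingSummary:
    """Scored bouts, per-bin percentages and totals for one trace."""

    bouts: tuple[tuple[float, float], ...]  # (start s, duration s)
    total: float
    bin_s: float
    bin_percent: tuple[float, ...]
    excluded: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bouts, columns=["start", "duration"])


def _immobility_runs(trace: MovementTrace) -> list[tuple[int, int]]:
    """(start_index, run_length) of maximal immobile runs."""
    flags = trace.immobile.astype(np.int8)
    if flags.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], flags, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts, ends - starts))


def score_freezing(trace: MovementTrace, min_bout: float = 1.0, bin_s: float = 60.0) -> FreezingSummary:
    """Detect freezing bouts: maximal immobility runs strictly longer than ``min_bout``.

    Bout duration is ``run_length / fs``; totals are the sum of bout
    durations and per-bin values are the percentage of each ``bin_s`` bin
    spent in a scored bout.
    """
    runs = _immobility_runs(trace)
    bouts = []
    for start_idx, length in runs:
        dur = length / trace.fs
        if dur > min_bout:
            bouts.append((start_idx / trace.fs, dur))
    total = float(sum(d for _, d in bouts))

    n_bins = int(np.ceil(trace.duration / bin_s - 1e-9)) if trace.duration > 0 else 0
    per_bin = np.zeros(max(n_bins, 0))
    for start, dur in bouts:
        end = start + dur
        for b in range(n_bins):
            lo, hi = b * bin_s, min((b + 1) * bin_s, trace.duration)
            overlap = max(0.0, min(end, hi) - max(start, lo))
            per_bin[b] += overlap
    widths = np.array([min((b + 1) * bin_s, trace.duration) - b * bin_s for b in range(n_bins)])
    with np.errstate(invalid="ignore"):
        pct = np.where(widths > 0, 100.0 * per_bin / widths, 0.0)
    return FreezingSummary(
        bouts=tuple(bouts), total=total, bin_s=bin_s, bin_percent=tuple(pct.tolist())
    )


def exclude_outliers(values: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Inclusion mask under the >k-SD rule.

    A value is excluded iff ``|x - mean| > k * SD`` where mean and sample SD
    (ddof=1) are computed once over all values, candidate included — a
    single pass, no iteration.  Zero variance excludes nothing.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to screen for outliers")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.ones(v.size, dtype=bool)
    return np.abs(v - v.mean()) <= k * sd


def bin_locomotion(x: np.ndarray, y: np.ndarray, t: np.ndarray, bin_s: float = 300.0) -> np.ndarray:
    """Distance travelled per time bin from an (x, y, t) track.

    Each step's Euclidean length is assigned to the bin containing the step's
    start time.  A default 300-s bin over a 30-min open-field session yields
    6 values.  A single-point track travels zero distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (x.shape == y.shape == t.shape) or x.ndim != 1:
        raise ValueError("x, y, t must be equal-length 1-D arrays")
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be monotone non-decreasing")
    if t.size == 0:
        return np.zeros(0)
    n_bins = max(int(np.ceil((t[-1] - t[0]) / bin_s - 1e-9)), 1)
    out = np.zeros(n_bins)
    if t.size < 2:
        return out
    steps = np.hypot(np.diff(x), np.diff(y))
    bins = np.minimum(((t[:-1] - t[0]) / bin_s).astype(int), n_bins - 1)
    np.add.at(out, bins, steps)
    return out
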