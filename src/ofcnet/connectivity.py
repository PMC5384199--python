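"""Region×region theta cross-correlation matrices and their dynamics.

For each analysis epoch the theta-filtered signals of every unordered channel
pair are correlated; per-epoch coefficients are averaged arithmetically into
a symmetric unit-diagonal connectivity matrix (a Fisher-z mean is available
by flag).  Network change over the conditioning session is tracked by the
Euclidean dissimilarity between the habituation matrix and each quarter
matrix, summarized with a least-squares trend line.

The term "cross-correlation coefficient" is implemented as the zero-lag
Pearson correlation of the filtered epochs by default; a lagged-maximum mode
(maximum of the normalized cross-correlation within a configurable lag
window, default ±100 ms) is provided because the term is ambiguous in common
usage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Recording
from .protocol import EpochSet
from .spectral import THETA, bandpass
from .stats import linear_trend

__all__ = [
    "DEFAULT_REGIONS",
    "ConnectivityMatrix",
    "DissimilarityTrajectory",
    "pair_coefficient",
    "subject_matrix",
    "group_matrix",
    "matrix_dissimilarity",
    "dissimilarity_trajectory",
]

#: Bilateral recording sites: anterior cingulate, anterior insula,
#: retrosplenial cortex, basolateral amygdala.
DEFAULT_REGIONS = ("ACC_L", "ACC_R", "AI_L", "AI_R", "RSC_L", "RSC_R", "BLA_L", "BLA_R")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric matrix of pairwise coefficients for one band and phase."""

    labels: tuple[str, ...]
    values: np.ndarray
    band: tuple[float, float]
    phase: str
    mode: str = "zero-lag"
    epoch_stack: np.ndarray | None = None  # (n_epochs, n, n) per-epoch coefficients

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("connectivity matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("coefficients must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_epochs(self) -> int:
        return 0 if self.epoch_stack is None else self.epoch_stack.shape[0]

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def relabel(self, order: tuple[str, ...]) -> "ConnectivityMatrix":
        """Reorder regions; rows/columns are permuted consistently."""
        idx = [self.labels.index(lbl) for lbl in order]
        stack = None if self.epoch_stack is None else self.epoch_stack[:, idx][:, :, idx]
        return ConnectivityMatrix(
            labels=tuple(order),
            values=self.values[np.ix_(idx, idx)],
            band=self.band,
            phase=self.phase,
            mode=self.mode,
            epoch_stack=stack,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def write(self, tsv_path, meta_path=None) -> None:
        """Labeled TSV matrix plus JSON metadata."""
        self.to_frame().to_csv(tsv_path, sep="\t")
        if meta_path is not None:
            meta = {
                "band_hz": list(self.band),
                "phase": self.phase,
                "mode": self.mode,
                "n_epochs": self.n_epochs,
                "labels": list(self.labels),
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)


@dataclass(frozen=True)
class DissimilarityTrajectory:
    """Per-quarter distances from the habituation matrix, with trend line."""

    reference_phase: str
    values: tuple[float, ...]
    slope: float
    intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quarter": np.arange(1, len(self.values) + 1),
                "dissimilarity": self.values,
                "trend": [self.intercept + self.slope * i for i in range(len(self.values))],
            }
        )


def pair_coefficient(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "zero-lag",
    fs: float | None = None,
    max_lag_s: float = 0.1,
) -> float:
    """Correlation coefficient of two equal-length filtered epochs.

    ``zero-lag`` (default): Pearson correlation at lag 0.
    ``lagged-max``: signed maximum of the normalized cross-correlation over
    lags within ±``max_lag_s`` (requires ``fs``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("epochs must be equal-length 1-D arrays")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance epoch: correlation undefined")
    if mode == "zero-lag":
        return float(np.clip(xc @ yc / (sx * sy), -1.0, 1.0))
    if mode == "lagged-max":
        if fs is None:
            raise ValueError("lagged-max mode requires the sampling rate fs")
        max_lag = int(round(max_lag_s * fs))
        n = x.size
        cc = np.correlate(xc, yc, mode="full") / (sx * sy)  # lags -(n-1) .. n-1
        mid = n - 1
        window = cc[mid - max_lag : mid + max_lag + 1]
        return float(np.clip(window.max(), -1.0, 1.0))
    raise ValueError(f"unknown mode {mode!r}")


def _epoch_corr_stack(sig: np.ndarray, mode: str, fs: float, max_lag_s: float) -> np.ndarray:
    """Pairwise coefficients for one epoch, all channels. sig: (n_ch, n_samp)."""
    n_ch = sig.shape[0]
    if mode == "zero-lag":
        sd = sig.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.argmax(sd == 0))
            raise ValueError(f"zero-variance epoch in channel index {bad}")
        c = np.corrcoef(sig)
        np.fill_diagonal(c, 1.0)
        return np.clip(c, -1.0, 1.0)
    m = np.eye(n_ch)
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            m[i, j] = m[j, i] = pair_coefficient(
                sig[i], sig[j], mode=mode, fs=fs, max_lag_s=max_lag_s
            )
    return m


def subject_matrix(
    rec: Recording,
    epochs: EpochSet,
    band: tuple[float, float] = THETA,
    labels: tuple[str, ...] | None = None,
    mode: str = "zero-lag",
    max_lag_s: float = 0.1,
    fisher_mean: bool = False,
) -> ConnectivityMatrix:
    """Connectivity matrix of one subject for one epoch set.

    Epochs are sliced from the raw recording and band-filtered per epoch
    (zero-phase), so samples inside shock windows never reach the filter;
    per-epoch coefficient matrices are then averaged across epochs
    (arithmetic mean by default, Fisher-z mean with ``fisher_mean=True``).
    """
    labels = tuple(labels or rec.labels)
    missing = [lbl for lbl in labels if lbl not in rec.labels]
    if missing:
        raise ValueError(f"recording is missing channel(s): {', '.join(missing)}")
    idx = [rec.labels.index(lbl) for lbl in labels]
    data = rec.samples[idx]

    stack = []
    for sl in epochs.sample_slices(rec.fs):
        seg = bandpass(data[:, sl], band, rec.fs)
        stack.append(_epoch_corr_stack(seg, mode, rec.fs, max_lag_s))
    stack = np.asarray(stack)

    if fisher_mean:
        z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    mean = (mean + mean.T) / 2
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(
        labels=labels,
        values=np.clip(mean, -1.0, 1.0),
        band=band,
        phase=epochs.phase,
        mode=mode,
        epoch_stack=stack,
    )


def group_matrix(
    matrices: list[ConnectivityMatrix],
) -> tuple[ConnectivityMatrix, pd.DataFrame]:
    """Element-wise mean across subjects, plus per-pair subject values.

    The returned DataFrame (one row per subject × unordered pair) is the
    export used for external statistics on Fig.-2-style bar graphs.
    """
    if not matrices:
        raise ValueError("need at least one subject matrix")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.labels != ref.labels or m.band != ref.band or m.phase != ref.phase:
            raise ValueError("subject matrices differ in labels, band, or phase")
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 1.0)
    rows = []
    n = len(ref.labels)
    for s, m in enumerate(matrices):
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (s, ref.labels[i], ref.labels[j], float(m.values[i, j]))
                )
    table = pd.DataFrame(rows, columns=["subject", "region_a", "region_b", "coefficient"])
    out = ConnectivityMatrix(
        labels=ref.labels, values=mean, band=ref.band, phase=ref.phase, mode=ref.mode
    )
    return out, table


def matrix_dissimilarity(m1: ConnectivityMatrix | np.ndarray, m2: ConnectivityMatrix | np.ndarray) -> float:
    """Euclidean distance between two connectivity matrices.

    The norm is taken over the strict upper triangle — each unordered region
    pair counted once, diagonal excluded.  Zero iff the matrices agree on
    every pair.
    """
    a = m1.values if isinstance(m1, ConnectivityMatrix) else np.asarray(m1, dtype=float)
    b = m2.values if isinstance(m2, ConnectivityMatrix) else np.asarray(m2, dtype=float)
    if isinstance(m1, ConnectivityMatrix) and isinstance(m2, ConnectivityMatrix):
        if m1.labels != m2.labels:
            raise ValueError("matrices have different region labels")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.linalg.norm(a[iu] - b[iu]))


def dissimilarity_trajectory(
    hab: ConnectivityMatrix,
    quarters: list[ConnectivityMatrix],
) -> DissimilarityTrajectory:
    """Distance from the habituation matrix to each quarter matrix.

    Returns the per-quarter values together with the ordinary-least-squares
    trend over quarter index (0-based x).
    """
    if len(quarters) < 2:
        raise ValueError("need at least 2 quarter matrices for a trend")
    values = tuple(matrix_dissimilarity(hab, q) for q in quarters)
    slope, intercept = linear_trend(np.asarray(values))
    return DissimilarityTrajectory(
        reference_phase=hab.phase, values=values, slope=slope, intercept=intercept
    )
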