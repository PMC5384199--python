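"""Band filtering and normalized spectral power.

Frequency bands follow the study's definitions — delta 1–3, theta 3–8,
alpha 8–13, beta 14–30, gamma 30–55 Hz (the 13–14 Hz gap between alpha and
beta is kept as defined rather than silently bridged).  Power spectra are
min–max normalized, ``(x_i - min(x)) / (max(x) - min(x))``, across all
frequency bins in 1–55 Hz, per channel and per phase, so that a habituation
spectrum and a conditioning spectrum are each mapped onto [0, 1] before they
are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

__all__ = [
    "BAND_TABLE",
    "BandTable",
    "bandpass",
    "theta_filter",
    "psd",
    "minmax_normalize",
    "band_powers",
]

THETA = (3.0, 8.0)

#: Band edges in Hz, half-open [low, high).
BAND_TABLE: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (3.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 55.0),
}


@dataclass(frozen=True)
class BandTable:
    """Named frequency bands with [low, high) edges in Hz."""

    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi):
                raise ValueError(f"band {name!r}: need 0 < low < high, got [{lo}, {hi})")

    def validate_for(self, fs: float) -> None:
        for name, (_, hi) in self.bands.items():
            if hi >= fs / 2:
                raise ValueError(f"band {name!r} upper edge {hi} Hz >= Nyquist {fs / 2} Hz")

    @property
    def span(self) -> tuple[float, float]:
        los = [lo for lo, _ in self.bands.values()]
        his = [hi for _, hi in self.bands.values()]
        return min(los), max(his)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in self.bands.items()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BandTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({k: (float(v[0]), float(v[1])) for k, v in raw.items()})

    @classmethod
    def default(cls) -> "BandTable":
        return cls(dict(BAND_TABLE))


def _butter_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"invalid band [{lo}, {hi}): need 0 < low < high")
    if hi >= fs / 2:
        raise ValueError(f"band upper edge {hi} Hz is at or above Nyquist ({fs / 2} Hz)")
    return sps.butter(order, band, btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, band: tuple[float, float], fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis.

    A 4th-order Butterworth applied forward-backward (``sosfiltfilt``), so the
    output has no phase lag — required because lag structure feeds the
    cross-correlation stage.  Output has the same shape and sampling rate.
    """
    x = np.asarray(x, dtype=float)
    sos = _butter_sos(band, fs, order)
    return sps.sosfiltfilt(sos, x, axis=-1)


def theta_filter(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 3–8 Hz filtering, the study's theta band."""
    return bandpass(x, THETA, fs)


def psd(
    epochs: np.ndarray,
    fs: float,
    segment_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch spectral estimate averaged over equal-length epochs.

    Parameters
    ----------
    epochs : array, shape (n_epochs, ..., n_samples)
        Equal-length signal epochs; leading axes beyond the first (e.g. a
        channel axis) are preserved.
    fs : float
        Sampling rate in Hz.
    segment_s : float
        Welch segment length in seconds (2-s Hann segments, 50% overlap by
        default, giving 0.5 Hz resolution).

    Returns
    -------
    freqs : array of bin frequencies (Hz)
    power : array, epoch-averaged power spectral density
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    nper = int(round(segment_s * fs))
    if epochs.shape[-1] < nper:
        raise ValueError(
            f"epoch length {epochs.shape[-1] / fs:.3f} s shorter than one "
            f"{segment_s:.0f}-s Welch segment"
        )
    freqs, pxx = sps.welch(
        epochs,
        fs=fs,
        window="hann",
        nperseg=nper,
        noverlap=int(round(nper * overlap)),
        axis=-1,
    )
    return freqs, pxx.mean(axis=0)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min–max normalization ``(x_i - min(x)) / (max(x) - min(x))``.

    Order-preserving map onto [0, 1]; the minimum maps to 0 and the maximum
    to 1.  Constant input is rejected (the denominator would vanish).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant vector (max == min)")
    return (x - lo) / (hi - lo)


def band_powers(
    freqs: np.ndarray,
    power: np.ndarray,
    bands: BandTable | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Normalized band power from a PSD.

    The PSD bins spanning the band table (1–55 Hz by default) are min–max
    normalized, then each band's value is the mean of the normalized bins
    with ``low <= f < high``.

    Returns the per-band means (Series indexed by band name) and the
    normalized spectrum over the analysed bins.
    """
    bands = bands or BandTable.default()
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    lo_all, hi_all = bands.span
    sel = (freqs >= lo_all) & (freqs <= hi_all)
    if not sel.any() or freqs[sel].min() > lo_all or freqs[sel].max() < hi_all:
        raise ValueError(f"PSD does not cover the {lo_all}-{hi_all} Hz analysis range")
    norm = minmax_normalize(power[sel])
    fsel = freqs[sel]
    out = {}
    for name, (lo, hi) in bands.bands.items():
        m = (fsel >= lo) & (fsel < hi)
        if not m.any():
            raise ValueError(f"no PSD bins inside band {name!r} [{lo}, {hi})")
        out[name] = float(norm[m].mean())
    return pd.Series(out, name="normalized_power"), norm
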