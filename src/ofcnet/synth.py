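"""Synthetic study data with known ground truth.

Every input the pipeline consumes can be generated here: multichannel LFP
with controlled narrowband coupling, shock artifacts, immobility traces with
prescribed freezing bouts, and plaque images with an exact target area
fraction.

Coupling model
--------------
A coupled channel pair shares a common band-limited Gaussian source ``s``
(unit variance in the carrier band) mixed into each channel's background
noise: ``x_k = c * s + noise_k``.  The background is pink noise (power
spectral density ~ 1/f^exponent) whose standard deviation *within the
analysis (theta) band* is calibrated to ``noise_sd``.  This in-band
calibration is what makes the expected theta-filtered correlation of a pair
exactly closed-form:

    rho = c^2 / (c^2 + noise_sd^2)

so gain 1 with noise_sd = sigma gives the reference curve 1 / (1 + sigma^2),
and the generator can be verified against it.

Coupling gains may differ between session phases (habituation vs
conditioning) and may ramp across sub-intervals of a phase, which is how a
"Tg-like" cohort with network change that grows over conditioning quarters
is emulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .behavior import MovementTrace
from .io import Recording
from .protocol import SessionProtocol
from .spectral import THETA, bandpass

__all__ = [
    "CouplingSpec",
    "SimConfig",
    "GroupSpec",
    "generate_coupled_lfp",
    "inject_shock_artifacts",
    "generate_movement_trace",
    "generate_plaque_image",
    "generate_group_dataset",
    "pink_noise",
]

_REGIONS8 = ("ACC_L", "ACC_R", "AI_L", "AI_R", "RSC_L", "RSC_R", "BLA_L", "BLA_R")


@dataclass(frozen=True)
class CouplingSpec:
    """One shared-source coupling: a channel pair, a phase, gain(s), a band.

    ``gain`` may be a scalar in [0, 1] or a sequence of scalars, in which
    case the phase is split into equal sub-intervals with one gain each.
    """

    pair: tuple[str, str]
    phase: str
    gain: float | tuple[float, ...]
    band: tuple[float, float] = THETA

    def gains(self) -> tuple[float, ...]:
        g = self.gain
        return tuple(g) if isinstance(g, (tuple, list)) else (float(g),)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording."""

    n_channels: int
    duration: float
    fs: float = 1600.0
    labels: tuple[str, ...] | None = None
    coupling_spec: tuple[CouplingSpec, ...] = ()
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    phases: dict | None = None  # {label: (start s, end s)}; None = {"all": whole}
    shock_schedule: tuple[tuple[float, float, float], ...] = ()  # (onset, dur, amp)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        labels = self.labels
        if labels is None:
            labels = _REGIONS8 if self.n_channels == 8 else tuple(
                f"ch{i}" for i in range(self.n_channels)
            )
        labels = tuple(labels)
        if len(labels) != self.n_channels:
            raise ValueError("label count must match n_channels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "coupling_spec", tuple(self.coupling_spec))
        phases = self.phases if self.phases is not None else {"all": (0.0, self.duration)}
        for name, (lo, hi) in phases.items():
            if not (0 <= lo < hi <= self.duration + 1e-9):
                raise ValueError(f"phase {name!r} interval [{lo}, {hi}) outside recording")
        object.__setattr__(self, "phases", dict(phases))
        for spec in self.coupling_spec:
            lo, hi = spec.band
            if not (0 < lo < hi):
                raise ValueError(f"invalid carrier band [{lo}, {hi}): need 0 < low < high")
            if hi >= self.fs / 2:
                raise ValueError(
                    f"carrier band [{lo}, {hi}) reaches Nyquist ({self.fs / 2} Hz); "
                    "need fs > 2 * high"
                )
            for g in spec.gains():
                if not (0 <= g <= 1):
                    raise ValueError(f"coupling gain {g} outside [0, 1]")
            if spec.phase not in self.phases:
                raise ValueError(f"coupling references unknown phase {spec.phase!r}")
            for lbl in spec.pair:
                if lbl not in self.labels:
                    raise ValueError(f"coupling references unknown channel {lbl!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(asdict(self)), fh, sort_keys=False)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD ~ 1/f**exponent (DC removed)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2)
    return np.fft.irfft(spec * shape, n=n)


def _band_limited_source(n: int, band: tuple[float, float], fs: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Gaussian process confined to the carrier band, unit analysis variance.

    Normalized so the *refiltered* source (the analysis stage band-filters
    every epoch again) has unit sample variance; the noise calibration uses
    the same single-pass convention, which keeps the closed-form pair
    correlation rho = c^2 / (c^2 + sigma^2) exact in expectation.
    """
    s = bandpass(rng.standard_normal(n), band, fs)
    sd = bandpass(s, band, fs).std()
    if sd == 0:
        raise ValueError("degenerate source (zero variance)")
    return s / sd


def generate_coupled_lfp(config: SimConfig, calibration_band: tuple[float, float] = THETA) -> Recording:
    """Simulate a multichannel LFP recording under the shared-source model.

    Each channel carries pink noise scaled so its standard deviation within
    ``calibration_band`` equals ``noise_sd``; each coupling spec adds
    ``gain * s(t)`` of a common band-limited source to both channels of its
    pair during its phase.  Deterministic: the same config (including seed)
    reproduces the output bit for bit.
    """
    n = int(round(config.duration * config.fs))
    ss = np.random.SeedSequence(config.seed)
    noise_seeds, source_seeds = ss.spawn(2)
    noise_rngs = [np.random.default_rng(s) for s in noise_seeds.spawn(config.n_channels)]
    source_rngs = [
        np.random.default_rng(s) for s in source_seeds.spawn(max(len(config.coupling_spec), 1))
    ]

    data = np.zeros((config.n_channels, n))
    if config.noise_sd > 0:
        for k in range(config.n_channels):
            x = pink_noise(n, config.noise_exponent, noise_rngs[k])
            inband_sd = bandpass(x, calibration_band, config.fs).std()
            data[k] = x * (config.noise_sd / inband_sd)

    for spec, rng in zip(config.coupling_spec, source_rngs):
        lo_t, hi_t = config.phases[spec.phase]
        i0, i1 = int(np.floor(lo_t * config.fs)), int(np.floor(hi_t * config.fs))
        s = _band_limited_source(i1 - i0, spec.band, config.fs, rng)
        gains = spec.gains()
        n_sub = len(gains)
        edges = np.linspace(0, i1 - i0, n_sub + 1).astype(int)
        envelope = np.empty(i1 - i0)
        for g, a, b in zip(gains, edges[:-1], edges[1:]):
            envelope[a:b] = g
        contribution = envelope * s
        for lbl in spec.pair:
            data[config.labels.index(lbl)][i0:i1] += contribution

    annotations = {
        "phases": {k: list(v) for k, v in config.phases.items()},
        "coupling": [
            {"pair": list(sp.pair), "phase": sp.phase, "gain": list(sp.gains()),
             "band": list(sp.band)}
            for sp in config.coupling_spec
        ],
        "seed": config.seed,
    }
    return Recording(samples=data, fs=config.fs, labels=config.labels,
                     annotations=annotations)


def inject_shock_artifacts(rec: Recording, protocol: SessionProtocol,
                           amplitude: float) -> Recording:
    """Add high-amplitude transients inside each shock window.

    The artifact is a Hann-windowed deflection of the given amplitude on
    every channel; samples outside the shock windows are untouched
    (bit-exact), which is what the guard-trimmed epoching relies on.
    """
    shocks = protocol.shock_intervals()
    for (a0, a1), (b0, b1) in zip(shocks, shocks[1:]):
        if b0 < a1:
            raise ValueError("overlapping shock intervals")
    out = rec.copy()
    n = out.n_samples
    for onset, end in shocks:
        i0, i1 = int(np.floor(onset * rec.fs)), int(np.floor(end * rec.fs))
        if i0 < 0 or i1 > n:
            raise ValueError(
                f"shock [{onset}, {end}) s outside the {n / rec.fs:.1f}-s recording"
            )
        out.samples[:, i0:i1] += amplitude * np.hanning(i1 - i0)
    out.annotations = dict(out.annotations)
    out.annotations["shocks"] = [list(iv) for iv in shocks]
    return out


def generate_movement_trace(bouts: list[tuple[float, float]], total: float,
                            fs_beh: float = 30.0, phase: str = "") -> MovementTrace:
    """Binary immobility trace, immobile exactly during the listed bouts.

    ``bouts`` are (start s, duration s), non-overlapping and inside
    [0, total]; sample *i* is immobile iff ``start <= i/fs < start+duration``
    for some bout.
    """
    events = sorted((float(s), float(d)) for s, d in bouts)
    prev_end = 0.0
    for start, dur in events:
        if dur <= 0:
            raise ValueError("bout durations must be positive")
        if start < prev_end - 1e-12:
            raise ValueError("bouts overlap")
        if start < 0 or start + dur > total + 1e-12:
            raise ValueError(f"bout ({start}, {dur}) outside [0, {total}]")
        prev_end = start + dur
    n = int(round(total * fs_beh))
    immobile = np.zeros(n, dtype=bool)
    for start, dur in events:
        i0 = int(np.ceil(start * fs_beh - 1e-9))
        i1 = int(np.ceil((start + dur) * fs_beh - 1e-9))
        immobile[i0:min(i1, n)] = True
    return MovementTrace(immobile=immobile, fs=fs_beh, phase=phase)


def generate_plaque_image(
    region_mask: np.ndarray,
    target_fraction: float,
    blob_params: dict | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    background: float = 20.0,
    foreground: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic plaque image: bright blobs covering an exact area fraction.

    Random disks are unioned inside the region mask until the plaque pixel
    count equals ``round(target_fraction/100 * region_area)``; the last disk
    is trimmed (pixels nearest its centre kept) to land on the exact count.
    Returns ``(image, truth_mask)``; with ``noise_sd = 0`` the image is
    noiseless two-level.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not (0 <= target_fraction <= 100):
        raise ValueError("target_fraction must lie in [0, 100]")
    region_px = int(region_mask.sum())
    if region_px == 0:
        raise ValueError("region mask is empty")
    params = {"radius_range": (3, 8)}
    params.update(blob_params or {})
    r_lo, r_hi = params["radius_range"]
    if r_lo < 1 or r_hi < r_lo:
        raise ValueError(f"unusable blob radius range {params['radius_range']}")

    rng = np.random.default_rng(seed)
    target_px = int(round(target_fraction / 100 * region_px))
    truth = np.zeros_like(region_mask)
    region_coords = np.argwhere(region_mask)
    h, w = region_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    placed = 0
    guard = 0
    while placed < target_px:
        guard += 1
        if guard > 100000:
            raise ValueError("target fraction unreachable with these blob parameters")
        cy, cx = region_coords[rng.integers(len(region_coords))]
        r = rng.integers(r_lo, r_hi + 1)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = (d2 <= r * r) & region_mask & ~truth
        new = int(disk.sum())
        if new == 0:
            continue
        need = target_px - placed
        if new <= need:
            truth |= disk
            placed += new
        else:
            # trim the final blob to the exact remaining pixel count
            cand = np.argwhere(disk)
            order = np.argsort(d2[disk], kind="stable")[:need]
            sel = cand[order]
            truth[sel[:, 0], sel[:, 1]] = True
            placed += need
    image = np.where(truth, foreground, background).astype(float)
    image[~region_mask] = 0.0
    if noise_sd > 0:
        image = image + noise_sd * rng.standard_normal(image.shape)
    return image, truth


@dataclass(frozen=True)
class GroupSpec:
    """Study conditions for one cohort.

    Defaults emulate the 11-month transgenic ("Tg"-like) condition: theta
    coupling between left anterior insula and right basolateral amygdala that
    is modest during habituation and elevated during conditioning, ramping
    across the four conditioning quarters; higher freezing; plaque burden
    monotonically linked to freezing.  :meth:`wildtype` gives the matched
    control with equal gains in both phases and no plaque.
    """

    name: str = "Tg"
    n_subjects: int = 10
    pair: tuple[str, str] = ("AI_L", "BLA_R")
    hab_gain: float = 0.3
    cond_gains: tuple[float, ...] = (0.5, 0.65, 0.8, 0.95)
    noise_sd: float = 1.0
    fs: float = 1600.0
    freeze_fraction: tuple[float, float] = (0.45, 0.75)  # range of conditioning freezing
    plaque_slope: float = 0.25  # burden %-points per %-point of freezing
    plaque_noise: float = 1.0
    regions: tuple[str, ...] = ("AI", "BLA", "RSC", "ACC")
    # per-region noise multipliers: the AI link is tightest, so its
    # burden-freezing correlation is the strongest of the four regions
    region_noise_scale: tuple[float, ...] = (1.0, 1.5, 2.5, 3.0)

    @classmethod
    def wildtype(cls, n_subjects: int = 7) -> "GroupSpec":
        return cls(
            name="Wt",
            n_subjects=n_subjects,
            hab_gain=0.3,
            cond_gains=(0.3, 0.3, 0.3, 0.3),
            freeze_fraction=(0.05, 0.30),
            plaque_slope=0.0,
            plaque_noise=0.0,
        )


def _subject_bouts(rng: np.random.Generator, t0: float, t1: float,
                   frac: float) -> list[tuple[float, float]]:
    """Non-overlapping freezing bouts covering ~frac of [t0, t1)."""
    span = t1 - t0
    target = frac * span
    bouts: list[tuple[float, float]] = []
    cursor = t0
    accumulated = 0.0
    while accumulated < target and cursor < t1 - 1.5:
        gap = rng.uniform(0.5, 4.0)
        dur = rng.uniform(1.5, 6.0)
        start = cursor + gap
        dur = min(dur, t1 - start, target - accumulated + 1.1)
        if start >= t1 or dur <= 1.1:
            break
        bouts.append((start, dur))
        accumulated += dur
        cursor = start + dur
    return bouts


def generate_group_dataset(
    spec: GroupSpec,
    protocol: SessionProtocol | None = None,
    seed: int = 0,
) -> dict:
    """Generate a cohort: per-subject recordings, traces and plaque burdens.

    Returns a bundle ``{"spec", "protocol", "subjects"}`` where each subject
    carries a :class:`Recording` (habituation + conditioning phases),
    a :class:`MovementTrace` over the full session, per-region plaque burden
    percentages linked monotonically to conditioning freezing, and the
    ground-truth parameters used.
    """
    protocol = protocol or SessionProtocol()
    name_tag = zlib.crc32(spec.name.encode()) & 0xFFFF  # stable across processes
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, name_tag])
    phases = {
        "habituation": (0.0, protocol.habituation_duration),
        "conditioning": (protocol.conditioning_start, protocol.total_duration),
    }
    subjects = []
    for i, child in enumerate(ss.spawn(spec.n_subjects)):
        sub_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        rng = np.random.default_rng(child)
        config = SimConfig(
            n_channels=8,
            duration=protocol.total_duration,
            fs=spec.fs,
            coupling_spec=(
                CouplingSpec(spec.pair, "habituation", spec.hab_gain),
                CouplingSpec(spec.pair, "conditioning", spec.cond_gains),
            ),
            noise_sd=spec.noise_sd,
            phases=phases,
            seed=sub_seed,
        )
        rec = generate_coupled_lfp(config)

        frac = rng.uniform(*spec.freeze_fraction)
        bouts = _subject_bouts(
            rng, protocol.conditioning_start, protocol.total_duration, frac
        )
        trace = generate_movement_trace(bouts, protocol.total_duration)
        freezing_s = sum(d for _, d in bouts)
        freezing_pct = 100.0 * freezing_s / protocol.conditioning_duration

        burdens = {}
        for region, scale in zip(spec.regions, spec.region_noise_scale):
            base = spec.plaque_slope * freezing_pct
            noise = (
                spec.plaque_noise * scale * rng.standard_normal()
                if spec.plaque_noise
                else 0.0
            )
            burdens[region] = float(np.clip(base + noise, 0.0, 100.0))

        subjects.append(
            {
                "id": f"{spec.name}-{i + 1}",
                "recording": rec,
                "trace": trace,
                "freezing_pct": freezing_pct,
                "plaque_burden": burdens,
                "config": config,
            }
        )
    return {"spec": spec, "protocol": protocol, "subjects": subjects}
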