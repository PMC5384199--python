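"""Recording container and file formats.

A :class:`Recording` holds a channels × time sample matrix in signal units,
the sampling rate, unique channel labels (``REGION_HEMI``, e.g. ``AI_L``),
and optional annotations (phase and shock intervals).  Supported on-disk
formats:

* HDF5 — lossless float64 round trip (``samples`` dataset + attributes).
* CSV + JSON sidecar — samples as one column per channel; sampling rate,
  labels and annotations in ``<stem>.json`` next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["Recording", "read_recording", "write_recording"]


@dataclass
class Recording:
    """Multichannel signal with labels, sampling rate and annotations."""

    samples: np.ndarray  # (n_channels, n_samples), signal units
    fs: float
    labels: tuple[str, ...]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = tuple(self.labels)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None

    def copy(self) -> "Recording":
        return Recording(
            samples=self.samples.copy(),
            fs=self.fs,
            labels=self.labels,
            annotations=dict(self.annotations),
        )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format explicitly")


def write_recording(rec: Recording, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "w") as h5:
            ds = h5.create_dataset("samples", data=rec.samples)
            ds.attrs["fs"] = rec.fs
            ds.attrs["labels"] = json.dumps(list(rec.labels))
            ds.attrs["annotations"] = json.dumps(rec.annotations)
    elif fmt == "csv":
        # %.17g round-trips IEEE doubles exactly
        pd.DataFrame(rec.samples.T, columns=list(rec.labels)).to_csv(
            path, index=False, float_format="%.17g"
        )
        sidecar = path.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {"fs": rec.fs, "labels": list(rec.labels), "annotations": rec.annotations},
                fh,
                indent=2,
            )
    else:
        raise ValueError(f"unsupported format {fmt!r} (supported: hdf5, csv)")


def read_recording(path, fmt: str | None = None) -> Recording:
    """Read a Recording from HDF5 or CSV + JSON sidecar.

    The CSV reader requires a ``<stem>.json`` sidecar carrying the sampling
    rate and labels; a missing sidecar is an error naming the expected file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "r") as h5:
            ds = h5["samples"]
            samples = ds[()]
            labels = tuple(json.loads(ds.attrs["labels"]))
            annotations = json.loads(ds.attrs["annotations"])
            fs = float(ds.attrs["fs"])
        return Recording(samples=samples, fs=fs, labels=labels, annotations=annotations)
    if fmt == "csv":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"CSV recording {path} requires sidecar {sidecar} with fs/labels"
            )
        with open(sidecar) as fh:
            meta = json.load(fh)
        frame = pd.read_csv(path, float_precision="round_trip")
        labels = tuple(meta["labels"])
        if list(frame.columns) != list(labels):
            raise ValueError(
                f"CSV columns {list(frame.columns)} do not match sidecar labels {list(labels)}"
            )
        return Recording(
            samples=frame.to_numpy().T,
            fs=float(meta["fs"]),
            labels=labels,
            annotations=meta.get("annotations", {}),
        )
    raise ValueError(f"unsupported format {fmt!r} (supported: hdf5, csv)")
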