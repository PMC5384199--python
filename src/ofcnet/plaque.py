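"""Amyloid plaque burden: area percentage of stained plaque within a region.

Burden is ``100 * (plaque pixel area / region pixel area)``, following the
thioflavin-S quantification convention.  Segmentation defaults to an Otsu
threshold computed from the pixel intensities *within* the region mask (a
fixed threshold is available); the threshold used is always reported so a
run can be reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = ["segment_plaques", "plaque_burden", "quantify", "PlaqueBurdenTable"]


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray
    threshold: float
    method: str


def segment_plaques(
    image: np.ndarray,
    region_mask: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_blob_px: int = 0,
) -> SegmentationResult:
    """Binary plaque mask within the region.

    ``otsu`` (default) computes the threshold from in-region intensities;
    ``fixed`` uses the supplied ``threshold``.  The returned mask is a subset
    of the region mask.  A region whose intensities are constant yields an
    empty mask (nothing to separate).  ``min_blob_px`` optionally removes
    connected components smaller than the given pixel count.
    """
    image = np.asarray(image, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if image.shape != region_mask.shape:
        raise ValueError(f"image {image.shape} and mask {region_mask.shape} shapes differ")
    if not region_mask.any():
        raise ValueError("region mask is empty")
    inside = image[region_mask]
    if method == "otsu":
        if np.ptp(inside) == 0:
            return SegmentationResult(
                mask=np.zeros_like(region_mask), threshold=float(inside[0]), method="otsu"
            )
        th = float(threshold_otsu(inside))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        th = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = (image > th) & region_mask
    if min_blob_px > 0:
        from skimage.measure import label

        lbl = label(mask)
        counts = np.bincount(lbl.ravel())
        keep = np.flatnonzero(counts >= min_blob_px)
        keep = keep[keep != 0]
        mask = np.isin(lbl, keep)
    return SegmentationResult(mask=mask, threshold=th, method=method)


def plaque_burden(plaque_mask: np.ndarray, region_mask: np.ndarray) -> float:
    """Plaque area as a percentage of region area: 100 * plaque_px / region_px."""
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if plaque_mask.shape != region_mask.shape:
        raise ValueError("mask shapes differ")
    region_px = int(region_mask.sum())
    if region_px == 0:
        raise ValueError("region has zero area")
    if np.any(plaque_mask & ~region_mask):
        raise ValueError("plaque mask extends outside the region mask")
    return 100.0 * int(plaque_mask.sum()) / region_px


def quantify(
    image: np.ndarray,
    region_mask: np.ndarray,
    animal: str,
    region: str,
    **seg_kwargs,
) -> dict:
    """Segment and measure one image; returns a burden-table row."""
    seg = segment_plaques(image, region_mask, **seg_kwargs)
    return {
        "animal": animal,
        "region": region,
        "burden": plaque_burden(seg.mask, region_mask),
        "threshold": seg.threshold,
        "method": seg.method,
    }


class PlaqueBurdenTable:
    """Per-animal, per-region burden percentages, exportable to CSV."""

    COLUMNS = ["animal", "region", "burden", "threshold", "method"]

    def __init__(self, rows: list[dict] | None = None):
        self.rows: list[dict] = list(rows or [])
        for row in self.rows:
            self._validate(row)

    @staticmethod
    def _validate(row: dict) -> None:
        if not (0 <= row["burden"] <= 100):
            raise ValueError(f"burden {row['burden']} outside [0, 100]")

    def add(self, row: dict) -> None:
        self._validate(row)
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
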