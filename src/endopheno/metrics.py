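"""Per-cell intensity metrics and profile extraction.

The central statistic is the GFP signal-accumulation score: the maximal
pixel intensity of a cell ROI divided by its median pixel intensity,
computed on raw pixels over the whole cell (nucleus included, no
background subtraction).  A score of 1 means the signal is homogeneous
through the cell, as for free GFP; a punctate, endosome-localized
protein concentrates signal into a few bright pixels and scores high.
The score is a ratio, so it is invariant under multiplicative intensity
scaling (exposure, gain) but not under additive offsets.

Also here: signal-to-noise filtering against a non-expressing reference
cell in the same field, line-scan profiles for colocalization display,
and pulldown densitometry normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import FieldError, ImageField, RegionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccumulationRecord:
    """Max, median and their ratio for one cell ROI."""

    cell_id: int
    max_intensity: float
    median_intensity: float
    score: float
    construct: str = "unknown"
    replicate: int = 1


def accumulation_score(image: ImageField, regions: RegionSet,
                       channel: str = "gfp") -> pd.DataFrame:
    """Signal-accumulation score (max / median) for every labeled cell.

    Returns a DataFrame with columns ``cell_id``, ``construct``,
    ``replicate``, ``max``, ``median``, ``score``.  The median uses
    midpoint interpolation for even pixel counts.  A cell whose median
    is zero cannot be scored; it is excluded with a logged warning and
    reported with NaN score.
    """
    rows = []
    for cell_id in regions.labels:
        meta = regions.row(int(cell_id))
        pix = regions.pixels(image, int(cell_id), channel)
        med = float(np.median(pix))
        mx = float(pix.max())
        if med <= 0:
            logger.warning("cell %d: zero median intensity, excluded", cell_id)
            score = np.nan
        else:
            score = mx / med
        rows.append({"cell_id": int(cell_id), "construct": meta["construct"],
                     "replicate": meta["replicate"], "max": mx,
                     "median": med, "score": score})
    return pd.DataFrame(rows)


def snr_table(image: ImageField, regions: RegionSet, reference_cell: int,
              channel: str = "gfp") -> pd.DataFrame:
    """Signal-to-noise ratio of every cell against a non-expressing
    reference cell in the same field.

    SNR is the cell ROI median divided by the reference ROI median.
    """
    ref = float(np.median(regions.pixels(image, reference_cell, channel)))
    if ref <= 0:
        raise FieldError(f"reference cell {reference_cell} has nonpositive median")
    rows = []
    for cell_id in regions.labels:
        med = float(np.median(regions.pixels(image, int(cell_id), channel)))
        rows.append({"cell_id": int(cell_id), "cell_median": med,
                     "reference_median": ref, "snr": med / ref})
    return pd.DataFrame(rows)


def snr_filter(records: pd.DataFrame, cutoff: float = 3.0
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition an SNR table into (kept, excluded) at ``snr >= cutoff``.

    The partition is exhaustive and disjoint.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if (records["reference_median"] <= 0).any():
        raise ValueError("nonpositive reference median in SNR table")
    keep = records["snr"] >= cutoff
    return records[keep].copy(), records[~keep].copy()


@dataclass
class LineScanProfile:
    """Normalized intensity profiles sampled along a segment.

    ``positions`` are distances (px) along the segment, strictly
    increasing; each channel's profile is min-max normalized to [0, 1]
    along the scan (a constant channel maps to all zeros).
    """

    positions: np.ndarray
    profiles: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, **self.profiles})


def line_scan(image: ImageField, p0: tuple[float, float],
              p1: tuple[float, float], channels: list[str] | None = None,
              step: float = 0.5) -> LineScanProfile:
    """Bilinear line-scan profile between two pixel-center coordinates.

    Coordinates are 0-based (row, col).  Samples are uniformly spaced by
    ``step`` px from ``p0`` toward ``p1``, endpoint included.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("zero-length scan segment")
    nrow, ncol = image.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= nrow - 1 and 0 <= p[1] <= ncol - 1):
            raise ValueError(f"scan endpoint {tuple(p)} outside image")
    if channels is None:
        channels = list(image.channels)
    n = int(np.floor(length / step)) + 1
    positions = np.arange(n) * step
    if positions[-1] < length:          # keep the true endpoint
        positions = np.append(positions, length)
    frac = positions / length
    coords = np.outer(1 - frac, p0) + np.outer(frac, p1)
    profiles = {}
    for name in channels:
        raw = ndimage.map_coordinates(image[name], coords.T, order=1,
                                      mode="nearest")
        lo, hi = raw.min(), raw.max()
        profiles[name] = ((raw - lo) / (hi - lo) if hi > lo
                          else np.zeros_like(raw))
    return LineScanProfile(positions=positions, profiles=profiles)


@dataclass(frozen=True)
class DensitometryRecord:
    """Pulldown band intensity normalized to load and to a reference
    pulldown (reference against itself gives exactly 1)."""

    eluate: float
    load: float
    reference_ratio: float
    normalized_binding: float


def normalized_binding(eluate: float, load: float, reference_eluate: float,
                       reference_load: float) -> DensitometryRecord:
    """(eluate/load) divided by (reference_eluate/reference_load)."""
    if load <= 0 or reference_load <= 0:
        raise ValueError("load volumes must be positive")
    if reference_eluate <= 0:
        raise ValueError("reference eluate must be positive")
    ref_ratio = reference_eluate / reference_load
    return DensitometryRecord(
        eluate=eluate, load=load, reference_ratio=ref_ratio,
        normalized_binding=(eluate / load) / ref_ratio,
    )
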