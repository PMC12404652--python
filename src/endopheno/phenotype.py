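"""Deterministic cytoplasmic / distributed / clustered phenotype calls.

A numeric surrogate for blinded human scoring of GFP localization.  A
cell is called:

* ``cytoplasmic`` when less than ``localized_fraction_cutoff`` of its
  above-threshold signal sits in puncta (mostly diffuse signal),
* otherwise ``clustered`` when the punctate signal is confined to at
  most ``cluster_max`` contiguous structures (the field's "three or
  fewer" convention), and
* ``distributed`` when it spreads over more structures.

Only ``cluster_max`` is a fixed convention; the threshold multiplier,
minimum structure area, merge radius and localized-fraction cutoff are
documented implementation defaults.  The threshold is median-relative,
so calls are invariant under multiplicative intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, remove_small_objects

from .fields import FieldError, ImageField, RegionSet

LABELS = ("cytoplasmic", "distributed", "clustered")


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable parameters of the phenotype surrogate.

    threshold_multiplier
        A pixel is punctate when its intensity exceeds this multiple of
        the cell's median intensity (must exceed 1).
    min_structure_area
        Components smaller than this (px^2) are discarded as noise.
    merge_radius
        Structures are dilated by this radius (px) before counting, so
        near-touching vesicle clumps merge — emulating a human's
        grouping of contiguous structures.
    localized_fraction_cutoff
        Minimum fraction of cell signal in puncta for a "localized"
        (non-cytoplasmic) call; a tie counts as localized.
    cluster_max
        Maximum contiguous structure count for a ``clustered`` call.
    """

    threshold_multiplier: float = 3.0
    min_structure_area: int = 4
    merge_radius: int = 2
    localized_fraction_cutoff: float = 0.5
    cluster_max: int = 3

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 1:
            raise ValueError("threshold_multiplier must exceed 1")
        if not 0 < self.localized_fraction_cutoff < 1:
            raise ValueError("localized_fraction_cutoff must be in (0, 1)")
        if self.cluster_max < 1:
            raise ValueError("cluster_max must be >= 1")
        if self.min_structure_area < 1 or self.merge_radius < 0:
            raise ValueError("invalid area/radius parameters")


@dataclass(frozen=True)
class PhenotypeCall:
    cell_id: int
    label: str
    punctate_signal_fraction: float
    structure_count: int
    params: ClassifierParams


def puncta_mask(image: ImageField | np.ndarray, regions: RegionSet,
                cell_id: int, params: ClassifierParams = ClassifierParams(),
                channel: str = "gfp") -> np.ndarray:
    """Binary raster of the cell's punctate pixels.

    A pixel is punctate iff its intensity strictly exceeds
    ``threshold_multiplier`` times the cell's median; components smaller
    than ``min_structure_area`` are removed.
    """
    arr = image[channel] if isinstance(image, ImageField) else np.asarray(image)
    cell = regions.label_mask == cell_id
    if not cell.any():
        raise FieldError(f"cell {cell_id} labels no pixels")
    med = float(np.median(arr[cell]))
    if med <= 0:
        raise FieldError(f"cell {cell_id}: zero median intensity")
    mask = cell & (arr > params.threshold_multiplier * med)
    # remove components with area < min_structure_area
    return remove_small_objects(mask, max_size=params.min_structure_area - 1)


def count_structures(mask: np.ndarray, merge_radius: int = 2) -> int:
    """Number of contiguous structures in a binary raster.

    The mask is dilated by a disk of ``merge_radius`` and 8-connected
    components are counted; deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    if merge_radius > 0:
        mask = dilation(mask, disk(merge_radius))
    return int(cc_label(mask, connectivity=2).max())


def classify(image: ImageField | np.ndarray, regions: RegionSet, cell_id: int,
             params: ClassifierParams = ClassifierParams(),
             channel: str = "gfp") -> PhenotypeCall:
    """Phenotype call for one cell."""
    arr = image[channel] if isinstance(image, ImageField) else np.asarray(image)
    mask = puncta_mask(arr, regions, cell_id, params)
    cell = regions.label_mask == cell_id
    total = float(arr[cell].sum())
    punctate = float(arr[mask].sum()) if total > 0 else 0.0
    fraction = punctate / total if total > 0 else 0.0
    count = count_structures(mask, params.merge_radius)
    if fraction < params.localized_fraction_cutoff:
        label = "cytoplasmic"
    elif count <= params.cluster_max:
        label = "clustered"
    else:
        label = "distributed"
    return PhenotypeCall(cell_id=cell_id, label=label,
                         punctate_signal_fraction=fraction,
                         structure_count=count, params=params)


def classify_all(image: ImageField, regions: RegionSet,
                 params: ClassifierParams = ClassifierParams(),
                 channel: str = "gfp") -> pd.DataFrame:
    """Phenotype calls for every labeled cell, as a DataFrame."""
    rows = []
    for cell_id in regions.labels:
        call = classify(image, regions, int(cell_id), params, channel)
        rows.append({"cell_id": call.cell_id, "label": call.label,
                     "punctate_fraction": call.punctate_signal_fraction,
                     "structure_count": call.structure_count})
    return pd.DataFrame(rows)


def blind_ids(cell_ids, seed: int = 0) -> pd.DataFrame:
    """Blinding key: shuffle cell identifiers into randomized numbers.

    Emulates renaming images to random numbers before scoring.  Returns
    a two-column key (``cell_id``, ``blinded_id``); the mapping is a
    seeded permutation, so scoring can later be un-blinded.
    """
    ids = np.asarray(list(cell_ids))
    rng = np.random.default_rng(seed)
    blinded = rng.permutation(len(ids)) + 1
    return pd.DataFrame({"cell_id": ids, "blinded_id": blinded})
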