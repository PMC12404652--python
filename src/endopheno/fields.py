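"""Image and ROI data model plus TIFF/CSV input-output.

An :class:`ImageField` is a set of named, same-shape 2D intensity rasters
(channel roles such as ``gfp``, ``membrane``, ``dna``, ``marker``); a
:class:`RegionSet` is a per-cell integer label mask plus a cell metadata
table (construct, replicate, expressing flag).  Fields are written as
multi-page TIFF with a JSON sidecar recording channel order and intensity
scaling; label masks are 16-bit TIFF; metadata is plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

CHANNEL_ORDER = ("gfp", "membrane", "dna", "marker")

#: columns required in a cell metadata table
METADATA_COLUMNS = ("cell_id", "construct", "replicate", "expressing")


class FieldError(ValueError):
    """Raised for inconsistent image/mask/metadata combinations."""


@dataclass
class ImageField:
    """Multi-channel 2D intensity image.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2D float array.  All channels must
        share one shape and contain finite, nonnegative intensities.
    pixel_size
        Optional physical pixel size (units per pixel); informational only.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise FieldError("ImageField needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise FieldError(f"channels differ in shape: {sorted(shapes)}")
        clean: dict[str, np.ndarray] = {}
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2:
                raise FieldError(f"channel {name!r} is not 2D")
            if not np.all(np.isfinite(arr)):
                raise FieldError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise FieldError(f"channel {name!r} contains negative intensities")
            clean[name] = arr
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels

    def __getitem__(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel]
        except KeyError:
            raise FieldError(
                f"channel {channel!r} not present (have {sorted(self.channels)})"
            ) from None


@dataclass
class RegionSet:
    """Per-cell label mask and metadata.

    ``label_mask`` holds 0 for background and a positive integer per cell.
    ``metadata`` is a DataFrame with columns ``cell_id``, ``construct``,
    ``replicate``, ``expressing``; every listed cell id must be present
    in the mask and label a nonempty region.
    """

    label_mask: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        mask = np.asarray(self.label_mask)
        if mask.ndim != 2:
            raise FieldError("label mask must be 2D")
        if not np.issubdtype(mask.dtype, np.integer):
            raise FieldError("label mask must be integer-typed")
        if mask.min() < 0:
            raise FieldError("label mask labels must be nonnegative")
        self.label_mask = mask
        if self.metadata.empty:
            ids = self.labels
            self.metadata = pd.DataFrame(
                {
                    "cell_id": ids,
                    "construct": "unknown",
                    "replicate": 1,
                    "expressing": True,
                }
            )
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise FieldError(f"metadata missing columns {missing}")
        present = set(self.labels.tolist())
        absent = sorted(set(self.metadata["cell_id"]) - present)
        if absent:
            raise FieldError(f"metadata references labels absent from mask: {absent}")

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.label_mask)
        return lab[lab > 0]

    def pixels(self, image: ImageField | np.ndarray, cell_id: int,
               channel: str | None = None) -> np.ndarray:
        """Intensities of one cell's pixels, as a flat array."""
        arr = image[channel] if isinstance(image, ImageField) else np.asarray(image)
        if arr.shape != self.label_mask.shape:
            raise FieldError("image and label mask shapes differ")
        sel = arr[self.label_mask == cell_id]
        if sel.size == 0:
            raise FieldError(f"cell {cell_id} labels no pixels")
        return sel

    def row(self, cell_id: int) -> pd.Series:
        hit = self.metadata[self.metadata["cell_id"] == cell_id]
        if hit.empty:
            raise FieldError(f"no metadata for cell {cell_id}")
        return hit.iloc[0]


def write_field(image: ImageField, path: str | Path, scale_to_uint16: bool = True) -> None:
    """Write a field as a multi-page TIFF plus a JSON sidecar.

    Page order follows :data:`CHANNEL_ORDER` for the channels present,
    then any extra channels alphabetically.  Intensities are scaled to
    the 16-bit range; the per-channel scale factor is stored in the
    sidecar so :func:`read_field` can undo it.
    """
    path = Path(path)
    names = [c for c in CHANNEL_ORDER if c in image.channels]
    names += sorted(set(image.channels) - set(names))
    pages, scales = [], {}
    for name in names:
        arr = image.channels[name]
        if scale_to_uint16:
            top = float(arr.max())
            scale = (65535.0 / top) if top > 0 else 1.0
            pages.append(np.round(arr * scale).astype(np.uint16))
        else:
            scale = 1.0
            pages.append(arr.astype(np.float32))
        scales[name] = scale
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    sidecar = {"channels": names, "scales": scales,
               "pixel_size": image.pixel_size}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_field(path: str | Path) -> ImageField:
    """Read a field written by :func:`write_field`.

    Without a sidecar the pages are assigned the default channel order and
    missing roles (e.g. an absent ``marker``) are simply not present;
    callers test with ``"marker" in field``.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        names = sidecar["channels"]
        scales = sidecar.get("scales", {})
        pixel_size = sidecar.get("pixel_size")
    else:
        names = list(CHANNEL_ORDER[: len(stack)])
        scales = {}
        pixel_size = None
    if len(names) != len(stack):
        raise FieldError(
            f"sidecar lists {len(names)} channels but TIFF has {len(stack)} pages"
        )
    channels = {
        name: stack[i].astype(np.float32) / float(scales.get(name, 1.0))
        for i, name in enumerate(names)
    }
    return ImageField(channels=channels, pixel_size=pixel_size)


def write_regions(regions: RegionSet, mask_path: str | Path,
                  metadata_path: str | Path | None = None) -> None:
    """Write the label mask as 16-bit TIFF and metadata as ``cells.csv``."""
    mask = regions.label_mask
    if mask.max() > np.iinfo(np.uint16).max:
        raise FieldError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(Path(mask_path), mask.astype(np.uint16))
    if metadata_path is not None:
        regions.metadata.to_csv(metadata_path, index=False)


def read_regions(mask_path: str | Path,
                 metadata_path: str | Path | None = None) -> RegionSet:
    """Read a label mask TIFF and optional metadata CSV into a RegionSet."""
    mask = tifffile.imread(Path(mask_path)).astype(np.int64)
    if metadata_path is None:
        return RegionSet(label_mask=mask)
    meta = pd.read_csv(metadata_path)
    if "expressing" in meta.columns:
        meta["expressing"] = meta["expressing"].astype(bool)
    return RegionSet(label_mask=mask, metadata=meta)
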