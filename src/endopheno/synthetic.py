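"""Seeded synthetic microscopy fields, flow-cytometry event tables and
sequence fixtures, with ground truth for recovery testing.

The scene generator emulates the statistical structure a transient
transfection imaging experiment hands to the downstream analyses:

* log-normal per-cell total GFP (high- and low-expressing cells in one
  field, plus optional non-expressing cells),
* a tunable fraction ``punctate_fraction`` of each cell's GFP partitioned
  into endosome-like puncta versus diffuse cytoplasm,
* ``distributed`` (scattered) versus ``clustered`` (perinuclear groups)
  puncta arrangements,
* Poisson photon noise followed by Gaussian read noise,
* an endosome-marker channel containing each punctum with probability
  ``marker_coloc_prob``.

Cells are ellipses with a concentric elliptical nucleus; puncta are 2D
Gaussian spots truncated at 3 sigma and renormalised to unit mass inside
the truncation, so with noise off the summed GFP of a cell equals its
drawn expression level up to discretization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, erosion

from .fields import ImageField, RegionSet
from .seqfeat import ProteinRecord

ARRANGEMENTS = ("distributed", "clustered")

#: intensity of the membrane outline and nucleus fill channels
_STAIN_LEVEL = 50.0
#: peak-mass of a marker-channel punctum
_MARKER_AMPLITUDE = 400.0


class PlacementError(RuntimeError):
    """Raised when non-overlapping cells cannot be placed in the field."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic imaging field.

    ``punctate_fraction`` may be a single fraction (all expressing cells
    get construct label ``"FL"``) or a mapping ``{construct: fraction}``;
    with a mapping, expressing cells are assigned constructs cyclically.
    ``include_nonexpressing`` adds that many untransfected cells (zero
    GFP above the pedestal) to the field and the label mask.
    """

    field_shape: tuple[int, int] = (512, 512)
    n_cells: int = 12
    expression_mu: float = 10.0          # log of typical per-cell total GFP
    expression_sigma: float = 0.8        # ~10-fold spread across cells
    punctate_fraction: float | Mapping[str, float] = 0.1
    n_puncta: int = 6
    arrangement: str = "distributed"
    n_cluster_centers: int = 2
    puncta_sigma: float = 1.0            # px
    puncta_min_separation: float = 12.0  # px, distributed arrangement only
    cytoplasm_baseline: float = 2.0      # additive per-cell pedestal
    photon_noise: bool = True
    read_sigma: float = 2.0
    marker_coloc_prob: float = 0.9
    include_nonexpressing: int = 0
    replicate: int = 1
    cell_radius_range: tuple[float, float] = (16.0, 22.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for phi in self.fractions().values():
            if not 0.0 <= phi <= 1.0:
                raise ValueError(f"punctate_fraction {phi} outside [0, 1]")
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"arrangement must be one of {ARRANGEMENTS}")
        if self.n_cluster_centers < 1:
            raise ValueError("n_cluster_centers must be >= 1")
        if self.n_puncta < 0 or self.include_nonexpressing < 0:
            raise ValueError("counts must be nonnegative")
        if self.read_sigma < 0 or self.cytoplasm_baseline < 0:
            raise ValueError("noise and baseline levels must be nonnegative")
        if not 0.0 <= self.marker_coloc_prob <= 1.0:
            raise ValueError("marker_coloc_prob must be a probability")

    def fractions(self) -> dict[str, float]:
        if isinstance(self.punctate_fraction, Mapping):
            return dict(self.punctate_fraction)
        return {"FL": float(self.punctate_fraction)}


@dataclass
class FlowSimSpec:
    """Parameters of a simulated receptor internalization/recycling run.

    Events are emitted for four conditions: ``Total`` (antagonist only),
    ``Internalized`` (agonist only), ``Recycled`` (agonist then
    antagonist) and a non-expressing ``Control`` used for gating.  With
    ``cv=0`` the construction is exact: the expressing-event surface
    geometric means are ``T``, ``T*(1-i)`` and ``I + r*(T-I)``.
    """

    n_events: int = 10_000
    true_internalization: float = 0.4
    true_recycling: float = 0.5
    base_surface_gmean: float = 100.0
    cv: float = 0.3                      # log-normal coefficient of variation
    gfp_expressing_fraction: float = 0.8
    gfp_positive_gmean: float = 1000.0
    gfp_negative_gmean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.true_internalization <= 1.0:
            raise ValueError("true_internalization outside [0, 1]")
        if not 0.0 <= self.true_recycling <= 1.0:
            raise ValueError("true_recycling outside [0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if not 0.0 < self.gfp_expressing_fraction <= 1.0:
            raise ValueError("gfp_expressing_fraction must be in (0, 1]")


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], theta: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _place_cells(spec: SceneSpec, n_total: int, rng: np.random.Generator,
                 max_tries: int = 200):
    """Draw non-overlapping ellipse cells fully inside the field."""
    shape = tuple(spec.field_shape)
    occupied = np.zeros(shape, dtype=bool)
    cells = []
    lo, hi = spec.cell_radius_range
    for _ in range(n_total):
        for attempt in range(max_tries):
            axes = rng.uniform(lo, hi, size=2)
            theta = rng.uniform(0, np.pi)
            margin = axes.max() + 1
            if 2 * margin >= min(shape):
                raise PlacementError("cell radius too large for the field")
            center = (rng.uniform(margin, shape[0] - margin),
                      rng.uniform(margin, shape[1] - margin))
            mask = _ellipse_mask(shape, center, tuple(axes), theta)
            if not (mask & occupied).any():
                occupied |= mask
                cells.append({"center": center, "axes": tuple(axes),
                              "theta": theta, "mask": mask})
                break
        else:
            raise PlacementError(
                f"could not place cell {len(cells) + 1}/{n_total} "
                f"after {max_tries} tries"
            )
    return cells


def _gaussian_kernel(sigma: float) -> np.ndarray:
    """Unit-mass 2D Gaussian truncated at 3 sigma."""
    r = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = yy ** 2 + xx ** 2
    k = np.exp(-d2 / (2 * sigma ** 2))
    k[d2 > (3 * sigma) ** 2] = 0.0
    return k / k.sum()


def _sample_punctum_centers(cell: dict, spec: SceneSpec,
                            rng: np.random.Generator) -> list[tuple[int, int]]:
    """Pixel positions for puncta centers, inside the eroded cell mask."""
    r = int(np.ceil(3 * spec.puncta_sigma))
    allowed = erosion(cell["mask"], disk(r))
    if not allowed.any():
        allowed = cell["mask"]
    coords = np.argwhere(allowed)

    if spec.arrangement == "distributed":
        # scattered puncta: enforce a minimum pairwise separation so the
        # spots render as distinct contiguous structures; relax to the
        # best (farthest-from-chosen) candidate when the cell is too full
        chosen: list[tuple[int, int]] = []
        for _ in range(spec.n_puncta):
            best, best_d = None, -1.0
            for _ in range(150):
                cand = tuple(coords[rng.integers(len(coords))])
                d = min((np.hypot(cand[0] - p[0], cand[1] - p[1])
                         for p in chosen), default=np.inf)
                if d >= spec.puncta_min_separation:
                    best = cand
                    break
                if d > best_d:
                    best, best_d = cand, d
            chosen.append(best)
        return chosen

    # clustered: centers in the perinuclear band (annulus just outside the
    # nucleus), members jittered tightly so each group stays contiguous
    nucleus = _ellipse_mask(tuple(spec.field_shape), cell["center"],
                            tuple(0.45 * a for a in cell["axes"]), cell["theta"])
    band = dilation(nucleus, disk(3)) & ~nucleus & allowed
    band_coords = np.argwhere(band) if band.any() else coords
    k = min(spec.n_cluster_centers, len(band_coords))
    centers = band_coords[rng.choice(len(band_coords), size=k, replace=False)]
    allowed_set = {tuple(c) for c in map(tuple, coords)}
    out: list[tuple[int, int]] = []
    for j in range(spec.n_puncta):
        cy, cx = centers[j % k]
        for _ in range(20):
            p = (int(round(cy + rng.normal(0, 1.0))),
                 int(round(cx + rng.normal(0, 1.0))))
            if p in allowed_set:
                out.append(p)
                break
        else:
            out.append((int(cy), int(cx)))
    return out


def _add_spot(img: np.ndarray, center: tuple[int, int], kernel: np.ndarray,
              amplitude: float) -> None:
    r = kernel.shape[0] // 2
    y, x = center
    y0, y1 = y - r, y + r + 1
    x0, x1 = x - r, x + r + 1
    ky0, kx0 = max(0, -y0), max(0, -x0)
    y0, x0 = max(0, y0), max(0, x0)
    y1, x1 = min(img.shape[0], y1), min(img.shape[1], x1)
    img[y0:y1, x0:x1] += amplitude * kernel[ky0:ky0 + (y1 - y0),
                                            kx0:kx0 + (x1 - x0)]


def simulate_field(spec: SceneSpec) -> tuple[ImageField, RegionSet, pd.DataFrame]:
    """Render one synthetic field.

    Returns the image (channels ``gfp``, ``membrane``, ``dna``,
    ``marker``), the label mask with metadata, and a ground-truth table
    with one row per cell: ``cell_id``, ``construct``, ``replicate``,
    ``punctate_fraction``, ``arrangement``, ``structure_count``,
    ``expressing`` and the drawn ``expression`` level.  Deterministic for
    a fixed spec (``spec.seed`` seeds every random draw).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.field_shape)
    fractions = spec.fractions()
    construct_names = list(fractions)
    n_total = spec.n_cells + spec.include_nonexpressing
    cells = _place_cells(spec, n_total, rng)

    gfp = np.zeros(shape, dtype=np.float64)
    membrane = np.zeros(shape, dtype=np.float64)
    dna = np.zeros(shape, dtype=np.float64)
    marker = np.zeros(shape, dtype=np.float64)
    label_mask = np.zeros(shape, dtype=np.int32)
    kernel = _gaussian_kernel(spec.puncta_sigma)

    truth_rows = []
    for i, cell in enumerate(cells):
        cell_id = i + 1
        mask = cell["mask"]
        label_mask[mask] = cell_id
        expressing = i < spec.n_cells
        construct = (construct_names[i % len(construct_names)]
                     if expressing else "untransfected")
        phi = fractions[construct] if expressing else 0.0
        expression = (float(rng.lognormal(spec.expression_mu,
                                          spec.expression_sigma))
                      if expressing else 0.0)

        area = int(mask.sum())
        gfp[mask] += spec.cytoplasm_baseline + (1.0 - phi) * expression / area

        puncta_img = np.zeros(shape, dtype=np.float64)
        n_spots = spec.n_puncta if (expressing and phi > 0) else 0
        if n_spots:
            centers = _sample_punctum_centers(cell, spec, rng)
            amp = phi * expression / n_spots
            for c in centers:
                _add_spot(puncta_img, c, kernel, amp)
                if rng.uniform() < spec.marker_coloc_prob:
                    _add_spot(marker, c, kernel, _MARKER_AMPLITUDE)
        gfp += puncta_img
        structure_count = int(cc_label(puncta_img > 0, connectivity=2).max())

        outline = mask & ~erosion(mask, disk(1))
        membrane[outline] += _STAIN_LEVEL
        nucleus = _ellipse_mask(shape, cell["center"],
                                tuple(0.45 * a for a in cell["axes"]),
                                cell["theta"])
        dna[nucleus] += _STAIN_LEVEL

        truth_rows.append({
            "cell_id": cell_id, "construct": construct,
            "replicate": spec.replicate, "punctate_fraction": phi,
            "arrangement": spec.arrangement if n_spots else "none",
            "structure_count": structure_count, "expressing": expressing,
            "expression": expression,
        })

    channels = {}
    for name, img in (("gfp", gfp), ("membrane", membrane),
                      ("dna", dna), ("marker", marker)):
        out = img
        if spec.photon_noise:
            out = rng.poisson(out).astype(np.float64)
        if spec.read_sigma > 0:
            out = out + rng.normal(0.0, spec.read_sigma, size=shape)
        channels[name] = np.clip(out, 0.0, None).astype(np.float32)

    truth = pd.DataFrame(truth_rows)
    metadata = truth[["cell_id", "construct", "replicate", "expressing"]].copy()
    regions = RegionSet(label_mask=label_mask, metadata=metadata)
    return ImageField(channels=channels), regions, truth


def simulate_experiment(
    fractions: Mapping[str, float],
    n_replicates: int = 3,
    cells_per_replicate: int = 30,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[list[tuple[ImageField, RegionSet, pd.DataFrame]], pd.DataFrame]:
    """Simulate a multi-construct, multi-replicate imaging experiment.

    One field is rendered per (replicate) with all constructs mixed in the
    field, mirroring a transfection experiment imaged over biological
    replicates.  Returns the per-replicate field triples and the
    concatenated ground truth (cell ids made globally unique).
    """
    out, truths = [], []
    offset = 0
    for rep in range(1, n_replicates + 1):
        spec = SceneSpec(punctate_fraction=dict(fractions),
                         n_cells=cells_per_replicate, replicate=rep,
                         seed=seed + rep, **spec_kwargs)
        fieldset = simulate_field(spec)
        image, regions, truth = fieldset
        truth = truth.copy()
        truth["cell_id"] += offset
        regions.metadata["cell_id"] += offset
        relabel = regions.label_mask.copy()
        relabel[relabel > 0] += offset
        regions = RegionSet(label_mask=relabel, metadata=regions.metadata)
        offset = int(truth["cell_id"].max())
        out.append((image, regions, truth))
        truths.append(truth)
    return out, pd.concat(truths, ignore_index=True)


def simulate_flow(spec: FlowSimSpec) -> pd.DataFrame:
    """Simulate one internalization/recycling flow run.

    Returns an event table with columns ``event_id``, ``condition``,
    ``gfp`` and ``surface``.  Expressing events carry the condition's
    surface level; non-expressing events (and all ``Control`` events)
    always sit at the untreated surface level, so failing to gate them
    out biases the estimators — exactly the situation expression gating
    guards against.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.base_surface_gmean
    i, r = spec.true_internalization, spec.true_recycling
    internalized = T * (1.0 - i)
    recycled = internalized + r * (T - internalized)
    sigma = float(np.sqrt(np.log1p(spec.cv ** 2)))

    def lognoise(n: int) -> np.ndarray:
        if sigma == 0.0:
            return np.ones(n)
        return np.exp(rng.normal(0.0, sigma, size=n))

    rows = []
    condition_levels = {"Total": T, "Internalized": internalized,
                        "Recycled": recycled}
    for cond, level in condition_levels.items():
        n_pos = int(round(spec.n_events * spec.gfp_expressing_fraction))
        n_neg = spec.n_events - n_pos
        gfp = np.concatenate([
            spec.gfp_positive_gmean * lognoise(n_pos),
            spec.gfp_negative_gmean * lognoise(n_neg),
        ])
        surface = np.concatenate([
            level * lognoise(n_pos),
            T * lognoise(n_neg),
        ])
        rows.append(pd.DataFrame({"condition": cond, "gfp": gfp,
                                  "surface": surface}))
    rows.append(pd.DataFrame({
        "condition": "Control",
        "gfp": spec.gfp_negative_gmean * lognoise(spec.n_events),
        "surface": T * lognoise(spec.n_events),
    }))
    events = pd.concat(rows, ignore_index=True)
    events.insert(0, "event_id", np.arange(len(events)))
    return events


# --- packaged sequence fixtures -------------------------------------------

# Synthetic stand-in for the human DNAJC13 record (UniProt O75165), which is
# deliberately not bundled.  The stand-in has the documented coarse anatomy:
# total length 2243, a C-terminal 45-mer (residues 2199-2243) carrying YLT
# motifs starting at 2206 and 2215 and exactly 13 phospho-capable (S/T/Y)
# residues (29% of 45).  Everything upstream is tyrosine-free filler, so the
# first YLT match in the full record is at 2206.  It is a synthetic sequence
# for exercising the machinery, not the real protein.
_SYNTHETIC_CTERM45 = "GPENQDRYLTSPRGEDYLTAQSFTDNKSGELYPRTMSNQDVSEHT"
_FILLER_UNIT = "ADLGKPEQNRVH"          # no Y: cannot create an upstream YLT
_SYNTHETIC_FULL = (_FILLER_UNIT * 184)[:2198] + _SYNTHETIC_CTERM45

_FIXTURES = {
    "toy6": "MKYLTQ",
    "allala": "A" * 45,
    "ylt_pair": "YLTQYLT",
    "O75165_SYNTHETIC": _SYNTHETIC_FULL,
}


def sequence_fixtures() -> list[ProteinRecord]:
    """Packaged toy protein sequences of known composition (no downloads).

    Includes ``toy6`` (a 6-mer), ``allala`` (poly-Ala 45-mer with zero
    phospho-capable residues), ``ylt_pair`` (two overlapping-scan YLT
    hits) and ``O75165_SYNTHETIC``, a synthetic full-length stand-in whose
    C-terminal 45 residues satisfy the documented worked values.
    """
    return [ProteinRecord(id=k, sequence=v) for k, v in _FIXTURES.items()]


def get_fixture(name: str) -> ProteinRecord:
    try:
        return ProteinRecord(id=name, sequence=_FIXTURES[name])
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
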