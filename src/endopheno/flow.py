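"""Flow-cytometry expression gating and receptor trafficking estimators.

A surface-labeling internalization/recycling assay compares the
geometric mean of surface-receptor fluorescence across three treatment
conditions: ``Total`` (antagonist only — all receptor on the surface),
``Internalized`` (agonist only — receptor driven inside), and
``Recycled`` (agonist then antagonist — receptor allowed to return).
Events are first gated for transfected-protein expression against a
non-expressing ``Control`` population, then summarized as

* internalization fraction = 1 - Internalized/Total
* recycling fraction = (Recycled - Internalized)/(Total - Internalized)

Geometric means are the standard summary for log-normally distributed
cytometry intensities; nonpositive values are excluded (with a logged
count) rather than offset, since offsets distort the geometric mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("Total", "Internalized", "Recycled", "Control")


@dataclass(frozen=True)
class GateSpec:
    """Expression gate: keep events whose ``channel`` intensity strictly
    exceeds the ``control_percentile`` of the control population."""

    control_percentile: float = 99.0
    channel: str = "gfp"

    def __post_init__(self) -> None:
        if not 50.0 < self.control_percentile < 100.0:
            raise ValueError("control_percentile must lie in (50, 100)")


def geometric_mean(values) -> tuple[float, int]:
    """exp(mean(log v)) over positive values.

    Returns ``(gmean, n_excluded)`` where ``n_excluded`` counts the
    nonpositive values dropped (also logged).  Raises if no positive
    value remains.
    """
    v = np.asarray(values, dtype=float)
    if v.size and not np.isfinite(v).all():
        raise ValueError("non-finite intensities")
    pos = v[v > 0]
    excluded = int(v.size - pos.size)
    if excluded:
        logger.info("geometric mean: excluded %d nonpositive value(s)", excluded)
    if pos.size == 0:
        raise ValueError("no positive values for geometric mean")
    return float(np.exp(np.mean(np.log(pos)))), excluded


def gate_expressing(events: pd.DataFrame, control: pd.DataFrame,
                    gate: GateSpec = GateSpec()) -> tuple[pd.DataFrame, float]:
    """Expression-gate an event table against a non-expressing control.

    The threshold is the ``control_percentile`` (linear interpolation) of
    the control's gate channel; kept events satisfy a strict ``>``.
    Returns ``(gated_events, threshold)``.
    """
    if control.empty:
        raise ValueError("control population is empty")
    threshold = float(np.percentile(control[gate.channel].to_numpy(dtype=float),
                                    gate.control_percentile))
    kept = events[events[gate.channel] > threshold].copy()
    if kept.empty:
        logger.warning("expression gate at %.3g removed every event", threshold)
    return kept, threshold


def internalization(total_gmean: float, internalized_gmean: float
                    ) -> tuple[float, bool]:
    """Internalized receptor fraction, 1 - Internalized/Total.

    Returns ``(fraction, in_range)``; values outside [0, 1] are returned
    with the flag set False rather than clipped.
    """
    if total_gmean <= 0:
        raise ValueError("Total geometric mean must be positive")
    frac = 1.0 - internalized_gmean / total_gmean
    return frac, 0.0 <= frac <= 1.0


def recycling(total_gmean: float, internalized_gmean: float,
              recycled_gmean: float) -> tuple[float, bool]:
    """Recycled receptor fraction, (Recycled - Internalized)/(Total - Internalized)."""
    if total_gmean == internalized_gmean:
        raise ZeroDivisionError(
            "Total equals Internalized (no internalization): "
            "recycling fraction is undefined"
        )
    frac = (recycled_gmean - internalized_gmean) / (total_gmean - internalized_gmean)
    return frac, 0.0 <= frac <= 1.0


@dataclass
class FlowConditionSummary:
    """Per-condition geometric means and the derived trafficking fractions."""

    gmeans: dict[str, float]
    internalization: float
    recycling: float
    internalization_in_range: bool
    recycling_in_range: bool
    gate_threshold: float
    n_gated: dict[str, int]
    n_excluded: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gmeans": self.gmeans,
            "internalization": self.internalization,
            "recycling": self.recycling,
            "internalization_in_range": self.internalization_in_range,
            "recycling_in_range": self.recycling_in_range,
            "gate_threshold": self.gate_threshold,
            "n_gated": self.n_gated,
            "n_excluded": self.n_excluded,
        }


def summarize_conditions(events: pd.DataFrame,
                         gate: GateSpec = GateSpec(),
                         control_condition: str = "Control"
                         ) -> FlowConditionSummary:
    """Full trafficking readout from an event table.

    ``events`` needs columns ``condition``, ``gfp`` and ``surface`` with
    conditions drawn from ``Total``/``Internalized``/``Recycled`` plus
    the control.  Events of the three assay conditions are expression-
    gated against the control, surface geometric means are computed per
    condition, and the internalization and recycling fractions derived.
    """
    bad = set(events["condition"].unique()) - set(CONDITIONS) - {control_condition}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    control = events[events["condition"] == control_condition]
    gmeans, n_gated, n_excluded = {}, {}, {}
    threshold = None
    for cond in ("Total", "Internalized", "Recycled"):
        subset = events[events["condition"] == cond]
        if subset.empty:
            raise ValueError(f"no events for condition {cond!r}")
        gated, threshold = gate_expressing(subset, control, gate)
        gmeans[cond], n_excluded[cond] = geometric_mean(gated["surface"])
        n_gated[cond] = len(gated)
    i_frac, i_ok = internalization(gmeans["Total"], gmeans["Internalized"])
    r_frac, r_ok = recycling(gmeans["Total"], gmeans["Internalized"],
                             gmeans["Recycled"])
    return FlowConditionSummary(
        gmeans=gmeans, internalization=i_frac, recycling=r_frac,
        internalization_in_range=i_ok, recycling_in_range=r_ok,
        gate_threshold=float(threshold), n_gated=n_gated,
        n_excluded=n_excluded,
    )
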