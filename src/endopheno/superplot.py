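"""Replicate-aware (SuperPlot) statistics.

Per-cell measurements from imaging experiments are hierarchical: cells
are nested in biological replicates, and treating cells as independent
pseudo-replicates inflates significance.  Following the SuperPlot
prescription, every statistical test here consumes only the arithmetic
mean of each (construct, replicate) group; cell-level values are kept
for plotting and export only.

Supported designs mirror the comparisons common in this field:

* ``paired_t_two_tailed`` — two constructs measured in the same
  replicates;
* ``paired_anova_dunnett`` — repeated-measures one-way ANOVA with
  Dunnett's many-to-one adjustment against a reference construct;
* ``paired_anova_tukey`` — repeated-measures ANOVA with Tukey all-pairs
  adjustment (studentized-range);
* ``unpaired_anova_dunnett`` — ordinary one-way ANOVA Dunnett
  (delegates to :func:`scipy.stats.dunnett`).

The paired Dunnett adjustment is computed from the equicorrelated
(rho = 1/2) multivariate-t rectangle probability by deterministic
quadrature, using the repeated-measures error mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import gammaln

DESIGNS = ("paired_t_two_tailed", "paired_anova_dunnett",
           "paired_anova_tukey", "unpaired_anova_dunnett")

SIGNIFICANCE_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                      (5e-2, "*"))


class DegenerateComparisonError(ValueError):
    """Raised when a test statistic is undefined (e.g. zero variance of
    paired differences) instead of returning a silent p-value."""


def annotate(p: float) -> str:
    """Significance band for a p-value: ns / * / ** / *** / ****.

    Boundaries are inclusive: p = 0.05 earns ``*``, p = 0.051 is ``ns``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for cutoff, band in SIGNIFICANCE_BANDS:
        if p <= cutoff:
            return band
    return "ns"


def replicate_means(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Arithmetic mean of cell values within each construct x replicate.

    ``table`` needs columns ``construct``, ``replicate`` and the value
    column.  Downstream tests see only these means.
    """
    if table.empty:
        raise ValueError("empty observation table")
    for col in ("construct", "replicate", value):
        if col not in table.columns:
            raise ValueError(f"observation table lacks column {col!r}")
    vals = pd.to_numeric(table[value])
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in observation table")
    out = (table.assign(**{value: vals})
           .groupby(["construct", "replicate"], sort=True)[value]
           .mean().rename("mean").reset_index())
    return out


def superplot_frame(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Cell rows plus replicate-mean rows, tagged for SuperPlot export."""
    cells = table.copy()
    cells["kind"] = "cell"
    means = replicate_means(table, value=value).rename(columns={"mean": value})
    means["kind"] = "replicate_mean"
    return pd.concat([cells, means], ignore_index=True)


def _pivot_paired(means: pd.DataFrame, groups: list[str]) -> np.ndarray:
    """Rows = replicates, columns = groups; requires a complete design."""
    wide = means.pivot(index="replicate", columns="construct", values="mean")
    missing = [g for g in groups if g not in wide.columns]
    if missing:
        raise ValueError(f"groups absent from means table: {missing}")
    wide = wide[groups]
    if wide.isna().any().any():
        raise ValueError("paired design requires equal replicate ids "
                         "across groups")
    if len(wide) < 2:
        raise ValueError("need >= 2 replicates for nonzero degrees of freedom")
    return wide.to_numpy(dtype=float)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test; returns (t, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and equal-length")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateComparisonError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), len(d) - 1)
    return float(t), float(p)


def _rm_anova(data: np.ndarray) -> tuple[float, float, int, float]:
    """One-way repeated-measures ANOVA on a (replicates x groups) array.

    Returns (F, p, df_error, mse) where mse is the subject-by-treatment
    interaction mean square used as the error term.
    """
    n, k = data.shape
    grand = data.mean()
    group_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_treat = n * ((group_means - grand) ** 2).sum()
    resid = data - group_means[None, :] - subj_means[:, None] + grand
    ss_err = (resid ** 2).sum()
    df_treat, df_err = k - 1, (k - 1) * (n - 1)
    if ss_err == 0:
        raise DegenerateComparisonError("zero error variance in RM-ANOVA")
    ms_treat, mse = ss_treat / df_treat, ss_err / df_err
    F = ms_treat / mse
    return float(F), float(stats.f.sf(F, df_treat, df_err)), df_err, float(mse)


def _mvt_rectangle(q: float, k: int, df: int) -> float:
    """P(max_j |T_j| <= q) for k equicorrelated (rho=1/2) multivariate-t
    variates with ``df`` degrees of freedom (Dunnett two-sided kernel).

    Uses the factor representation T_j = (Z_j + Z_0)/(sqrt(2) S):
    Gauss-Hermite over the shared factor, adaptive quadrature over the
    chi-distributed scale.
    """
    if q <= 0:
        return 0.0
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(120)
    norm = stats.norm

    def inner(s: float) -> float:
        hw = q * s * np.sqrt(2.0)
        probs = norm.cdf(hw - gh_x) - norm.cdf(-hw - gh_x)
        return float(np.dot(gh_w, probs ** k)) / np.sqrt(2.0 * np.pi)

    # chi density of S = sqrt(V/df), V ~ chi^2_df
    log_norm = np.log(2.0) + (df / 2.0) * np.log(df / 2.0) - gammaln(df / 2.0)

    def integrand(s: float) -> float:
        return np.exp(log_norm + (df - 1) * np.log(s) - df * s * s / 2.0) \
            * inner(s)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return min(max(val, 0.0), 1.0)


def dunnett_paired(data: np.ndarray, groups: list[str],
                   reference: str) -> pd.DataFrame:
    """Many-to-one comparisons on a repeated-measures design.

    ``data`` is (replicates x groups) of replicate means.  Statistics use
    the RM-ANOVA error mean square; adjusted p-values come from the
    two-sided equicorrelated multivariate-t distribution.
    """
    n, k = data.shape
    _, _, df_err, mse = _rm_anova(data)
    ref_idx = groups.index(reference)
    se = np.sqrt(2.0 * mse / n)
    rows = []
    for j, g in enumerate(groups):
        if j == ref_idx:
            continue
        t = (data[:, j].mean() - data[:, ref_idx].mean()) / se
        p_adj = 1.0 - _mvt_rectangle(abs(t), k - 1, df_err)
        rows.append({"group": g, "reference": reference, "statistic": t,
                     "p_adj": p_adj, "band": annotate(p_adj)})
    return pd.DataFrame(rows)


def tukey_paired(data: np.ndarray, groups: list[str]) -> pd.DataFrame:
    """All-pairs comparisons on a repeated-measures design, adjusted with
    the studentized range (Tukey HSD on the RM-ANOVA error term)."""
    n, k = data.shape
    _, _, df_err, mse = _rm_anova(data)
    se = np.sqrt(mse / n)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = data[:, a].mean() - data[:, b].mean()
            qstat = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(qstat, k, df_err))
            rows.append({"group_a": groups[a], "group_b": groups[b],
                         "statistic": diff / (se * np.sqrt(2.0)),
                         "p_adj": p_adj, "band": annotate(p_adj)})
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Outcome of a replicate-means comparison.

    ``comparisons`` has one row per comparison with the statistic,
    adjusted p and significance band; ``anova`` carries the omnibus
    (F, p) when a design computes one.
    """

    design: str
    comparisons: pd.DataFrame
    reference: str | None = None
    anova: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        out = {"design": self.design, "reference": self.reference,
               "comparisons": self.comparisons.to_dict(orient="records")}
        if self.anova is not None:
            out["anova_F"], out["anova_p"] = self.anova
        return out


def compare(means: pd.DataFrame, design: str,
            reference: str | None = None) -> ComparisonResult:
    """Run the requested design on a replicate-means table.

    ``means`` has columns ``construct``, ``replicate``, ``mean`` (as
    produced by :func:`replicate_means`).  Paired designs require the
    same replicate ids in every group.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    groups = sorted(means["construct"].unique())
    if reference is not None and reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups {groups}")

    if design == "paired_t_two_tailed":
        if len(groups) != 2:
            raise ValueError("paired t-test needs exactly two groups")
        data = _pivot_paired(means, groups)
        t, p = paired_t(data[:, 0], data[:, 1])
        comp = pd.DataFrame([{"group_a": groups[0], "group_b": groups[1],
                              "statistic": t, "p_adj": p,
                              "band": annotate(p)}])
        return ComparisonResult(design=design, comparisons=comp)

    if design == "paired_anova_dunnett":
        if reference is None:
            raise ValueError("Dunnett designs need a reference group")
        data = _pivot_paired(means, groups)
        F, p, _, _ = _rm_anova(data)
        comp = dunnett_paired(data, groups, reference)
        return ComparisonResult(design=design, comparisons=comp,
                                reference=reference, anova=(F, p))

    if design == "paired_anova_tukey":
        data = _pivot_paired(means, groups)
        F, p, _, _ = _rm_anova(data)
        comp = tukey_paired(data, groups)
        return ComparisonResult(design=design, comparisons=comp,
                                anova=(F, p))

    # unpaired_anova_dunnett
    if reference is None:
        raise ValueError("Dunnett designs need a reference group")
    samples = [means.loc[means["construct"] == g, "mean"].to_numpy()
               for g in groups if g != reference]
    control = means.loc[means["construct"] == reference, "mean"].to_numpy()
    res = stats.dunnett(*samples, control=control)
    others = [g for g in groups if g != reference]
    comp = pd.DataFrame({
        "group": others, "reference": reference,
        "statistic": res.statistic, "p_adj": res.pvalue,
        "band": [annotate(p) for p in res.pvalue],
    })
    return ComparisonResult(design=design, comparisons=comp,
                            reference=reference)


def fold_change(means: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Fold of each construct's score over the reference construct.

    The default convention is the ratio of means: mean of the construct's
    replicate means divided by the mean of the reference's replicate
    means (exactly 1 for the reference itself).  For complete paired
    designs the mean of per-replicate ratios is reported alongside.
    """
    groups = sorted(means["construct"].unique())
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups {groups}")
    grand = means.groupby("construct")["mean"].mean()
    rows = []
    wide = means.pivot(index="replicate", columns="construct", values="mean")
    complete = not wide.isna().any().any()
    for g in groups:
        row = {"construct": g,
               "fold_ratio_of_means": grand[g] / grand[reference]}
        if complete:
            row["fold_mean_of_ratios"] = float(
                (wide[g] / wide[reference]).mean())
        rows.append(row)
    return pd.DataFrame(rows)
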