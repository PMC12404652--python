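"""Replicate-means statistics: paired t, Dunnett, Tukey, bands, folds."""

import numpy as np
import pandas as pd
import pytest

from endopheno import (
    DegenerateComparisonError,
    annotate,
    compare,
    fold_change,
    paired_t,
    replicate_means,
    superplot_frame,
)
from endopheno.superplot import _mvt_rectangle, _rm_anova


def _obs(groups):
    rows = []
    cid = 0
    for construct, reps in groups.items():
        for rep, values in enumerate(reps, start=1):
            for v in values:
                cid += 1
                rows.append({"cell_id": cid, "construct": construct,
                             "replicate": rep, "value": float(v)})
    return pd.DataFrame(rows)


class TestReplicateMeans:
    def test_simple_mean(self):
        table = _obs({"FL": [[2, 4, 6]]})
        out = replicate_means(table)
        assert out.loc[0, "mean"] == 4.0

    def test_tests_consume_means_only(self):
        base = _obs({"A": [[1, 3], [2, 4], [3, 5]],
                     "B": [[2], [3.5], [4]]})
        # add cells to A's replicate 1 that keep its mean at 2
        extra = _obs({"A": [[0, 4]]})
        extra["cell_id"] += 100
        res_a = compare(replicate_means(base), "paired_t_two_tailed")
        res_b = compare(replicate_means(pd.concat([base, extra])),
                        "paired_t_two_tailed")
        assert (res_a.comparisons["statistic"].iloc[0]
                == pytest.approx(res_b.comparisons["statistic"].iloc[0]))

    def test_single_cell_replicate_passes_through(self):
        out = replicate_means(_obs({"FL": [[7.5]]}))
        assert out.loc[0, "mean"] == 7.5

    def test_permuting_cells_changes_nothing(self):
        table = _obs({"A": [[1, 5, 2], [4, 1, 3]], "B": [[2, 2], [5, 1]]})
        shuffled = table.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(replicate_means(table),
                                      replicate_means(shuffled))


class TestPairedT:
    def test_closed_form_n3_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([1.5, 3.1, 3.9])
        d = a - b
        oracle_t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t, p = paired_t(a, b)
        assert t == pytest.approx(oracle_t, abs=1e-12)
        assert 0 < p < 1

    def test_swapping_groups_negates_t_keeps_p(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.5, 5.0])
        t_ab, p_ab = paired_t(a, b)
        t_ba, p_ba = paired_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_variance_differences_raise(self):
        with pytest.raises(DegenerateComparisonError):
            paired_t(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))

    def test_type_one_error_is_nominal(self):
        # 5000 null experiments of 3 paired replicates
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(5000):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            _, p = paired_t(a, b)
            rejections += p <= 0.05
        assert rejections / 5000 == pytest.approx(0.05, abs=0.02)


class TestDunnettPaired:
    def test_rectangle_probability_matches_multivariate_t_reference(self):
        # references computed with mvtnorm::pmvt (equicorrelated rho=1/2)
        assert 1 - _mvt_rectangle(1.5, 2, 4) == pytest.approx(0.32728758,
                                                              abs=1e-3)
        assert 1 - _mvt_rectangle(3.0, 2, 4) == pytest.approx(0.06701079,
                                                              abs=1e-3)
        assert 1 - _mvt_rectangle(2.5, 3, 8) == pytest.approx(0.08786218,
                                                              abs=1e-3)

    def test_two_group_degeneracy_reduces_to_paired_t(self):
        means = replicate_means(_obs({
            "FL": [[1.0], [2.0], [3.0], [2.5]],
            "mut": [[2.0], [4.1], [4.0], [3.6]],
        }))
        res = compare(means, "paired_anova_dunnett", reference="FL")
        wide = means.pivot(index="replicate", columns="construct",
                           values="mean")
        t_ref, p_ref = paired_t(wide["mut"].to_numpy(),
                                wide["FL"].to_numpy())
        row = res.comparisons.iloc[0]
        assert row["statistic"] == pytest.approx(t_ref, abs=1e-10)
        assert row["p_adj"] == pytest.approx(p_ref, abs=1e-6)

    def test_three_group_dunnett_orders_and_bounds(self):
        means = replicate_means(_obs({
            "FL": [[1.0], [1.2], [0.9]],
            "m1": [[4.0], [4.4], [3.8]],
            "m2": [[1.1], [1.3], [1.0]],
        }))
        res = compare(means, "paired_anova_dunnett", reference="FL")
        comp = res.comparisons.set_index("group")
        assert comp.loc["m1", "p_adj"] < comp.loc["m2", "p_adj"]
        assert ((comp["p_adj"] >= 0) & (comp["p_adj"] <= 1)).all()
        # adjusted p is never smaller than the unadjusted marginal p
        for g in ("m1", "m2"):
            t = abs(comp.loc[g, "statistic"])
            marginal = 1 - _mvt_rectangle(t, 1, 4)
            assert comp.loc[g, "p_adj"] >= marginal - 1e-12


class TestTukeyPaired:
    def test_studentized_range_reference(self):
        # references computed with R ptukey
        from scipy.stats import studentized_range
        assert studentized_range.sf(4.0, 3, 4) == pytest.approx(0.09834062,
                                                                abs=1e-6)
        assert studentized_range.sf(3.2, 4, 6) == pytest.approx(0.20903264,
                                                                abs=1e-6)

    def test_all_pairs_emitted(self):
        means = replicate_means(_obs({
            "a": [[1.0], [2.0], [1.5]],
            "b": [[2.0], [3.0], [2.5]],
            "c": [[1.1], [2.2], [1.4]],
        }))
        res = compare(means, "paired_anova_tukey")
        assert len(res.comparisons) == 3
        assert res.anova is not None and res.anova[0] > 0


class TestUnpairedDunnett:
    def test_runs_and_bounds(self):
        means = replicate_means(_obs({
            "FL": [[1.0], [1.5], [0.8], [1.2]],
            "mut": [[3.0], [3.5], [2.8], [3.3]],
        }))
        res = compare(means, "unpaired_anova_dunnett", reference="FL")
        assert len(res.comparisons) == 1
        assert 0 <= res.comparisons["p_adj"].iloc[0] <= 1


class TestAnnotate:
    @pytest.mark.parametrize("p,band", [
        (0.05, "*"), (0.051, "ns"), (0.3, "ns"),
        (0.01, "**"), (0.0101, "*"),
        (0.001, "***"), (0.0011, "**"),
        (0.0001, "****"), (0.00005, "****"), (0.00011, "***"),
    ])
    def test_band_boundaries_are_inclusive(self, p, band):
        assert annotate(p) == band

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            annotate(1.5)


class TestFoldChange:
    def test_reference_fold_is_one(self):
        means = replicate_means(_obs({
            "FL": [[1.0], [2.0]], "mut": [[4.0], [6.0]],
        }))
        out = fold_change(means, "FL").set_index("construct")
        assert out.loc["FL", "fold_ratio_of_means"] == 1.0
        assert out.loc["mut", "fold_ratio_of_means"] == pytest.approx(10 / 3)
        # paired convention reported alongside
        assert out.loc["mut", "fold_mean_of_ratios"] == pytest.approx(3.5)


def test_superplot_frame_tags_cells_and_means():
    table = _obs({"FL": [[1, 3], [2, 4]]})
    frame = superplot_frame(table)
    assert (frame["kind"] == "replicate_mean").sum() == 2
    assert (frame["kind"] == "cell").sum() == 4


def test_rm_anova_zero_error_raises():
    data = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
    with pytest.raises(DegenerateComparisonError):
        _rm_anova(data)
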