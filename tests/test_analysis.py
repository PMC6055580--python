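import numpy as np
import pandas as pd
import pytest
from scipy import stats

from daphnia_ifd.analysis import (
    AnalysisError,
    bonferroni_alpha,
    compare_groups,
    density_regression,
    mean_depth,
    run_comparison_battery,
)


class TestMeanDepth:
    def test_uniform_is_half_depth(self, column):
        assert mean_depth(np.full(10, 0.1), column) == pytest.approx(0.5)

    def test_extreme_sectors(self, column):
        top = np.zeros(10)
        top[0] = 1.0
        assert mean_depth(top, column) == pytest.approx(0.05)
        bottom = np.zeros(10)
        bottom[-1] = 1.0
        assert mean_depth(bottom, column) == pytest.approx(0.95)

    def test_consistent_permutation_invariance(self, column):
        rng = np.random.default_rng(0)
        frac = rng.dirichlet(np.ones(10))
        direct = mean_depth(frac, column)
        perm = rng.permutation(10)
        permuted = float(frac[perm] @ column.midpoints[perm])
        assert permuted == pytest.approx(direct)

    def test_bad_fractions_rejected(self, column):
        with pytest.raises(AnalysisError):
            mean_depth(np.full(10, 0.2), column)


def _records(slope, intercept, densities, noise_sd=0.0, seed=0, **labels):
    rng = np.random.default_rng(seed)
    d = np.asarray(densities, dtype=float)
    depth = intercept + slope * d + rng.normal(0, noise_sd, len(d))
    out = pd.DataFrame({"density": d, "mean_depth": depth})
    for k, v in labels.items():
        out[k] = v
    return out


class TestDensityRegression:
    def test_exact_on_collinear_records(self):
        rec = _records(0.004, 0.21, [1, 5, 10, 20, 40])
        fit = density_regression(rec)
        assert fit.slope == pytest.approx(0.004)
        assert fit.intercept == pytest.approx(0.21)
        assert fit.r_squared == pytest.approx(1.0)

    def test_translation_changes_only_intercept(self):
        rec = _records(0.003, 0.2, [1, 4, 9, 30], noise_sd=0.01, seed=1)
        shifted = rec.copy()
        shifted["mean_depth"] += 0.1
        a, b = density_regression(rec), density_regression(shifted)
        assert b.slope == pytest.approx(a.slope)
        assert b.intercept == pytest.approx(a.intercept + 0.1)

    def test_null_slope_ci_covers_zero(self):
        rec = _records(0.0, 0.5, np.linspace(1, 60, 24), noise_sd=0.03, seed=3)
        fit = density_regression(rec)
        assert abs(fit.slope) < 2.5 * fit.slope_se

    def test_degenerate_rejected(self):
        with pytest.raises(AnalysisError):
            density_regression(_records(0, 0.5, [5, 5, 5]))


class TestCompareGroups:
    def test_identical_groups_zero_f(self):
        base = _records(0.002, 0.3, np.linspace(1, 60, 12), noise_sd=0.02,
                        seed=5)
        a = base.assign(group="x")
        b = base.assign(group="y")
        res = compare_groups(pd.concat([a, b]), "group")
        assert res.slope_F == pytest.approx(0.0, abs=1e-9)
        assert res.intercept_F == pytest.approx(0.0, abs=1e-9)
        assert res.intercept_reported

    def test_intercept_offset_detected_with_common_slope(self):
        d = np.linspace(1, 60, 15)
        a = _records(0.002, 0.30, d, noise_sd=0.01, seed=1, group="x")
        b = _records(0.002, 0.45, d, noise_sd=0.01, seed=2, group="y")
        res = compare_groups(pd.concat([a, b]), "group")
        assert res.slope_p > 0.05
        assert res.intercept_reported
        assert res.intercept_p < 0.001

    def test_slope_difference_suppresses_intercept_report(self):
        d = np.linspace(1, 60, 15)
        a = _records(0.001, 0.30, d, noise_sd=0.005, seed=1, group="x")
        b = _records(0.008, 0.30, d, noise_sd=0.005, seed=2, group="y")
        res = compare_groups(pd.concat([a, b]), "group")
        assert res.slope_p < 0.05
        assert not res.intercept_reported

    def test_null_permutation_p_values_uniform(self):
        rng = np.random.default_rng(8)
        d = np.tile(np.linspace(1, 60, 10), 2)
        depth = 0.3 + 0.002 * d + rng.normal(0, 0.02, len(d))
        rec = pd.DataFrame({"density": d, "mean_depth": depth})
        pvals = []
        for _ in range(200):
            rec["group"] = rng.permutation(
                np.repeat(["x", "y"], len(d) // 2)
            )
            pvals.append(compare_groups(rec, "group").intercept_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_requires_two_levels(self):
        rec = _records(0.001, 0.3, [1, 5, 9], group="only")
        with pytest.raises(AnalysisError):
            compare_groups(rec, "group")


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 12, 0.00417), (0.05, 4, 0.0125), (0.03, 1, 0.03)]
    )
    def test_printed_levels(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == expected

    def test_invalid_inputs(self):
        with pytest.raises(AnalysisError):
            bonferroni_alpha(1.5, 4)
        with pytest.raises(AnalysisError):
            bonferroni_alpha(0.05, 0)


def _battery_records(seed=0, adult_offset_both=0.0):
    """Synthetic record set covering every treatment x age x source cell."""
    rng = np.random.default_rng(seed)
    rows = []
    for source in ("experiment", "simulation-II", "simulation-III"):
        for tr in ("none", "food", "risk", "both"):
            for age in ("juvenile", "adult"):
                for dens in np.linspace(0.2, 60, 8):
                    depth = 0.4 + 0.001 * dens + rng.normal(0, 0.02)
                    if age == "adult" and tr == "both":
                        depth += adult_offset_both
                    rows.append(dict(source=source, treatment=tr, age=age,
                                     column_side="left", density=dens,
                                     mean_depth=np.clip(depth, 0, 1)))
    return pd.DataFrame(rows)


class TestBattery:
    def test_shape_and_families(self):
        battery = run_comparison_battery(_battery_records())
        assert len(battery) == 12 + 16
        assert (battery["family"] == "experiment").sum() == 12

    def test_null_records_rarely_flagged(self):
        battery = run_comparison_battery(_battery_records(seed=3))
        flags = (battery["slope_significant"] | battery["intercept_significant"])
        assert flags.sum() <= 2  # Bonferroni keeps family-wise errors rare

    def test_planted_age_effect_flagged_in_both_gradients(self):
        battery = run_comparison_battery(
            _battery_records(seed=1, adult_offset_both=0.3)
        )
        exp = battery[battery["family"] == "experiment"]
        hit = exp[exp["comparison"].str.contains("treatment=both")]
        assert hit["intercept_significant"].all()
        others = exp[exp["comparison"].str.contains("treatment=none")]
        assert not others["intercept_significant"].any()

    def test_empty_cell_reported_not_crashed(self):
        rec = _battery_records()
        rec = rec[~((rec["treatment"] == "risk") & (rec["age"] == "adult"))]
        battery = run_comparison_battery(rec)
        assert len(battery) == 28
        missing = battery[battery["missing"]]
        assert len(missing) >= 1
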