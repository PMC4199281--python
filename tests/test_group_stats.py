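"""Aggregation, group comparisons, peak+spread regression, shared variance."""

import numpy as np
import pandas as pd
import pytest

from boldspread.group_stats import (
    age_regression,
    aggregate,
    group_compare,
    shared_variance,
    shared_variance_matrices,
)


def long_records(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "network", "roi_label", "run_id", "measure", "value"],
    )


def one_way_anova_f(groups):
    """Closed-form one-way ANOVA F: MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(groups).mean()
    k, n = len(groups), sum(len(g) for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestAggregate:
    def test_single_run_identity(self):
        rec = long_records([("s1", "a", "task_positive", "roi", "run-1", "peak_3mm", 2.5)])
        out = aggregate(rec)
        assert out["roi"]["value"].iloc[0] == 2.5
        assert out["network"]["value"].iloc[0] == 2.5

    def test_two_runs_averaged(self):
        rec = long_records(
            [
                ("s1", "a", "task_positive", "roi", "run-1", "peak_3mm", 1.0),
                ("s1", "a", "task_positive", "roi", "run-2", "peak_3mm", 3.0),
            ]
        )
        assert aggregate(rec)["roi"]["value"].iloc[0] == pytest.approx(2.0)

    def test_network_mean_is_mean_of_roi_means(self):
        rng = np.random.default_rng(0)
        rows = []
        for sid in ("s1", "s2", "s3"):
            for roi in ("r1", "r2", "r3"):
                for run in ("run-1", "run-2"):
                    rows.append((sid, "a", "task_positive", roi, run, "spread_slope", rng.normal()))
        out = aggregate(long_records(rows))
        roi = out["roi"]
        for sid in ("s1", "s2", "s3"):
            expected = roi[roi["subject_id"] == sid]["value"].mean()
            got = out["network"].loc[out["network"]["subject_id"] == sid, "value"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_values_excluded(self):
        rec = long_records(
            [
                ("s1", "a", "task_positive", "roi", "run-1", "peak_3mm", 1.0),
                ("s1", "a", "task_positive", "roi", "run-2", "peak_3mm", np.nan),
            ]
        )
        assert aggregate(rec)["roi"]["value"].iloc[0] == pytest.approx(1.0)


def network_table(values_by_group, measure="spread_slope", network="task_positive"):
    rows = []
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "subject_id": f"{group}{i}",
                    "group": group,
                    "network": network,
                    "measure": measure,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_identical_groups_null(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        out = group_compare(network_table({"a": vals, "b": vals}), "spread_slope")
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_one_way_anova(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 12)
        out = group_compare(network_table({"a": a, "b": b}), "spread_slope")
        assert out["F"].iloc[0] == pytest.approx(one_way_anova_f([a, b]), abs=1e-9)

    def test_adjusted_means_without_covariates_are_group_means(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 9.0]
        out = group_compare(network_table({"a": a, "b": b}), "spread_slope")
        assert out["adj_mean_a"].iloc[0] == pytest.approx(np.mean(a))
        assert out["adj_mean_b"].iloc[0] == pytest.approx(np.mean(b))

    def test_covariate_adjustment_shifts_means(self):
        tbl = network_table({"a": [1.0, 2.0, 3.0, 4.0], "b": [3.0, 4.0, 5.0, 6.0]})
        tbl["education"] = [10, 12, 14, 16, 14, 16, 18, 20]
        out = group_compare(tbl, "spread_slope", covariates=("education",))
        # education fully explains the group offset here, so adjusted means converge
        assert abs(out["adj_mean_a"].iloc[0] - out["adj_mean_b"].iloc[0]) < abs(2.5 - 4.5)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            group_compare(network_table({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]}), "spread_slope")

    def test_missing_measure_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            group_compare(network_table({"a": [1.0] * 3, "b": [2.0] * 3}), "nope")


def regression_table(peak, spread, groups):
    rows = []
    for i, (p, s, g) in enumerate(zip(peak, spread, groups)):
        sid = f"s{i}"
        rows.append(dict(subject_id=sid, group=g, network="task_positive",
                         measure="peak_3mm", value=p))
        rows.append(dict(subject_id=sid, group=g, network="task_positive",
                         measure="spread_slope", value=s))
    return pd.DataFrame(rows)


class TestAgeRegression:
    def test_constant_spread_drops_to_simple_regression(self):
        rng = np.random.default_rng(1)
        n = 20
        peak = rng.normal(size=n)
        groups = ["a"] * 10 + ["b"] * 10
        out = age_regression(regression_table(peak, [5.0] * n, groups))
        assert out["beta_spread"].iloc[0] == 0.0
        assert "spread" in out["constant_predictors"].iloc[0]
        y = np.array([g == "b" for g in groups], dtype=float)
        simple_beta = np.corrcoef(peak, y)[0, 1]
        assert out["beta_peak"].iloc[0] == pytest.approx(simple_beta, abs=1e-9)

    def test_orthogonal_predictors_r2_additive(self):
        """With orthogonal standardized predictors, R^2 = r1^2 + r2^2."""
        rng = np.random.default_rng(2)
        n = 40
        peak = rng.normal(size=n)
        spread = rng.normal(size=n)
        spread -= peak * (peak @ spread) / (peak @ peak)  # orthogonalize
        y = rng.normal(size=n)
        tbl = regression_table(peak, spread, ["a"] * 20 + ["b"] * 20)
        tbl = tbl.assign(age=np.repeat(y, 2))
        out = age_regression(tbl, criterion="age")
        zp = (peak - peak.mean()) / peak.std(ddof=1)
        zs = (spread - spread.mean()) / spread.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        r1, r2 = np.corrcoef(zp, zy)[0, 1], np.corrcoef(zs, zy)[0, 1]
        # exact identity requires exactly orthogonal centered predictors
        assert out["R2"].iloc[0] == pytest.approx(r1**2 + r2**2, abs=1e-3)

    def test_amplitude_only_group_difference(self):
        rng = np.random.default_rng(3)
        groups = ["a"] * 15 + ["b"] * 15
        peak = np.r_[rng.normal(0, 0.3, 15), rng.normal(2.0, 0.3, 15)]
        spread = rng.normal(10, 0.5, 30)
        out = age_regression(regression_table(peak, spread, groups))
        assert out["p_peak"].iloc[0] < 0.001
        assert out["p_spread"].iloc[0] > 0.05


def roi_table_from_matrices(spread, peak, network="task_positive"):
    rows = []
    for sid in spread.index:
        for roi in spread.columns:
            rows.append(dict(subject_id=sid, group="g", network=network, roi_label=roi,
                             measure="spread_slope", value=spread.loc[sid, roi]))
            rows.append(dict(subject_id=sid, group="g", network=network, roi_label=roi,
                             measure="peak_3mm", value=peak.loc[sid, roi]))
    return pd.DataFrame(rows)


class TestSharedVariance:
    def test_duplicated_matrices(self):
        """peak == spread: SS = PP = SP_all, and SP_same = 1 (self-correlation)."""
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        out = shared_variance_matrices(m, m.copy())
        assert out["PP"] == pytest.approx(out["SS"], abs=1e-12)
        assert out["SP_all"] == pytest.approx(out["SS"], abs=1e-12)
        assert out["SP_same"] == pytest.approx(1.0, abs=1e-12)

    def test_subject_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        s = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        p = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        base = shared_variance_matrices(s, p)
        perm = rng.permutation(10)
        permuted = shared_variance_matrices(s.iloc[perm], p.iloc[perm])
        for key in base:
            assert permuted[key] == pytest.approx(base[key], abs=1e-12)

    def test_common_factor_spread_independent_peaks(self):
        """Spread columns sharing one subject factor give SS -> 1 while
        independent peaks keep SP_same near zero (n = 200)."""
        rng = np.random.default_rng(6)
        factor = rng.normal(size=200)
        spread = pd.DataFrame({c: factor for c in "abcd"})
        peak = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        out = shared_variance_matrices(spread, peak)
        assert out["SS"] > 0.95
        assert out["SP_same"] < 0.05

    def test_zero_variance_region_rejected(self):
        s = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        p = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 3.0, 4.0, 5.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            shared_variance_matrices(s, p)

    def test_table_interface_values_in_unit_interval(self):
        rng = np.random.default_rng(7)
        s = pd.DataFrame(rng.normal(size=(16, 3)), columns=list("abc"),
                         index=[f"s{i}" for i in range(16)])
        p = pd.DataFrame(rng.normal(size=(16, 3)), columns=list("abc"), index=s.index)
        s.index.name = p.index.name = "subject_id"
        tbl = roi_table_from_matrices(s, p)
        summary = shared_variance(tbl, n_permutations=200, seed=0).table
        for key in ("SS", "PP", "SP_all", "SP_same"):
            assert ((summary[key] >= 0) & (summary[key] <= 1)).all()
        assert set(summary["network"]) == {"task_positive", "all"}

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        s = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        p = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        base = shared_variance_matrices(s, p)
        rescaled = shared_variance_matrices(s * 3.7 - 2.0, p * -0.4 + 11.0)
        for key in base:
            assert rescaled[key] == pytest.approx(base[key], abs=1e-12)
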