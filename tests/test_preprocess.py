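import numpy as np
import pandas as pd
import pytest

from metaminer import (PeakTable, SampleMetadata, SimDesign, basic_statistics,
                       impute_missing, normalize, replace_outliers,
                       simulate_peak_table, transform)


def _table(columns: dict) -> PeakTable:
    frame = pd.DataFrame(columns)
    frame.index = [f"s{i}" for i in range(len(frame))]
    return PeakTable(frame)


class TestReplaceOutliers:
    def test_constant_variable_unchanged(self):
        t = _table({"v": [5.0, 5.0, 5.0]})
        out, report = replace_outliers(t)
        assert out.data["v"].tolist() == [5.0, 5.0, 5.0]
        assert report.per_variable["n_outliers_replaced"]["v"] == 0

    def test_gross_outlier_replaced_by_max_of_rest(self):
        values = [1, 2, 3, 2, 1, 2, 3, 2, 1, 2, 1000.0]
        # oracle: single-pass mean/SD flags only the extreme point
        arr = np.array(values)
        assert abs(1000 - arr.mean()) > 3 * arr.std(ddof=1)
        t = _table({"v": values})
        out, report = replace_outliers(t)
        assert report.per_variable["n_outliers_replaced"]["v"] == 1
        assert out.data["v"].iloc[-1] == 3.0

    def test_too_few_values_skipped(self):
        t = _table({"v": [1.0, 2.0, np.nan, np.nan]})
        with pytest.warns(UserWarning, match="skipped"):
            out, _ = replace_outliers(t)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_second_pass_replaces_no_more(self, rng):
        data = rng.lognormal(2, 1, size=(30, 5))
        data[0, 0] *= 50
        t = PeakTable(pd.DataFrame(data, columns=[f"v{j}" for j in range(5)]))
        once, rep1 = replace_outliers(t)
        twice, rep2 = replace_outliers(once)
        assert (rep2.per_variable["n_outliers_replaced"].sum()
                <= rep1.per_variable["n_outliers_replaced"].sum())


class TestImpute:
    @pytest.mark.parametrize("method", ["minimum", "knn", "qrilc"])
    def test_complete_table_unchanged(self, small_table, method):
        out = impute_missing(small_table, method, seed=1)
        pd.testing.assert_frame_equal(out.data, small_table.data)

    def test_minimum_rule(self):
        t = _table({"v": [2.0, np.nan, 6.0]})
        out = impute_missing(t, "minimum")
        assert out.data["v"].tolist() == [2.0, 2.0, 6.0]

    def test_knn_large_k_equals_mean_of_others(self):
        t = _table({"v": [2.0, np.nan, 6.0, 7.0],
                    "w": [1.0, 1.0, 1.0, 2.0]})
        out = impute_missing(t, "knn", k=10)
        assert out.data.loc["s1", "v"] == pytest.approx(np.mean([2.0, 6.0, 7.0]))

    def test_no_missing_after_any_method(self, rng):
        design = SimDesign(n_per_group=15, n_variables=25, missing_rate=0.2,
                           seed=3)
        t, _, _ = simulate_peak_table(design)
        for method in ["minimum", "knn", "qrilc"]:
            assert impute_missing(t, method, seed=5).n_missing() == 0

    def test_qrilc_seed_reproducible_and_left_censored(self):
        design = SimDesign(n_per_group=25, n_variables=20, missing_rate=0.25,
                           censor_left=True, seed=4)
        t, _, _ = simulate_peak_table(design)
        a = impute_missing(t, "qrilc", seed=9)
        b = impute_missing(t, "qrilc", seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)
        mask = t.data.isna()
        imputed = a.data.to_numpy()[mask.to_numpy()]
        observed = t.data.to_numpy()[~mask.to_numpy()]
        assert np.median(imputed) < np.median(observed)

    def test_all_missing_variable_dropped(self):
        t = _table({"v": [np.nan, np.nan, np.nan], "w": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="all-missing"):
            out = impute_missing(t, "minimum")
        assert out.variable_ids == ["w"]

    def test_unknown_method(self, small_table):
        with pytest.raises(ValueError):
            impute_missing(small_table, "magic")


class TestNormalize:
    def test_total_intensity_equalizes_row_sums(self, rng):
        data = pd.DataFrame(rng.lognormal(3, 1, size=(8, 6)))
        t = PeakTable(data.set_axis([f"s{i}" for i in range(8)]))
        out, _ = normalize(t, "total_intensity")
        sums = out.data.sum(axis=1)
        np.testing.assert_allclose(sums, sums.iloc[0], rtol=1e-12)

    def test_total_intensity_scale_invariance(self, rng):
        # scale the largest-total sample so the median row total (the
        # common rescale factor) is untouched: its output must not change
        data = pd.DataFrame(rng.lognormal(3, 1, size=(8, 6)),
                            index=[f"s{i}" for i in range(8)])
        t = PeakTable(data)
        target = data.sum(axis=1).idxmax()
        scaled = data.copy()
        scaled.loc[target] *= 7.5
        out1, _ = normalize(t, "total_intensity")
        out2, _ = normalize(PeakTable(scaled), "total_intensity")
        np.testing.assert_allclose(out1.data.loc[target],
                                   out2.data.loc[target], rtol=1e-10)

    def test_internal_standard_identity(self, small_table):
        with_is = small_table.copy()
        with_is.data["IS"] = 1.0
        out, _ = normalize(with_is, "internal_standard", is_variable="IS")
        pd.testing.assert_frame_equal(out.data.drop(columns="IS"),
                                      small_table.data)

    def test_qc_rlsc_reduces_qc_cv(self):
        design = SimDesign(n_per_group=20, n_variables=15, n_informative=0,
                           drift_slope=0.05, qc_every=5, seed=6)
        t, meta, _ = simulate_peak_table(design)
        out, _ = normalize(t, "qc_rlsc", meta=meta)
        qc = meta.is_qc()
        cv_pre = (t.data[qc].std() / t.data[qc].mean()).median()
        cv_post = (out.data[qc].std() / out.data[qc].mean()).median()
        assert cv_post < cv_pre

    def test_qc_rlsc_needs_qcs(self, small_table, small_meta):
        with pytest.raises(ValueError, match="QC"):
            normalize(small_table, "qc_rlsc", meta=small_meta)


class TestTransform:
    def test_log_closed_form(self):
        t = _table({"v": [1.0, np.e, np.e ** 2]})
        out = transform(t, "log")
        np.testing.assert_allclose(out.data["v"], [0, 1, 2], atol=1e-12)
        assert out.log_transformed

    def test_zscore_moments(self, sim_study):
        table, _, _ = sim_study
        out = transform(table, "zscore")
        np.testing.assert_allclose(out.data.mean(), 0, atol=1e-10)
        np.testing.assert_allclose(out.data.std(ddof=1), 1, atol=1e-10)

    def test_zscore_constant_variable(self):
        t = _table({"v": [3.0, 3.0, 3.0], "w": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = transform(t, "zscore")
        assert (out.data["v"] == 0).all()

    def test_log_rejects_negatives(self):
        t = _table({"v": [-1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            transform(t, "log")

    def test_log_zero_gets_half_min_offset(self):
        t = _table({"v": [0.0, 4.0, 8.0]})
        out = transform(t, "log")
        assert out.data["v"].iloc[0] == pytest.approx(np.log(2.0))


class TestBasicStatistics:
    def test_closed_form(self):
        t = _table({"v": [1.0, 2.0, 3.0]})
        stats = basic_statistics(t)
        assert stats.loc["v", "mean"] == 2
        assert stats.loc["v", "sd"] == 1
        assert stats.loc["v", "median"] == 2

    def test_cv_of_constant_is_zero(self):
        t = _table({"v": [10.0, 10.0, 10.0]})
        assert basic_statistics(t).loc["v", "cv_pct"] == 0

    def test_per_group_columns(self, small_table, small_meta):
        stats = basic_statistics(small_table, small_meta)
        assert stats.loc["v1", "A.mean"] == 1.5
        assert stats.loc["v1", "B.mean"] == 3.5
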