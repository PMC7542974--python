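import numpy as np
import pandas as pd
import pytest

from metaminer import (MicrobeTable, PeakTable, SampleMetadata, clr_transform,
                       correlate, distance_correlation, gramm, retrieve_pairs,
                       simulate_coupled_microbiome, simulate_peak_table,
                       SimDesign)


def _table(cols, prefix="s"):
    frame = pd.DataFrame(cols)
    frame.index = [f"{prefix}{i}" for i in range(len(frame))]
    return PeakTable(frame)


def _dcor_bruteforce(x, y):
    """O(n^2) double-centering oracle, written from the definition."""
    n = len(x)
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = abs(x[i] - x[j])
            b[i, j] = abs(y[i] - y[j])
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a[i, j] - a[i].mean() - a[:, j].mean() + a.mean()
            B[i, j] = b[i, j] - b[i].mean() - b[:, j].mean() + b.mean()
    dcov2 = (A * B).mean()
    dvx = (A * A).mean()
    dvy = (B * B).mean()
    return np.sqrt(max(dcov2, 0) / np.sqrt(dvx * dvy)) if dvx * dvy > 0 else 0.0


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(6.0)
        t = _table({"x": x, "y": 2 * x + 1})
        res = correlate(t, method="pearson")
        row = res.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 0.05

    def test_spearman_monotone_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        t1 = _table({"x": x, "y": y})
        t2 = _table({"x": np.exp(x), "y": y ** 3})
        r1 = correlate(t1, method="spearman").iloc[0]["r"]
        r2 = correlate(t2, method="spearman").iloc[0]["r"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_symmetry_across_tables(self, rng):
        a = _table({"x": rng.normal(size=12)})
        b = _table({"y": rng.normal(size=12)})
        for method in ["pearson", "spearman", "kendall"]:
            rab = correlate(a, b, method=method).iloc[0]
            rba = correlate(b, a, method=method).iloc[0]
            assert rab["r"] == pytest.approx(rba["r"], abs=1e-12)
            assert rab["p"] == pytest.approx(rba["p"], abs=1e-12)

    def test_null_calibration(self, rng):
        n_pairs, alpha = 400, 0.05
        x = pd.DataFrame(rng.normal(size=(30, n_pairs)))
        y = pd.DataFrame(rng.normal(size=(30, n_pairs)),
                         columns=[f"y{i}" for i in range(n_pairs)])
        rate = np.mean([
            correlate(_table({"x": x[i], "y": y[f"y{i}"]}),
                      method="pearson").iloc[0]["p"] < alpha
            for i in range(n_pairs)])
        lo, hi = 0.05 - 2.58 * np.sqrt(0.05 * 0.95 / n_pairs), \
            0.05 + 2.58 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert lo <= rate <= hi

    def test_partial_spearman_removes_confounder(self, rng):
        n = 50
        z = rng.normal(size=n)
        x = 2 * z + rng.normal(0, 0.3, n)
        y = -3 * z + rng.normal(0, 0.3, n)
        t = _table({"x": x, "y": y})
        conf = SampleMetadata(pd.DataFrame(
            {"group": "all", "z": z}, index=t.data.index))
        naive = correlate(t, method="spearman").iloc[0]
        partial = correlate(t, method="partial_spearman",
                            confounders=conf).iloc[0]
        assert abs(naive["r"]) > 0.8
        assert abs(partial["r"]) < abs(naive["r"]) / 2

    def test_too_few_samples(self):
        t = _table({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="4"):
            correlate(t)


class TestDistanceCorrelation:
    def test_matches_bruteforce_oracle(self, rng):
        for n in [10, 25, 50]:
            x = rng.normal(size=n)
            y = x ** 2 + rng.normal(0, 0.5, n)
            assert distance_correlation(x, y) == pytest.approx(
                _dcor_bruteforce(x, y), abs=1e-10)

    def test_detects_quadratic_dependence(self, rng):
        x = rng.normal(size=100)
        y = x ** 2
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.3
        assert distance_correlation(x, y) > 0.4

    def test_constant_input_zero(self):
        assert distance_correlation(np.ones(10), np.arange(10.0)) == 0.0


class TestCLR:
    def test_rows_sum_to_zero(self, rng):
        ab = pd.DataFrame(rng.dirichlet(np.ones(5), size=8))
        clr = clr_transform(ab)
        np.testing.assert_allclose(clr.sum(axis=1), 0, atol=1e-10)

    def test_zeros_replaced(self):
        ab = pd.DataFrame([[0.0, 1.0, 3.0], [1.0, 1.0, 2.0]])
        clr = clr_transform(ab)
        assert np.isfinite(clr.to_numpy()).all()


@pytest.fixture(scope="module")
def coupled():
    design = SimDesign(n_per_group=30, n_variables=8, n_informative=0,
                       effect_size=0.0, seed=42)
    metab, _, _ = simulate_peak_table(design)
    return simulate_coupled_microbiome(metab, n_taxa=8, n_linear=2,
                                       n_nonlinear=2, n_confounded=1,
                                       seed=42)


class TestGramm:
    def test_planted_types_recovered(self, coupled):
        metab, microbe, truth, conf = coupled
        res = gramm(metab, microbe, confounders=conf, n_permutations=199,
                    seed=1)
        for _, planted in truth.iterrows():
            row = res[(res.feature_a == planted.metabolite)
                      & (res.feature_b == planted.taxon)].iloc[0]
            if planted["type"] == "linear":
                assert row["type"] == "linear"
                assert row["r"] > 0 and row["q"] < 0.05
            elif planted["type"] == "nonlinear":
                # quadratic link: near-zero Pearson, positive distance corr.
                assert row["type"] == "nonlinear"
                assert abs(row["pearson_r"]) < 0.4
                assert row["dcor"] > 0.2 and row["p"] < 0.05

    def test_confounded_pair_not_rejected(self, coupled):
        metab, microbe, truth, conf = coupled
        res = gramm(metab, microbe, confounders=conf, n_permutations=199,
                    seed=1)
        for _, planted in truth[truth["type"] == "confounded"].iterrows():
            row = res[(res.feature_a == planted.metabolite)
                      & (res.feature_b == planted.taxon)].iloc[0]
            assert row["q"] > 0.05

    def test_no_confounders_equals_intercept_only(self, coupled):
        metab, microbe, _, _ = coupled
        a = gramm(metab, microbe, confounders=None, n_permutations=49, seed=2)
        empty_conf = SampleMetadata(pd.DataFrame(
            {"group": "all"}, index=metab.data.index))
        b = gramm(metab, microbe, confounders=empty_conf, n_permutations=49,
                  seed=2)
        np.testing.assert_allclose(a["r"], b["r"], atol=1e-10)

    def test_requires_enough_samples(self):
        t = _table({"m": np.arange(10.0)})
        mic = MicrobeTable(pd.DataFrame(
            {"t1": np.ones(10)}, index=t.data.index))
        with pytest.raises(ValueError, match="20"):
            gramm(t, mic)


class TestRetrievePairs:
    def _results(self):
        return pd.DataFrame({
            "feature_a": ["a", "b", "c", "d"],
            "feature_b": ["x", "y", "z", "d"],
            "r": [0.9, -0.7, 0.3, 0.99],
            "p": [0.001, 0.002, 0.3, 0.0001],
            "q": [0.004, 0.008, 0.5, 0.001]})

    def test_threshold_and_ordering(self):
        edges = retrieve_pairs(self._results(), r_min=0.6, q_max=0.05)
        assert list(edges["feature_a"]) == ["a", "b"]
        assert list(edges["interaction"]) == ["positive", "negative"]

    def test_self_pairs_always_excluded(self):
        edges = retrieve_pairs(self._results(), r_min=0.0, q_max=1.0)
        assert "d" not in set(edges["feature_a"]) or \
            not ((edges["feature_a"] == "d") & (edges["feature_b"] == "d")).any()

    def test_empty_result_has_header(self):
        edges = retrieve_pairs(pd.DataFrame(), r_min=0.6)
        assert list(edges.columns) == ["feature_a", "interaction",
                                       "feature_b", "r", "q"]
        assert len(edges) == 0
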