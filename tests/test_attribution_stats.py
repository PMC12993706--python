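"""DTW correctness against exhaustive path enumeration, ranking behavior,
and the branching seasonal significance tests."""

import functools

import numpy as np
import pandas as pd
import pytest

from ecoforcing import attribution_stats as ast
from ecoforcing.ts_decomposition import COMPONENTS


def brute_force_dtw(a, b):
    """Independent oracle: minimum over all monotone warping paths."""
    n, m = len(a), len(b)

    @functools.lru_cache(maxsize=None)
    def best(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        prev = []
        if i > 0 and j > 0:
            prev.append(best(i - 1, j - 1))
        if i > 0:
            prev.append(best(i - 1, j))
        if j > 0:
            prev.append(best(i, j - 1))
        return c + min(prev)

    return best(n - 1, m - 1)


class TestDTW:
    def test_identical_series_zero(self):
        x = [1.0, 5.0, -2.0, 0.5]
        assert ast.dtw_distance(x, x) == 0.0

    def test_constant_offset_path(self):
        assert ast.dtw_distance([0, 0, 0], [1, 1, 1]) == 3.0

    def test_symmetry(self):
        a, b = [0.0, 1.0, 2.0, 1.5], [0.5, 2.0, 1.0]
        assert ast.dtw_distance(a, b) == ast.dtw_distance(b, a)

    def test_short_series_null(self):
        assert np.isnan(ast.dtw_distance([1.0, 2.0], [1.0, 2.0]))

    def test_matches_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n, m = rng.integers(3, 7, size=2)
            a = tuple(np.round(rng.normal(0, 1, n), 3))
            b = tuple(np.round(rng.normal(0, 1, m), 3))
            assert ast.dtw_distance(a, b) == pytest.approx(
                brute_force_dtw(a, b), abs=1e-12)

    def test_path_length_bounds(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 14)
        d, p = ast.dtw_distance(a, b, return_path_length=True)
        assert 14 <= p <= 10 + 14 - 1

    def test_gap_handling_splits_and_recombines(self):
        idx = pd.RangeIndex(10)
        a = pd.Series([0, 0, 0, np.nan, 1, 1, 1, 1, np.nan, 5], index=idx)
        b = pd.Series([1.0] * 10, index=idx)
        dist, path, n_used = ast.dtw_with_gaps(a, b)
        # two usable segments (length 3 and 4); trailing length-1 run skipped
        assert n_used == 7
        assert dist == pytest.approx(3.0 + 0.0)
        assert path == 3 + 4


class TestRanking:
    def _decomp(self, series_map, season="spring"):
        n = len(next(iter(series_map.values())))
        df = pd.DataFrame({"site_pair": "NT-CT", "layer": "ecosystem",
                           "season": season,
                           "date": pd.date_range("2021-03-01", periods=n)})
        for comp in COMPONENTS:
            df[comp] = series_map.get(comp, np.zeros(n))
        df["dTs_cal"] = series_map["dTs_cal"]
        return df

    def test_identical_component_ranks_first_with_zero_distance(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(0, 1, 30)
        rep = ast.normalized_component_ranking(
            self._decomp({"dTs_cal": sig, "d_g": sig,
                          "d_le": rng.normal(0, 1, 30)}))
        row = rep.set_index("component")
        assert row.loc["d_g", "dtw_normalized"] == 0.0
        assert row.loc["d_g", "rank"] == 1

    def test_offset_ranks_closer_than_sign_flip(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(0, 1, 40)
        rep = ast.normalized_component_ranking(
            self._decomp({"dTs_cal": sig, "d_le": sig + 0.3,
                          "d_h": -sig})).set_index("component")
        assert rep.loc["d_le", "rank"] < rep.loc["d_h", "rank"]

    def test_normalized_values_span_unit_interval(self):
        rng = np.random.default_rng(2)
        series = {c: rng.normal(0, 1, 25) for c in COMPONENTS}
        series["dTs_cal"] = rng.normal(0, 1, 25)
        rep = ast.normalized_component_ranking(self._decomp(series))
        assert rep["dtw_normalized"].min() == 0.0
        assert rep["dtw_normalized"].max() == 1.0
        assert sorted(rep["rank"]) == list(range(1, 9))

    def test_ranking_invariant_to_affine_signal_rescale(self):
        rng = np.random.default_rng(3)
        series = {c: rng.normal(0, 1, 25) for c in COMPONENTS}
        series["dTs_cal"] = rng.normal(0, 1, 25)
        rep1 = ast.normalized_component_ranking(self._decomp(series))
        scaled = {k: 3.0 * v for k, v in series.items()}
        rep2 = ast.normalized_component_ranking(self._decomp(scaled))
        assert rep1["rank"].tolist() == rep2["rank"].tolist()

    def test_small_group_skipped(self):
        rng = np.random.default_rng(4)
        rep = ast.normalized_component_ranking(
            self._decomp({"dTs_cal": rng.normal(0, 1, 5)}))
        assert rep.empty

    def test_tracking_component_tops_generator_group(self, noisy_results):
        """A synthetic group built so d_g tracks dTs_cal ranks d_g first."""
        rng = np.random.default_rng(5)
        sig = np.cumsum(rng.normal(0, 0.3, 60))
        series = {c: rng.normal(0, 1.0, 60) for c in COMPONENTS}
        series["d_g"] = sig + rng.normal(0, 0.01, 60)
        series["dTs_cal"] = sig
        rep = ast.normalized_component_ranking(
            self._decomp(series)).set_index("component")
        assert rep.loc["d_g", "rank"] == 1


class TestSeasonalGroupTest:
    def test_identical_distributions_share_one_letter(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 150)
        sites = np.repeat(["CT", "NT", "NPT"], 50)
        res = ast.seasonal_group_test(vals, sites)
        assert res["pvalue"] > 0.05
        letters = set(res["letters"].values())
        assert len(letters) == 1

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                               rng.normal(3, 1, 50)])
        sites = np.repeat(["CT", "NT", "NPT"], 50)
        res = ast.seasonal_group_test(vals, sites)
        assert res["pvalue"] < 0.05
        assert res["letters"]["NPT"] not in (res["letters"]["CT"],
                                             res["letters"]["NT"])
        assert res["letters"]["CT"] == res["letters"]["NT"]

    def test_heavy_tailed_data_selects_kruskal_wallis(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.standard_cauchy(60) for _ in range(3)])
        sites = np.repeat(["CT", "NT", "NPT"], 60)
        res = ast.seasonal_group_test(vals, sites)
        assert res["test"] == "Kruskal-Wallis"

    def test_normal_homoscedastic_selects_anova(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 60) for _ in range(3)])
        sites = np.repeat(["CT", "NT", "NPT"], 60)
        res = ast.seasonal_group_test(vals, sites)
        assert res["test"] == "ANOVA"

    def test_insufficient_sites_returns_none(self):
        assert ast.seasonal_group_test([1.0] * 20,
                                       ["CT"] * 10 + ["NT"] * 10) is None

    def test_pipeline_table_contains_all_layers(self, noisy_results):
        t = noisy_results["seasonal_tests"]
        assert set(t["layer"]) == {"ecosystem", "understory"}
        assert (t["pvalue"].between(0, 1)).all()
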