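"""Range-expansion analyses: accumulation, growth fits, graphs, join counts."""

import numpy as np
import pandas as pd
import pytest

from invasdm.geo import pairwise_haversine_km
from invasdm.occurrences import OccurrenceSet
from invasdm.spread import (NeighborGraph, accumulation_curve,
                            build_neighbor_graph, fit_growth,
                            join_count_exact_p, join_count_test,
                            sequential_models)


def occ_with_years(years):
    n = len(years)
    return OccurrenceSet(pd.DataFrame({
        "id": [f"r{i}" for i in range(n)],
        "longitude": np.linspace(-100, -99, n), "latitude": 35.0,
        "year": years, "precision": 0.001, "source": "t",
        "is_county_centroid": False}))


class TestAccumulation:
    def test_constant_rate_accumulates_linearly(self):
        occ = occ_with_years(np.repeat(np.arange(1960, 1970), 10))
        acc = accumulation_curve(occ)
        assert acc["cumulative"].iloc[-1] == 100
        assert (np.diff(acc["cumulative"]) == 10).all()

    def test_single_year_burst_is_a_step(self):
        acc = accumulation_curve(occ_with_years([1990] * 7))
        assert list(acc["cumulative"]) == [7]

    def test_matches_groupby_cumsum_oracle(self, study):
        occ = study["occ"]
        acc = accumulation_curve(occ)
        want = (pd.Series(occ.year.astype(int)).value_counts().sort_index()
                .cumsum())
        got = dict(zip(acc["year"], acc["cumulative"]))
        for year, total in want.items():
            assert got[year] == total


class TestFitGrowth:
    def test_exact_line_selects_linear_with_zero_rss(self):
        years = np.arange(2000, 2012)
        lin, log, selected = fit_growth(years, 5 + 2 * (years - 2000))
        assert selected == "linear"
        assert lin.rss == pytest.approx(0.0, abs=1e-16)

    def test_exact_exponential_selects_log_linear_with_zero_rss(self):
        years = np.arange(2000, 2012)
        lin, log, selected = fit_growth(years, 2 * np.exp(0.3 * (years - 2000)))
        assert selected == "log-linear"
        assert log.rss == pytest.approx(0.0, abs=1e-12)

    def test_aicc_matches_closed_form_oracle(self):
        years = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        aoo = np.array([2.0, 3, 5, 4, 8, 9, 12, 11])
        lin, log, _ = fit_growth(years, aoo)
        # least squares by hand
        A = np.column_stack([np.ones(8), years])
        for fitres, y in ((lin, aoo), (log, np.log(aoo))):
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            rss = ((y - A @ beta) ** 2).sum()
            k, n = 3, 8
            want = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert fitres.aicc == pytest.approx(want)
            # AICc = AIC + correction term
            assert fitres.aicc - (n * np.log(rss / n) + 2 * k) == pytest.approx(
                2 * k * (k + 1) / (n - k - 1))

    def test_jacobian_corrected_log_aicc_reported(self):
        years = np.arange(2000, 2010)
        aoo = 3 * np.exp(0.2 * (years - 2000))
        _, log, _ = fit_growth(years, aoo)
        assert log.aicc_response_scale == pytest.approx(
            log.aicc + 2 * np.log(aoo).sum())

    def test_noisy_exponential_mostly_selects_log_linear(self):
        picks = 0
        years = np.arange(20)
        for seed in range(25):
            rng = np.random.default_rng(seed)
            aoo = 5 * np.exp(0.25 * years) * np.exp(rng.normal(0, 0.1, 20))
            _, _, selected = fit_growth(years, aoo)
            picks += selected == "log-linear"
        assert picks >= 23

    def test_nonpositive_aoo_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_growth(np.arange(5), [1.0, 2.0, 0.0, 3.0, 4.0])


class TestNeighborGraph:
    def test_collinear_equidistant_triple_symmetrizes_to_two_edges(self):
        g = build_neighbor_graph([-100.0, -99.0, -98.0], [0.0, 0.0, 0.0],
                                 "knn:1")
        assert g.n_edges == 2
        assert {tuple(e) for e in g.edges} == {(0, 1), (1, 2)}

    def test_radius_beyond_diameter_gives_complete_graph(self, rng):
        lon = -100 + rng.uniform(0, 1, 12)
        lat = 35 + rng.uniform(0, 1, 12)
        g = build_neighbor_graph(lon, lat, "radius:1000")
        assert g.n_edges == 12 * 11 // 2

    def test_knn10_degrees_and_edges_match_distance_matrix_oracle(self, rng):
        lon = -100 + rng.uniform(0, 3, 50)
        lat = 33 + rng.uniform(0, 3, 50)
        g = build_neighbor_graph(lon, lat, "knn:10")
        assert (g.degrees() >= 10).all()
        D = pairwise_haversine_km(lon, lat)
        np.fill_diagonal(D, np.inf)
        want = set()
        for i in range(50):
            for j in np.argsort(D[i])[:10]:
                want.add((min(i, j), max(i, j)))
        assert {tuple(e) for e in g.edges} == want

    def test_radius_edges_match_brute_force(self, rng):
        lon = -100 + rng.uniform(0, 2, 40)
        lat = 33 + rng.uniform(0, 2, 40)
        g = build_neighbor_graph(lon, lat, "radius:80")
        D = pairwise_haversine_km(lon, lat)
        want = {(i, j) for i in range(40) for j in range(i + 1, 40)
                if D[i, j] <= 80}
        assert {tuple(e) for e in g.edges} == want

    def test_k_must_be_less_than_n(self):
        with pytest.raises(ValueError, match="smaller"):
            build_neighbor_graph([-100.0, -99.0], [0.0, 0.0], "knn:2")


class TestJoinCount:
    def path4(self):
        return NeighborGraph(n=4, edges=np.array([[0, 1], [1, 2], [2, 3]]),
                             scheme="path")

    def test_exact_enumeration_on_ppaa_path_gives_half(self):
        p = join_count_exact_p(self.path4(), [True, True, False, False])
        assert p == pytest.approx(0.5)

    def test_permutation_p_converges_to_exact_p(self):
        res = join_count_test(self.path4(), [True, True, False, False],
                              n_perm=1999, seed=0)
        assert res.pp == 1
        assert abs(res.p_value - 0.5) < 0.05

    def test_complete_graph_pp_is_permutation_invariant(self):
        edges = np.array([(i, j) for i in range(6) for j in range(i + 1, 6)])
        g = NeighborGraph(n=6, edges=edges, scheme="complete")
        res = join_count_test(g, [True] * 3 + [False] * 3, n_perm=199, seed=1)
        assert res.p_value == 1.0
        assert res.perm_sd_pp == 0.0

    def test_permutation_mean_matches_analytic_expectation(self, rng):
        lon = -100 + rng.uniform(0, 3, 60)
        lat = 33 + rng.uniform(0, 3, 60)
        g = build_neighbor_graph(lon, lat, "knn:3")
        labels = np.zeros(60, bool)
        labels[:20] = True
        res = join_count_test(g, rng.permutation(labels), n_perm=999, seed=2)
        m, n, E = 20, 60, g.n_edges
        expect = E * m * (m - 1) / (n * (n - 1))
        se = res.perm_sd_pp / np.sqrt(res.n_perm)
        assert abs(res.perm_mean_pp - expect) < 3 * se + 1e-9

    def test_edge_counts_partition(self, rng):
        lon = -100 + rng.uniform(0, 3, 30)
        lat = 33 + rng.uniform(0, 3, 30)
        g = build_neighbor_graph(lon, lat, "knn:2")
        res = join_count_test(g, rng.uniform(size=30) < 0.4, n_perm=99, seed=3)
        assert res.pp + res.pa + res.aa == g.n_edges
        assert res.p_value > 0.0

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="presence and one absence"):
            join_count_test(self.path4(), [True] * 4)


class TestSequentialModels:
    def test_sequence_reports_internal_and_forecast_metrics(self, study):
        res = sequential_models(study["occ"], study["stack"],
                                cutoffs=(1980, 2004), n_background=300,
                                seed=1, n_knots=4)
        assert [r.cutoff for r in res] == [1980, 2004]
        early, late = res
        assert early.forecast is not None
        assert 0 <= early.forecast.auc_test <= 1
        assert 0 <= early.proportion_suitable <= 1
        assert early.n_presence < late.n_presence
        assert early.aoo <= late.aoo

    def test_cutoff_at_final_year_has_no_forecast(self, study):
        res = sequential_models(study["occ"], study["stack"], cutoffs=(2005,),
                                n_background=300, seed=1, n_knots=4)
        assert res[0].forecast is None
        assert "no records after cutoff" in res[0].forecast_note

    def test_sparse_early_cutoffs_skipped_with_warning(self, study):
        with pytest.warns(UserWarning, match="skipped"):
            res = sequential_models(study["occ"], study["stack"],
                                    cutoffs=(1961, 2004),
                                    min_presences=50, n_background=300,
                                    seed=1, n_knots=4)
        assert [r.cutoff for r in res] == [2004]

    def test_all_suitable_projection_gives_proportion_one(self, study):
        from invasdm.spread import SequentialResult  # noqa: F401 (shape only)
        res = sequential_models(study["occ"], study["stack"], cutoffs=(2004,),
                                n_background=300, seed=1, n_knots=4,
                                suitable_threshold=0.0)
        assert res[0].proportion_suitable == 1.0
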