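"""Synthetic cohort generation, missingness induction and fixtures."""

import numpy as np
import pandas as pd
import pytest

from misscen import (
    NodeSpec,
    Policy,
    StructuralModel,
    analyze_patterns,
    apply_missingness,
    apply_policy,
    build_graph,
    draw_case_params,
    example1_dataset,
    fixture_nde,
    make_cvd_case,
    read_csv,
    sample_population,
    staircase_dataset,
    write_csv,
)
from misscen.mgraph import SELECTION_NODE


class TestSamplePopulation:
    def test_standard_normal_root(self):
        m = StructuralModel({"X": NodeSpec((), "linear_gaussian", 0.0, (), 1.0)})
        t = sample_population(m, 100_000, 0)
        assert abs(t["X"].mean()) < 0.02
        assert abs(t["X"].var() - 1.0) < 0.02

    def test_linear_child_moments(self):
        # Y = 2X + 1 with zero noise: mean 1, variance 4
        m = StructuralModel(
            {
                "X": NodeSpec((), "linear_gaussian", 0.0, (), 1.0),
                "Y": NodeSpec(("X",), "linear_gaussian", 1.0, (2.0,), 1e-12),
            }
        )
        t = sample_population(m, 100_000, 1)
        assert abs(t["Y"].mean() - 1.0) < 0.03
        assert abs(t["Y"].var() - 4.0) < 0.08

    def test_logistic_prevalence(self):
        b = -1.0
        m = StructuralModel({"Y": NodeSpec((), "logistic_bernoulli", b)})
        t = sample_population(m, 100_000, 2)
        want = 1 / (1 + np.exp(-b))
        assert abs(t["Y"].mean() - want) < 0.005

    def test_reproducible_given_seed(self):
        m = StructuralModel({"X": NodeSpec((), "linear_gaussian", 0.0, (), 1.0)})
        assert sample_population(m, 100, 7).equals(sample_population(m, 100, 7))


class TestApplyMissingness:
    @pytest.fixture
    def bivariate(self):
        model = StructuralModel(
            {
                "X1": NodeSpec((), "linear_gaussian", 0.0, (), 1.0),
                "X2": NodeSpec(("X1",), "linear_gaussian", 0.0, (1.0,), 1.0),
            }
        )
        graph = build_graph(
            {
                "variables": ["X1", "X2"],
                "edges": [["X1", "X2"]],
                "mechanisms": {
                    "R_X1": {"parents": [], "link": "constant", "probability": 0.7},
                    "R_X2": {"parents": [], "link": "constant", "probability": 0.7},
                },
            }
        )
        return model, graph

    def test_full_policy_leaves_no_missing(self, bivariate):
        model, graph = bivariate
        g_full = apply_policy(graph, Policy.full(graph.variables))
        t = sample_population(model, 500, 3)
        ds = apply_missingness(t, g_full, 4)
        assert not ds.proxies.isna().any().any()
        pd.testing.assert_frame_equal(ds.proxies, t)

    def test_constant_link_observed_fraction(self, bivariate):
        model, graph = bivariate
        t = sample_population(model, 10_000, 5)
        ds = apply_missingness(t, graph, 6)
        for v in ("X1", "X2"):
            frac = ds.indicators[v].mean()
            # +- 3 binomial SDs around 0.7
            assert abs(frac - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 10_000)

    def test_masking_reconstruction_is_exact(self, bivariate):
        model, graph = bivariate
        t = sample_population(model, 2_000, 8)
        ds = apply_missingness(t, graph, 9)
        rebuilt = t.where(ds.indicators == 1, other=np.nan)
        pd.testing.assert_frame_equal(rebuilt, ds.proxies)

    def test_counterfactuals_invariant_to_policy(self, bivariate):
        # changing only the availability policy never alters X
        model, graph = bivariate
        t = sample_population(model, 1_000, 10)
        ds_a = apply_missingness(t, graph, 11)
        ds_b = apply_missingness(t, apply_policy(graph, Policy.full(graph.variables)), 11)
        pd.testing.assert_frame_equal(ds_a.counterfactual, ds_b.counterfactual)


class TestCvdCases:
    def test_case1_indicators_exogenous(self):
        _, g = make_cvd_case(1, draw_case_params(1, 0))
        for r in g.indicators:
            assert g.mechanisms[r].link == "constant"
        assert not g.has_selection

    def test_case2_selection_driven_by_outcome(self):
        _, g = make_cvd_case(2, draw_case_params(2, 0))
        assert g.has_selection
        assert g.mechanisms[SELECTION_NODE].parents == ("CVD",)

    def test_case3_bp_indicator_driven_by_covariates(self):
        _, g = make_cvd_case(3, draw_case_params(3, 0))
        assert set(g.mechanisms["R_BP"].parents) == {"age", "BMI"}
        assert g.mechanisms["R_age"].link == "constant"
        assert g.mechanisms["R_BMI"].link == "constant"

    def test_case2_sick_kept_more_often(self):
        params = draw_case_params(2, 1)
        model, g = make_cvd_case(2, params)
        t = sample_population(model, 20_000, 2)
        ds = apply_missingness(t, g, 3)
        kept = ds.selection_mask.astype(bool)
        p_sick = kept[t["CVD"] == 1].mean()
        p_healthy = kept[t["CVD"] == 0].mean()
        assert p_sick > p_healthy

    def test_shared_counterfactual_dag(self):
        import networkx as nx

        graphs = [make_cvd_case(c, draw_case_params(c, 4))[1] for c in (1, 2, 3)]
        for g in graphs[1:]:
            assert nx.utils.graphs_equal(
                g.counterfactual_subgraph(), graphs[0].counterfactual_subgraph()
            )


class TestDrawCaseParams:
    def test_deterministic_given_seed(self):
        assert draw_case_params(2, 42) == draw_case_params(2, 42)

    @pytest.mark.parametrize("case", [1, 2, 3])
    def test_induced_missingness_rates_within_bounds(self, case):
        # recompute marginal missingness rates from a fresh simulation
        for k in range(6):
            params = draw_case_params(case, 100 + k)
            model, g = make_cvd_case(case, params)
            t = sample_population(model, 10_000, 200 + k)
            ds = apply_missingness(t, g, 300 + k)
            for v in ("age", "BMI", "BP"):
                rate = 1.0 - ds.indicators[v].mean()
                assert 0.05 < rate < 0.65, (case, k, v, rate)

    def test_distinct_across_seeds(self):
        draws = {str(draw_case_params(1, s).structural) for s in range(10)}
        assert len(draws) == 10


class TestFixtures:
    def test_example1_proxies_under_each_policy(self):
        assert example1_dataset("init").proxies["X1"].tolist()[:3] == [2.0, 3.0, 4.0]
        assert np.isnan(example1_dataset("init").proxies["X1"].iloc[3])
        new = example1_dataset("new").proxies["X1"]
        assert np.isnan(new.iloc[0]) and np.isnan(new.iloc[1])
        assert new.tolist()[2:] == [4.0, 7.0]
        assert example1_dataset("full").proxies["X1"].tolist() == [2.0, 3.0, 4.0, 7.0]

    def test_nde_fixture_without_direct_effect_restores_equality(self):
        ds = fixture_nde(w=1.0, w0=0.0, n=100_000, seed=0)
        y, r = ds.counterfactual["Y"], ds.indicators["X"]
        assert abs(y[r == 1].mean() - y[r == 0].mean()) < 0.03

    def test_nde_fixture_mixture_mean(self):
        # w=0, w0=2, p=0.5: overall mean(Y) = 0.5 * w0 = 1
        ds = fixture_nde(w=0.0, w0=2.0, n=100_000, seed=1)
        assert abs(ds.counterfactual["Y"].mean() - 1.0) < 0.03
        assert ds.graph.nde_violating

    def test_nde_policy_gap_matches_mixture_form(self):
        # difference between always-measured and collection-policy means
        # is (1 - p) * w0
        w0, p = 1.5, 0.5
        ds = fixture_nde(w=0.0, w0=w0, n=200_000, seed=2, p_obs=p)
        y, r = ds.counterfactual["Y"], ds.indicators["X"]
        gap = y[r == 1].mean() - y.mean()
        assert abs(gap - (1 - p) * w0) < 0.03


class TestStaircase:
    def test_sequential_mechanism_yields_monotone_patterns(self):
        ds = staircase_dataset(2_000, 0)
        assert analyze_patterns(ds.pattern_set()).is_monotone

    def test_exogenous_noise_breaks_monotonicity(self):
        ds = staircase_dataset(2_000, 0)
        rng = np.random.default_rng(1)
        ind = ds.indicators.copy()
        # invalid-entry style drops at random break the nesting
        noise = rng.random(ind.shape) < 0.15
        ind = ind.where(~noise, other=0)
        from misscen.mgraph import PatternSet

        pats = ind.astype(int).apply(tuple, axis=1).value_counts()
        ps = PatternSet(ds.variables, list(pats.index), [int(c) for c in pats])
        assert not analyze_patterns(ps).is_monotone


class TestCsvRoundTrip:
    def test_round_trip_with_indicator_columns(self, tmp_path):
        ds = example1_dataset("init")
        path = tmp_path / "ds.csv"
        write_csv(ds, path, with_indicators=True)
        back = read_csv(path)
        pd.testing.assert_frame_equal(back.proxies, ds.proxies)
        pd.testing.assert_frame_equal(
            back.indicators.astype(int), ds.indicators.astype(int)
        )

    def test_missing_cells_written_empty(self, tmp_path):
        ds = example1_dataset("init")
        path = tmp_path / "ds.csv"
        write_csv(ds, path)
        lines = path.read_text().strip().splitlines()
        # last row is a single missing cell: empty (possibly quoted) field
        assert lines[-1] in ("", '""')
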