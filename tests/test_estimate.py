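"""Complete-case, propensity fitting, IPW, monotone PS, imputation, classifier."""

import numpy as np
import pandas as pd
import pytest

from misscen import (
    Classifier,
    EstimandSpec,
    IncompleteDataset,
    NodeSpec,
    StructuralModel,
    apply_missingness,
    build_graph,
    complete_case_mean,
    evaluate_deployment,
    example1_dataset,
    factorize_propensity,
    fit_propensity,
    impute,
    ipw_mean,
    monotone_propensity,
    sample_population,
    staircase_dataset,
    train_classifier,
)
from misscen.estimate import PropensityFit, _FactorFit


class TestCompleteCaseMean:
    @pytest.mark.parametrize("policy,want", [("init", 3.0), ("full", 4.0), ("new", 5.5)])
    def test_worked_policy_means(self, policy, want):
        assert complete_case_mean(example1_dataset(policy), "X1") == want

    def test_no_observed_entries_raises(self):
        ds = IncompleteDataset(
            proxies=pd.DataFrame({"X": [np.nan, np.nan]}),
            indicators=pd.DataFrame({"X": [0, 0]}),
        )
        with pytest.raises(ValueError, match="observed"):
            complete_case_mean(ds, "X")


def _mcar_dataset(p=0.8, n=5_000, seed=0):
    g = build_graph(
        {
            "variables": ["X"],
            "edges": [],
            "mechanisms": {"R_X": {"parents": [], "link": "constant", "probability": p}},
        }
    )
    m = StructuralModel({"X": NodeSpec((), "linear_gaussian", 0.0, (), 1.0)})
    t = sample_population(m, n, seed)
    return apply_missingness(t, g, seed + 1), g


class TestFitPropensity:
    def test_intercept_only_factor_is_empirical_frequency(self):
        ds, g = _mcar_dataset(p=0.8)
        fit = fit_propensity(ds, factorize_propensity(g))
        ps = fit.predict(ds)
        assert np.allclose(ps, ds.indicators["X"].mean())

    def test_logistic_factor_recovers_generating_coefficients(self, fig3a):
        # R_X2 ~ sigmoid(1 + 2 * X1): recovery within +-0.15 at n = 10^4
        rng = np.random.default_rng(0)
        n = 10_000
        x1 = rng.normal(0, 1, n)
        t = pd.DataFrame({"X1": x1, "X2": x1 + rng.normal(0, 1, n)})
        g = build_graph(
            {
                "variables": ["X1", "X2"],
                "edges": [["X1", "X2"]],
                "mechanisms": {
                    "R_X1": {"parents": [], "link": "constant", "probability": 1.0},
                    "R_X2": {
                        "parents": ["X1"],
                        "link": "logistic",
                        "intercept": 1.0,
                        "weights": [2.0],
                    },
                },
            }
        )
        ds = apply_missingness(t, g, 1)
        fit = fit_propensity(ds, factorize_propensity(g))
        logit = next(f for f in fit.factor_fits if f.model is not None)
        assert abs(logit.model.intercept_[0] - 1.0) < 0.15
        assert abs(logit.model.coef_[0][0] - 2.0) < 0.15

    def test_two_factor_structure_for_worked_graph(self, fig3a):
        rng = np.random.default_rng(2)
        n = 2_000
        x1 = rng.normal(0, 1, n)
        t = pd.DataFrame({"X1": x1, "X2": x1 + rng.normal(0, 1, n)})
        ds = apply_missingness(t, fig3a, 3)
        fit = fit_propensity(ds, factorize_propensity(fig3a))
        kinds = sorted("constant" if f.constant is not None else "logistic"
                       for f in fit.factor_fits)
        assert kinds == ["constant", "logistic"]

    def test_unidentifiable_expression_rejected(self, self_masking_graph):
        expr = factorize_propensity(self_masking_graph)
        ds, _ = _mcar_dataset()
        with pytest.raises(ValueError, match="identifiable"):
            fit_propensity(ds, expr)


class TestIpwMean:
    def test_hand_computed_two_stratum_population(self):
        # 8 rows: X=0 stratum fully observed, X=1 stratum half observed;
        # weighting by the true availability probabilities restores the
        # population mean 0.5
        values = [0, 0, 0, 0, 1, 1, 1, 1]
        observed = [1, 1, 1, 1, 1, 1, 0, 0]
        ds = IncompleteDataset(
            proxies=pd.DataFrame({"X": [v if r else np.nan for v, r in zip(values, observed)]}),
            indicators=pd.DataFrame({"X": observed}),
        )
        ps = np.array([1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.5])

        class OracleFit:
            clip_lo = 0.01

            def predict(self, _):
                return ps

        assert ipw_mean(ds, "X", OracleFit()) == pytest.approx(0.5)

    def test_unit_propensity_equals_sample_mean_bitwise(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        ds = IncompleteDataset(
            proxies=pd.DataFrame({"X": x}), indicators=pd.DataFrame({"X": np.ones(100, int)})
        )
        fit = PropensityFit([_FactorFit("R_X", (), (), constant=1.0)])
        assert ipw_mean(ds, "X", fit) == float(np.sum(x) / 100)
        assert ipw_mean(ds, "X", fit) == complete_case_mean(ds, "X")


class TestMonotonePropensity:
    def test_covariate_free_staircase_recovers_complete_probability(self):
        ds = staircase_dataset(10_000, 0, pattern_probs=(0.7, 0.1, 0.1, 0.1))
        mp = monotone_propensity(ds)
        complete = ds.complete_rows()
        assert abs(mp.ps[complete].mean() - 0.7) < 0.02

    def test_pattern_probabilities_sum_to_one(self):
        ds = staircase_dataset(5_000, 1)
        mp = monotone_propensity(ds)
        complete = ds.complete_rows()
        sums = mp.pattern_probs.loc[complete].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_single_complete_pattern_gives_unit_ps(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"A": rng.normal(size=50), "B": rng.normal(size=50)})
        ds = IncompleteDataset(
            proxies=t, indicators=pd.DataFrame(np.ones((50, 2), int), columns=["A", "B"])
        )
        mp = monotone_propensity(ds)
        assert (mp.ps == 1.0).all()

    def test_non_monotone_input_refused(self):
        proxies = pd.DataFrame({"A": [1.0, np.nan, 1.0], "B": [np.nan, 1.0, 1.0]})
        ds = IncompleteDataset(proxies=proxies, indicators=(~proxies.isna()).astype(int))
        with pytest.raises(ValueError, match="monotone"):
            monotone_propensity(ds)

    def test_covariate_driven_dropout_makes_ps_increase_with_driver(self):
        # dropout hazard increases with X1, so completeness probability
        # decreases in X1
        ds = staircase_dataset(10_000, 2, dropout_slope=1.0)
        mp = monotone_propensity(ds)
        complete = ds.complete_rows()
        x1 = ds.proxies.loc[complete, "X1"]
        lo = mp.ps[complete][x1 < x1.quantile(0.3)].mean()
        hi = mp.ps[complete][x1 > x1.quantile(0.7)].mean()
        assert lo > hi

    def test_matches_generating_hazard_curve(self):
        # with the X1-tilted sequential mechanism the estimated PS should
        # track the generating completeness probability pointwise
        ds = staircase_dataset(10_000, 3, dropout_slope=0.8)
        mp = monotone_propensity(ds)
        complete = ds.complete_rows().to_numpy()
        # generating PS: product of (1 - hazard_j(x1)) over the three stages
        x1 = ds.proxies["X1"].to_numpy()
        probs = (0.7, 0.1, 0.1, 0.1)
        surv, truth = 1.0, np.ones_like(x1)
        for j in (3, 2, 1):
            base = probs[j] / surv
            eta = np.log(base / (1 - base)) + 0.8 * x1
            truth *= 1 - 1 / (1 + np.exp(-eta))
            surv -= probs[j]
        err = np.abs(mp.ps.to_numpy()[complete] - truth[complete])
        assert np.quantile(err, 0.9) < 0.05


class TestImpute:
    def test_complete_input_identity(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame({"A": rng.normal(size=30), "B": rng.normal(size=30)})
        ds = IncompleteDataset(proxies=t, indicators=pd.DataFrame(np.ones((30, 2), int),
                                                                  columns=["A", "B"]))
        pd.testing.assert_frame_equal(impute(ds, "column_mean"), t)

    def test_column_mean_on_worked_fixture(self):
        filled = impute(example1_dataset("init"), "column_mean")
        assert filled["X1"].tolist() == [2.0, 3.0, 4.0, 3.0]

    @pytest.mark.parametrize("method", ["column_mean", "iterative_forest"])
    def test_observed_cells_bit_identical(self, method):
        ds = _bivariate_mcar(n=300, seed=7)
        filled = impute(ds, method, seed=8)
        mask = ds.proxies.notna().to_numpy()
        assert np.array_equal(
            filled.to_numpy()[mask], ds.proxies.to_numpy()[mask]
        )

    def test_forest_beats_column_mean_on_correlated_data(self):
        # strongly correlated bivariate Gaussian, 30% missing at random:
        # conditional-mean style imputation must reduce RMSE
        wins = 0
        for rep in range(5):
            ds = _bivariate_mcar(n=2_000, seed=20 + rep, rho=0.9)
            truth = ds.counterfactual
            mask = ds.proxies.isna()
            rmse = {}
            for method in ("column_mean", "iterative_forest"):
                filled = impute(ds, method, seed=rep)
                err = (filled - truth)[mask]
                rmse[method] = float(np.sqrt(np.nanmean(np.square(err.to_numpy()))))
            wins += rmse["iterative_forest"] < rmse["column_mean"]
        assert wins >= 4

    def test_all_missing_column_rejected(self):
        ds = IncompleteDataset(
            proxies=pd.DataFrame({"A": [1.0, 2.0], "B": [np.nan, np.nan]}),
            indicators=pd.DataFrame({"A": [1, 1], "B": [0, 0]}),
        )
        with pytest.raises(ValueError, match="no observed"):
            impute(ds, "column_mean")


def _bivariate_mcar(n, seed, rho=0.9, p_miss=0.3):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rho * a + np.sqrt(1 - rho**2) * rng.normal(size=n)
    t = pd.DataFrame({"A": a, "B": b})
    ind = pd.DataFrame(rng.random((n, 2)) > p_miss, columns=["A", "B"]).astype(int)
    # keep at least one observed value per column
    ind.iloc[0] = 1
    proxies = t.where(ind == 1, other=np.nan)
    return IncompleteDataset(proxies=proxies, indicators=ind, counterfactual=t)


class TestClassifier:
    def test_separable_data_perfect_training_accuracy(self):
        t = pd.DataFrame({"X": [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0], "Y": [0, 0, 0, 1, 1, 1]})
        c = train_classifier(t, "Y")
        assert (c.predict(t) == t["Y"].to_numpy()).all()

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(9)
        n = 10_000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.random(n) < p).astype(int)
        c = train_classifier(pd.DataFrame({"X": x, "Y": y}), "Y")
        assert abs(c.intercept - 0.5) < 0.1
        assert abs(c.weights[0] - 1.2) < 0.1

    def test_single_class_target_rejected(self):
        t = pd.DataFrame({"X": [1.0, 2.0], "Y": [1, 1]})
        with pytest.raises(ValueError, match="single class"):
            train_classifier(t, "Y")


class TestEmpiricalLoss:
    def test_factual_and_shifted_losses_reflect_their_policies(self):
        # a classifier relying on X loses accuracy when the deployment
        # policy masks the informative stratum (mean imputation washes it
        # out), so the shifted loss exceeds the factual one
        from misscen import empirical_loss

        rng = np.random.default_rng(12)
        n = 4_000
        x = rng.normal(size=n)
        y = (x > 0).astype(float)
        t = pd.DataFrame({"X": x, "Y": y})

        def masked(ind_x):
            ind = pd.DataFrame({"X": ind_x, "Y": np.ones(n, int)})
            return IncompleteDataset(proxies=t.where(ind == 1, np.nan), indicators=ind)

        collection = masked((rng.random(n) < 0.9).astype(int))
        deployment = masked((x < 0.5).astype(int))  # masks most positives
        c = Classifier(features=("X",), weights=(50.0,), intercept=0.0)
        spec_f = EstimandSpec(kind="factual_loss", target="Y")
        spec_s = EstimandSpec(kind="shifted_loss", target="Y")
        assert empirical_loss(c, deployment, spec_s) > empirical_loss(
            c, collection, spec_f
        )

    def test_wrong_kind_rejected(self):
        from misscen import empirical_loss

        ds = example1_dataset("full")
        c = Classifier(features=("X1",), weights=(1.0,), intercept=0.0)
        with pytest.raises(ValueError, match="factual"):
            empirical_loss(c, ds, EstimandSpec(kind="full_policy_accuracy", target="X1"))


class TestEvaluateDeployment:
    def _spec(self):
        return EstimandSpec(kind="full_policy_accuracy", target="Y")

    def test_perfect_classifier_scores_one_everywhere(self):
        rng = np.random.default_rng(10)
        n = 400
        x = rng.normal(size=n)
        y = (x > 0).astype(float)
        t = pd.DataFrame({"X": x, "Y": y})
        ind = pd.DataFrame({"X": rng.integers(0, 2, n), "Y": np.ones(n, int)})
        ds = IncompleteDataset(proxies=t.where(ind == 1, np.nan), indicators=ind,
                               counterfactual=t)
        c = Classifier(features=("X",), weights=(100.0,), intercept=0.0)
        est, truth = evaluate_deployment(c, ds, self._spec(), "cca")
        assert est == 1.0 and truth == 1.0

    def test_mcar_complete_cases_estimate_truth(self):
        rng = np.random.default_rng(11)
        n = 4_000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-1.5 * x))
        y = (rng.random(n) < p).astype(float)
        t = pd.DataFrame({"X": x, "Y": y})
        ind = pd.DataFrame({"X": (rng.random(n) < 0.6).astype(int), "Y": np.ones(n, int)})
        ds = IncompleteDataset(proxies=t.where(ind == 1, np.nan), indicators=ind,
                               counterfactual=t)
        c = train_classifier(t, "Y")
        est, truth = evaluate_deployment(c, ds, self._spec(), "cca")
        n_complete = int(ind["X"].sum())
        se = np.sqrt(truth * (1 - truth) / n_complete)
        assert abs(est - truth) < 3 * se
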