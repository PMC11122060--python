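"""Estimators for incomplete health data: complete-case, IPW, imputation.

Implements the estimation step of the pipeline: complete-case statistics,
maximum-likelihood fitting of the factorized propensity score on observed
``(X*, R)`` data, the inverse-probability-weighted mean

    theta_hat = (1/N) * sum_i  1{r_i = 1} * theta(x_i) / PS(x_i),

a sequential-hazard propensity estimator for monotone missingness
patterns, pluggable imputation (column mean and iterative random-forest),
and training plus deployment-metric evaluation of a linear-logistic
classifier under the full-availability policy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression

from .identify import PropensityExpression
from .mgraph import analyze_patterns, proxy_name
from .simulate import IncompleteDataset

__all__ = [
    "DEFAULT_CLIP_LO",
    "PropensityFit",
    "Classifier",
    "EstimandSpec",
    "MonotonePropensity",
    "complete_case_mean",
    "fit_propensity",
    "ipw_mean",
    "monotone_propensity",
    "impute",
    "train_classifier",
    "evaluate_deployment",
    "empirical_loss",
]

logger = logging.getLogger("misscen")

DEFAULT_CLIP_LO = 0.01
_SEPARATION_COEF = 15.0


def complete_case_mean(ds: IncompleteDataset, var: str) -> float:
    """Arithmetic mean of ``var`` over the rows where it is observed."""
    observed = ds.indicators[var] == 1
    if not observed.any():
        raise ValueError(f"no observed entries for {var!r}")
    return float(ds.proxies.loc[observed, var].mean())


# ---------------------------------------------------------------------------
# Propensity fitting and IPW


@dataclass
class _FactorFit:
    indicator: str
    given_indicators: tuple[str, ...]
    given_variables: tuple[str, ...]
    constant: float | None = None
    model: LogisticRegression | None = None


@dataclass
class PropensityFit:
    """One fitted probabilistic model per factor of a propensity expression."""

    factor_fits: list[_FactorFit]
    clip_lo: float = DEFAULT_CLIP_LO
    clipped_rows: int = 0

    def predict(self, ds: IncompleteDataset) -> np.ndarray:
        """PS per row; NaN where a factor's conditioning proxies are missing."""
        n = ds.n_rows
        ps = np.ones(n)
        for f in self.factor_fits:
            if f.constant is not None:
                ps = ps * f.constant
                continue
            feats = ds.proxies[list(f.given_variables)].to_numpy(dtype=float)
            ok = ~np.isnan(feats).any(axis=1)
            prob = np.full(n, np.nan)
            if ok.any():
                prob[ok] = f.model.predict_proba(feats[ok])[:, 1]
            ps = ps * prob
        clipped = ps < self.clip_lo
        n_clip = int(np.nansum(clipped))
        if n_clip:
            self.clipped_rows += n_clip
            logger.info("propensity clipping: %d rows below %.3g", n_clip, self.clip_lo)
        return np.clip(ps, self.clip_lo, 1.0)


def _fit_logistic(features: np.ndarray, target: np.ndarray) -> LogisticRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, max_iter=2000)
        model.fit(features, target)
    if np.abs(model.coef_).max() > _SEPARATION_COEF:
        warnings.warn("separation detected in propensity factor; refitting with L2 penalty")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = LogisticRegression(C=1.0, max_iter=2000)
            model.fit(features, target)
    return model


def fit_propensity(
    ds: IncompleteDataset,
    expr: PropensityExpression,
    clip_lo: float = DEFAULT_CLIP_LO,
) -> PropensityFit:
    """Fit each factor of an identifiable propensity expression from (X*, R).

    Constant factors become empirical observation frequencies over the
    rows where the factor's conditioning indicators are 1; conditional
    factors are maximum-likelihood logistic regressions of the indicator
    on the stated proxies over the same subsample.
    """
    if not expr.identifiable:
        raise ValueError(f"expression is not identifiable: {expr.failure_reason}")
    fits: list[_FactorFit] = []
    for f in expr.factors:
        cond = np.ones(ds.n_rows, dtype=bool)
        for r in f.given_indicators:
            var = r[2:]  # indicator name is "R_<var>"
            cond &= ds.indicators[var].to_numpy() == 1
        if not cond.any():
            raise ValueError(f"empty fitting subsample for factor {f.formula()}")
        var = f.indicator[2:]
        target = ds.indicators.loc[cond, var].to_numpy()
        if not f.given_variables:
            fits.append(
                _FactorFit(
                    f.indicator, f.given_indicators, f.given_variables,
                    constant=float(target.mean()),
                )
            )
            continue
        feats = ds.proxies.loc[cond, list(f.given_variables)].to_numpy(dtype=float)
        ok = ~np.isnan(feats).any(axis=1)
        if not ok.any():
            raise ValueError(f"empty fitting subsample for factor {f.formula()}")
        if len(np.unique(target[ok])) < 2:
            fits.append(
                _FactorFit(
                    f.indicator, f.given_indicators, f.given_variables,
                    constant=float(target[ok].mean()),
                )
            )
            continue
        model = _fit_logistic(feats[ok], target[ok])
        fits.append(_FactorFit(f.indicator, f.given_indicators, f.given_variables, model=model))
    return PropensityFit(factor_fits=fits, clip_lo=clip_lo)


def ipw_mean(
    ds: IncompleteDataset,
    var: str,
    fit: PropensityFit,
    selection_probs: np.ndarray | None = None,
) -> float:
    """Inverse-probability-weighted mean of ``var`` over complete rows.

    Each complete row is weighted by 1/PS; the sum is divided by the total
    row count N (including incomplete rows). When a per-row selection
    probability is supplied (whole-row omission with a known, externally
    supplied model), rows are additionally weighted by the inverse
    selection probability and N is replaced by its selection-adjusted
    estimate ``sum_i 1/s_i``.
    """
    complete = ds.complete_rows().to_numpy()
    ps = fit.predict(ds)
    if selection_probs is not None:
        s = np.asarray(selection_probs, dtype=float)
        n_eff = float(np.sum(1.0 / s))
        w = 1.0 / (ps * s)
    else:
        n_eff = float(ds.n_rows)
        w = 1.0 / ps
    values = ds.proxies[var].to_numpy(dtype=float)
    return float(np.sum(values[complete] * w[complete]) / n_eff)


# ---------------------------------------------------------------------------
# Monotone-pattern propensity (sequential hazards)


@dataclass
class MonotonePropensity:
    """Per-row propensity of completeness under a monotone pattern set.

    Built by sequential hazards: for each non-complete pattern, one
    membership model predicts stopping at that prefix depth given the
    covariates observed within the pattern; the per-row pattern
    probabilities are cascade products of the hazards and sum to one, and
    PS is the complete-pattern probability 1 - sum of the others.
    """

    ordering: tuple[str, ...]
    ps: pd.Series
    pattern_probs: pd.DataFrame


def monotone_propensity(ds: IncompleteDataset) -> MonotonePropensity:
    pattern_set = ds.pattern_set()
    report = analyze_patterns(pattern_set)
    if not report.is_monotone:
        raise ValueError(
            "patterns are not monotone; use factorize_propensity / fit_propensity instead"
        )
    ordering = report.ordering
    d = len(ordering)
    ind = ds.indicators[list(ordering)].to_numpy()
    length = ind.sum(axis=1).astype(int)  # prefix depth observed per row
    # sanity: prefix structure
    stages = sorted(set(int(x) for x in length if x < d))

    n = ds.n_rows
    surv = np.ones(n)
    prob_cols: dict[str, np.ndarray] = {}
    for L in stages:
        at_risk = length >= L
        stop = (length == L).astype(int)
        feats_vars = list(ordering[:L])
        if feats_vars:
            feats = ds.proxies[feats_vars].to_numpy(dtype=float)
            can_eval = ~np.isnan(feats).any(axis=1)
        else:
            feats = None
            can_eval = np.ones(n, dtype=bool)
        fit_rows = at_risk & can_eval
        hazard = np.full(n, np.nan)
        y = stop[fit_rows]
        if feats is None or len(np.unique(y)) < 2:
            hazard[can_eval] = float(y.mean())
        else:
            model = _fit_logistic(feats[fit_rows], y)
            hazard[can_eval] = model.predict_proba(feats[can_eval])[:, 1]
        prob_cols[f"S_len{L}"] = hazard * surv
        surv = surv * (1.0 - hazard)
    prob_cols["S_complete"] = surv
    probs = pd.DataFrame(prob_cols, index=ds.proxies.index)
    return MonotonePropensity(
        ordering=ordering,
        ps=pd.Series(surv, index=ds.proxies.index, name="PS"),
        pattern_probs=probs,
    )


# ---------------------------------------------------------------------------
# Imputation


_MAX_FOREST_ROUNDS = 10
_FOREST_SIZE = 100


def impute(ds: IncompleteDataset, method: str = "column_mean", seed: int = 0) -> pd.DataFrame:
    """Fill missing entries; observed cells are returned bit-identical.

    ``column_mean`` fills each hole with its column's observed mean.
    ``iterative_forest`` runs round-robin random-forest regression (or
    classification for binary columns), refreshing each incomplete column
    from the others until the total squared change between successive
    rounds stops decreasing, up to 10 rounds.
    """
    proxies = ds.proxies
    for v in proxies.columns:
        if proxies[v].isna().all():
            raise ValueError(f"column {v!r} has no observed values")
    if method == "column_mean":
        return proxies.fillna(proxies.mean())
    if method != "iterative_forest":
        raise ValueError(f"unknown imputation method {method!r}")

    rng = np.random.default_rng(seed)
    filled = proxies.fillna(proxies.mean()).copy()
    missing_cols = [v for v in proxies.columns if proxies[v].isna().any()]
    # fewest missing first: better-supported columns stabilize earlier
    missing_cols.sort(key=lambda v: int(proxies[v].isna().sum()))
    masks = {v: proxies[v].isna().to_numpy() for v in missing_cols}
    binary = {
        v: set(np.unique(proxies[v].dropna())) <= {0.0, 1.0} for v in missing_cols
    }

    prev_change = np.inf
    snapshot = filled.copy()
    for _ in range(_MAX_FOREST_ROUNDS):
        change = 0.0
        for v in missing_cols:
            mask = masks[v]
            others = [c for c in proxies.columns if c != v]
            x_obs = filled.loc[~mask, others].to_numpy()
            y_obs = filled.loc[~mask, v].to_numpy()
            x_mis = filled.loc[mask, others].to_numpy()
            est_cls = RandomForestClassifier if binary[v] else RandomForestRegressor
            forest = est_cls(
                n_estimators=_FOREST_SIZE,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(x_obs, y_obs.astype(int) if binary[v] else y_obs)
            pred = forest.predict(x_mis).astype(float)
            old = filled.loc[mask, v].to_numpy()
            change += float(np.sum((pred - old) ** 2))
            filled.loc[mask, v] = pred
        if change >= prev_change:
            filled = snapshot  # keep the better (previous) round
            break
        prev_change = change
        snapshot = filled.copy()
    # observed entries must be untouched
    filled[proxies.notna()] = proxies
    return filled


# ---------------------------------------------------------------------------
# Classifier training and deployment evaluation


@dataclass(frozen=True)
class Classifier:
    """Linear-logistic decision rule with its training descriptor."""

    features: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float
    trained_on: str = ""

    def decision(self, table: pd.DataFrame) -> np.ndarray:
        x = table[list(self.features)].to_numpy(dtype=float)
        return self.intercept + x @ np.asarray(self.weights)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(table)))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.decision(table) >= 0.0).astype(int)


def train_classifier(
    table: pd.DataFrame, target: str, seed: int = 0, trained_on: str = ""
) -> Classifier:
    """Maximum-likelihood logistic regression of ``target`` on the rest."""
    y = table[target].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"target {target!r} has a single class; cannot train")
    features = tuple(c for c in table.columns if c != target)
    x = table[list(features)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, max_iter=2000, random_state=seed)
        model.fit(x, y.astype(int))
    return Classifier(
        features=features,
        weights=tuple(float(w) for w in model.coef_[0]),
        intercept=float(model.intercept_[0]),
        trained_on=trained_on,
    )


@dataclass(frozen=True)
class EstimandSpec:
    """What is being estimated, under which deployment policy.

    kinds: ``counterfactual_mean`` (mean of a variable had it always been
    available), ``factual_loss`` (MSE under the collection policy),
    ``shifted_loss`` (MSE under a new policy), ``full_policy_accuracy``
    (classification accuracy when deployment observes everything; for
    binary labels and hard predictions this is 1 - MSE).
    """

    kind: str
    target: str
    policy: str = "full"

    def __post_init__(self):
        kinds = ("counterfactual_mean", "factual_loss", "shifted_loss", "full_policy_accuracy")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")


def _accuracy(c: Classifier, table: pd.DataFrame, target: str) -> float:
    pred = c.predict(table)
    y = table[target].to_numpy(dtype=float)
    return float(np.mean(pred == y))


def empirical_loss(
    c: Classifier, ds: IncompleteDataset, spec: EstimandSpec, seed: int = 0
) -> float:
    """MSE of hard predictions under the policy that generated ``ds``.

    ``factual_loss`` scores the model under the collection policy;
    ``shifted_loss`` is the same computation on a dataset simulated under
    the deployment policy — both are direct empirical means over
    mean-imputed available covariates, no per-pattern submodels.
    """
    if spec.kind not in ("factual_loss", "shifted_loss"):
        raise ValueError("empirical_loss handles the factual/shifted MSE estimands")
    completed = impute(ds, method="column_mean", seed=seed)
    pred = c.predict(completed).astype(float)
    y = completed[spec.target].to_numpy(dtype=float)
    return float(np.mean((y - pred) ** 2))


def evaluate_deployment(
    c: Classifier,
    ds: IncompleteDataset,
    spec: EstimandSpec,
    method: str,
    fit: PropensityFit | None = None,
    selection_probs: np.ndarray | None = None,
    impute_method: str = "iterative_forest",
    seed: int = 0,
) -> tuple[float, float | None]:
    """Estimate the full-policy accuracy of ``c`` and, in simulation, its truth.

    ``cca`` scores complete rows only; ``impute_then_score`` scores the
    imputed table; ``ipw`` computes the propensity-weighted accuracy over
    complete rows. Ground truth (accuracy on the full counterfactual
    table, including rows removed by selection) is available only when the
    dataset was simulated.
    """
    if spec.kind != "full_policy_accuracy":
        raise ValueError("evaluate_deployment handles the full-policy accuracy estimand")
    target = spec.target
    truth = None
    if ds.counterfactual is not None:
        truth = _accuracy(c, ds.counterfactual, target)

    if method == "cca":
        complete = ds.complete_rows()
        estimate = _accuracy(c, ds.proxies.loc[complete], target)
    elif method == "impute_then_score":
        completed = impute(ds, method=impute_method, seed=seed)
        estimate = _accuracy(c, completed, target)
    elif method == "ipw":
        if fit is None:
            raise ValueError("ipw evaluation requires a PropensityFit")
        complete = ds.complete_rows().to_numpy()
        ps = fit.predict(ds)
        correct = (
            c.predict(ds.proxies) == ds.proxies[target].to_numpy(dtype=float)
        ).astype(float)
        if selection_probs is not None:
            s = np.asarray(selection_probs, dtype=float)
            n_eff = float(np.sum(1.0 / s))
            w = 1.0 / (ps * s)
        else:
            n_eff = float(ds.n_rows)
            w = 1.0 / ps
        estimate = float(np.sum(correct[complete] * w[complete]) / n_eff)
    else:
        raise ValueError(f"unknown method {method!r}")
    return estimate, truth
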