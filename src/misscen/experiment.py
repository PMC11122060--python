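"""The simulation study: scenario cases x estimands x methods x iterations.

For each of the three cardiovascular scenario cases, each iteration draws
fresh structural and mechanism coefficients from the documented search
space, simulates a cohort, induces the case's missingness, and computes
two estimands — the counterfactual mean systolic BP and the deployment
classification accuracy of a per-iteration logistic CVD classifier — by
three methods: complete-case analysis, iterative random-forest imputation,
and inverse probability weighting with graph-derived propensities (the
selection case additionally receives the externally supplied, in
simulation oracle, visit model). Biases are reported against the
simulated ground truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .estimate import (
    DEFAULT_CLIP_LO,
    EstimandSpec,
    complete_case_mean,
    evaluate_deployment,
    fit_propensity,
    impute,
    ipw_mean,
    train_classifier,
    _accuracy,
)
from .identify import factorize_propensity, without_selection
from .mgraph import SELECTION_NODE
from .simulate import (
    DEFAULT_SEARCH_SPACE,
    SearchSpace,
    apply_missingness,
    draw_case_params,
    make_cvd_case,
    sample_population,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "summarize"]

logger = logging.getLogger("misscen")

METHODS = ("cca", "missforest", "ipw")
ESTIMANDS = ("mean_bp", "accuracy")

# child seeds advance by a fixed stride so iterations never share streams
_SEED_STRIDE = 10007


@dataclass(frozen=True)
class ExperimentConfig:
    cases: tuple[int, ...] = (1, 2, 3)
    iterations: int = 20
    n: int = 2000
    master_seed: int = 0
    clip_lo: float = DEFAULT_CLIP_LO
    search_space: SearchSpace = DEFAULT_SEARCH_SPACE

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not set(self.cases) <= {1, 2, 3}:
            raise ValueError("cases must be a subset of {1, 2, 3}")

    def child_seed(self, case_id: int, iteration: int) -> int:
        return (self.master_seed + _SEED_STRIDE * (iteration * 4 + case_id)) % (2**31 - 1)


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    config: dict

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "records": self.records.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, indent=1, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentResult":
        obj = json.loads(text)
        records = pd.DataFrame(obj["records"])
        order = [
            "case", "iteration", "seed", "estimand", "method",
            "estimate", "ground_truth", "abs_bias", "refused", "log10_abs_bias",
        ]
        records = records[[c for c in order if c in records.columns]]
        return cls(records=records, config=obj["config"])


def _log10_bias(bias: float) -> float:
    return math.log10(max(bias, 1e-12))


def _iterate_once(cfg: ExperimentConfig, case_id: int, iteration: int) -> list[dict]:
    seed = cfg.child_seed(case_id, iteration)
    params = draw_case_params(case_id, seed, cfg.search_space)
    model, g = make_cvd_case(case_id, params)
    table = sample_population(model, cfg.n, seed + 1)
    ds = apply_missingness(table, g, seed + 2)

    truth_bp = float(table["BP"].mean())
    completed_mean = impute(ds, method="column_mean")
    clf = train_classifier(completed_mean, "CVD", seed=seed + 3, trained_on="column_mean")
    truth_acc = _accuracy(clf, table, "CVD")

    # propensity: the selection case gets an external (oracle) visit model
    selection_probs = None
    if case_id == 2:
        expr = factorize_propensity(without_selection(g))
        sel_mech = g.mechanisms[SELECTION_NODE]
        cvd = ds.proxies["CVD"].to_numpy(dtype=float)
        selection_probs = np.array([sel_mech.prob_observed((c,)) for c in cvd])
    else:
        expr = factorize_propensity(g)

    records: list[dict] = []

    def record(estimand, method, estimate, truth, refused=None):
        base = {
            "case": case_id,
            "iteration": iteration,
            "seed": seed,
            "estimand": estimand,
            "method": method,
        }
        if refused is not None:
            base.update(estimate=None, ground_truth=truth, abs_bias=None, refused=refused)
        else:
            bias = abs(estimate - truth)
            base.update(
                estimate=float(estimate),
                ground_truth=float(truth),
                abs_bias=float(bias),
                refused=None,
            )
            if estimand == "mean_bp":
                base["log10_abs_bias"] = _log10_bias(bias)
        records.append(base)

    completed_forest = impute(ds, method="iterative_forest", seed=seed + 4)

    # --- estimand 1: counterfactual mean BP
    record("mean_bp", "cca", complete_case_mean(ds, "BP"), truth_bp)
    record("mean_bp", "missforest", float(completed_forest["BP"].mean()), truth_bp)
    if expr.identifiable:
        fit = fit_propensity(ds, expr, clip_lo=cfg.clip_lo)
        record("mean_bp", "ipw", ipw_mean(ds, "BP", fit, selection_probs), truth_bp)
    else:
        fit = None
        record("mean_bp", "ipw", None, truth_bp, refused=expr.failure_reason)

    # --- estimand 2: deployment classification accuracy
    acc_spec = EstimandSpec(kind="full_policy_accuracy", target="CVD")
    est, _ = evaluate_deployment(clf, ds, acc_spec, "cca")
    record("accuracy", "cca", est, truth_acc)
    record("accuracy", "missforest", _accuracy(clf, completed_forest, "CVD"), truth_acc)
    if fit is not None:
        est, _ = evaluate_deployment(
            clf, ds, acc_spec, "ipw", fit=fit, selection_probs=selection_probs
        )
        record("accuracy", "ipw", est, truth_acc)
    else:
        record("accuracy", "ipw", None, truth_acc, refused=expr.failure_reason)
    return records


def run_experiment(cfg: ExperimentConfig = ExperimentConfig()) -> ExperimentResult:
    """Run the full study; deterministic given the master seed."""
    rows: list[dict] = []
    for iteration in range(cfg.iterations):
        for case_id in cfg.cases:
            logger.info("case %d iteration %d", case_id, iteration)
            rows.extend(_iterate_once(cfg, case_id, iteration))
    records = pd.DataFrame(rows)
    snapshot = {
        "cases": list(cfg.cases),
        "iterations": cfg.iterations,
        "n": cfg.n,
        "master_seed": cfg.master_seed,
        "clip_lo": cfg.clip_lo,
        "search_space": asdict(cfg.search_space),
    }
    return ExperimentResult(records=records, config=snapshot)


def summarize(result: ExperimentResult, figure_path=None) -> pd.DataFrame:
    """Aggregate absolute biases per case x method x estimand.

    Columns: median, IQR and max of the absolute bias, plus the median
    log10 absolute bias for the mean-BP estimand. Optionally writes a
    box-plot figure of the per-iteration biases.
    """
    rec = result.records
    if rec.empty:
        raise ValueError("empty experiment result")
    ok = rec[rec["abs_bias"].notna()]
    rows = []
    for (estimand, case, method), grp in ok.groupby(["estimand", "case", "method"]):
        b = grp["abs_bias"].to_numpy(dtype=float)
        row = {
            "estimand": estimand,
            "case": case,
            "method": method,
            "median_abs_bias": float(np.median(b)),
            "iqr_abs_bias": float(np.percentile(b, 75) - np.percentile(b, 25)),
            "max_abs_bias": float(np.max(b)),
        }
        if estimand == "mean_bp":
            row["median_log10_abs_bias"] = float(
                np.median(grp["log10_abs_bias"].to_numpy(dtype=float))
            )
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values(["estimand", "case", "method"]).reset_index(drop=True)

    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        for ax, estimand, label in zip(
            axes, ESTIMANDS, ("abs bias of mean BP (log10)", "abs bias of accuracy")
        ):
            sub = ok[ok["estimand"] == estimand]
            data, ticks = [], []
            for case in sorted(sub["case"].unique()):
                for method in METHODS:
                    vals = sub[(sub["case"] == case) & (sub["method"] == method)]["abs_bias"]
                    if estimand == "mean_bp":
                        vals = np.log10(np.maximum(vals.to_numpy(dtype=float), 1e-12))
                    data.append(np.asarray(vals, dtype=float))
                    ticks.append(f"c{case}\n{method}")
            ax.boxplot(data)
            ax.set_xticklabels(ticks, fontsize=7)
            ax.set_title(label)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return summary
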