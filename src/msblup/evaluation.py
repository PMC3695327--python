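"""Accuracy scoring and the replicated model-comparison study.

Accuracy is the Pearson correlation between predicted and true (simulated)
genetic values over a stated subset of individuals.  The study runner
simulates replicates of a scenario, fits the requested models on the
training-cohort phenotypes at the variances implied by the scenario, and
aggregates accuracies on the training cohorts and the target (last) cohort.

Variance components handed to the fitters are the *known* simulation values:
the total genetic variance h2 * V_p for the single-component models (II uses
it as sigma_u2, M spreads it over the markers), and the scenario's
infinitesimal/QTL split for the two-component models (MI and MS use
sigma_poly2 for the individual term and spread sigma_qtl2 over the markers).
Marker variance uses sigma2 / (2 sum p(1-p)) with allele frequencies taken
from the training individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .blup_models import (ModelFit, fit_model_II, fit_model_M, fit_model_MI,
                          fit_model_MS)
from .marker_data import VarianceComponents, allele_frequencies, \
    marker_variance_from_additive
from .simulator import SimScenario, TruthSet, run_scenario, scenario_with

__all__ = [
    "StudyResult",
    "accuracy",
    "scenario_variances",
    "fit_truthset",
    "replicate_study",
    "relative_accuracy",
    "paired_significance",
]

logger = logging.getLogger(__name__)

MODELS = ("II", "M", "MI", "MS")
SUBSETS = ("training", "test")


@dataclass
class StudyResult:
    """Replicated accuracies and their aggregates.

    ``per_replicate`` has columns (replicate, seed, model, subset, accuracy);
    ``summary`` has one row per model x subset with mean, se and n.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def mean_accuracy(self, model: str, subset: str) -> float:
        row = self.summary[(self.summary["model"] == model)
                           & (self.summary["subset"] == subset)]
        if row.empty:
            raise KeyError(f"no aggregate for model={model}, subset={subset}")
        return float(row["mean_accuracy"].iloc[0])

    def accuracies(self, model: str, subset: str) -> np.ndarray:
        df = self.per_replicate
        sel = df[(df["model"] == model) & (df["subset"] == subset)]
        return sel.sort_values("replicate")["accuracy"].to_numpy()


def accuracy(u_hat, u_true, subset=None) -> float:
    """Pearson correlation between predictions and truth on a subset.

    ``subset`` is an index/boolean selector into both vectors (default all).
    Returns NaN with a warning if either vector is constant on the subset.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    u_true = np.asarray(u_true, dtype=float)
    if subset is not None:
        u_hat, u_true = u_hat[subset], u_true[subset]
    if u_hat.size < 3:
        raise ValueError("accuracy needs at least 3 individuals")
    if u_hat.std() == 0 or u_true.std() == 0:
        logger.warning("accuracy undefined: zero variance in subset")
        return float("nan")
    return float(np.corrcoef(u_hat, u_true)[0, 1])


def scenario_variances(truth: TruthSet, model: str,
                       frequency_subset: str = "training") -> VarianceComponents:
    """Known-variance components implied by a simulated scenario for a model."""
    scen = truth.scenario
    sigma_g2 = scen.h2 * scen.pheno_var
    subset = None
    if frequency_subset == "training":
        subset = truth.training_ids
    elif frequency_subset == "base":
        subset = truth.ped.base_ids
    p = allele_frequencies(truth.markers, subset)
    if model == "II":
        return VarianceComponents(sigma_u2=sigma_g2, sigma_e2=scen.sigma_e2)
    if model == "M":
        return VarianceComponents(
            sigma_m2=marker_variance_from_additive(sigma_g2, p),
            sigma_e2=scen.sigma_e2,
        )
    if model in ("MI", "MS"):
        return VarianceComponents(
            sigma_u2=scen.sigma_poly2,
            sigma_m2=marker_variance_from_additive(scen.sigma_qtl2, p),
            sigma_e2=scen.sigma_e2,
        )
    raise ValueError(f"unknown model kind: {model}")


def fit_truthset(truth: TruthSet, model: str, ms_design_choice: str = "eq7",
                 frequency_subset: str = "training") -> ModelFit:
    """Fit one model to a simulated replicate's training phenotypes."""
    ids = list(truth.training_ids)
    y = truth.y[truth.use_in_training]
    variance = scenario_variances(truth, model, frequency_subset)
    if model == "II":
        return fit_model_II(y, ids, truth.ped, variance)
    if model == "M":
        return fit_model_M(y, ids, truth.markers, variance)
    if model == "MI":
        return fit_model_MI(y, ids, truth.markers, truth.ped, variance)
    if model == "MS":
        return fit_model_MS(y, ids, truth.markers, truth.ped, variance,
                            design_choice=ms_design_choice)
    raise ValueError(f"unknown model kind: {model}")


def replicate_study(scenario: SimScenario, models=("M", "MS"), n_reps: int = 50,
                    seed: int = 1, ms_design_choice: str = "eq7",
                    max_failure_fraction: float = 0.1,
                    fisher_z: bool = False) -> StudyResult:
    """Simulate ``n_reps`` replicates and score each model on both subsets.

    Replicate r uses seed ``seed + r``.  Training accuracy is computed over
    the phenotyped (training-cohort) individuals, test accuracy over the
    target cohort; base individuals enter neither subset.  A failing
    replicate is dropped with a warning; more than ``max_failure_fraction``
    failures aborts the study.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    rows = []
    failures = []
    for r in range(n_reps):
        rep_seed = seed + r
        try:
            truth = run_scenario(scenario_with(scenario, seed=rep_seed))
            train_mask = truth.use_in_training
            test_mask = truth.is_target
            for model in models:
                fit = fit_truthset(truth, model, ms_design_choice)
                for subset, mask in (("training", train_mask), ("test", test_mask)):
                    rows.append({
                        "replicate": r, "seed": rep_seed, "model": model,
                        "subset": subset,
                        "accuracy": accuracy(fit.u_hat, truth.u_total, mask),
                    })
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            logger.warning("replicate %d (seed %d) failed: %s", r, rep_seed, exc)
            failures.append((r, str(exc)))
    if len(failures) > max_failure_fraction * n_reps:
        raise RuntimeError(
            f"{len(failures)}/{n_reps} replicates failed; first: {failures[0]}"
        )
    per_replicate = pd.DataFrame(rows)

    def _mean(x):
        x = np.asarray(x, dtype=float)
        if fisher_z:
            return float(np.tanh(np.mean(np.arctanh(np.clip(x, -1 + 1e-12,
                                                            1 - 1e-12)))))
        return float(np.mean(x))

    summary_rows = []
    for model in models:
        for subset in SUBSETS:
            acc = per_replicate[(per_replicate["model"] == model)
                                & (per_replicate["subset"] == subset)]["accuracy"]
            acc = acc.dropna().to_numpy()
            summary_rows.append({
                "model": model, "subset": subset, "mean_accuracy": _mean(acc),
                "se": float(np.std(acc, ddof=1) / np.sqrt(len(acc))),
                "n_replicates": int(len(acc)),
            })
    summary = pd.DataFrame(summary_rows)
    result = StudyResult(
        per_replicate=per_replicate, summary=summary,
        metadata={
            "scenario": scenario.__dict__ | {"seed": None},
            "base_seed": seed, "n_reps": n_reps, "models": tuple(models),
            "ms_design_choice": ms_design_choice, "fisher_z": fisher_z,
            "n_failed": len(failures),
        },
    )
    # pairwise paired t-tests on per-replicate accuracies
    pvals = {}
    for subset in SUBSETS:
        for i, a in enumerate(models):
            for b in models[i + 1:]:
                acc_a = result.accuracies(a, subset)
                acc_b = result.accuracies(b, subset)
                pvals[f"{a}_vs_{b}_{subset}"] = (
                    paired_significance(acc_a, acc_b) if acc_a.size >= 3
                    else float("nan")
                )
    result.metadata["p_values"] = pvals
    return result


def relative_accuracy(study: StudyResult, model_num: str, model_den: str,
                      subset: str) -> float:
    """100 x mean accuracy of ``model_num`` over mean accuracy of ``model_den``."""
    num = study.mean_accuracy(model_num, subset)
    den = study.mean_accuracy(model_den, subset)
    if den == 0:
        raise ZeroDivisionError("denominator model has zero mean accuracy")
    return 100.0 * num / den


def paired_significance(acc_a, acc_b) -> float:
    """Two-sided paired t-test p-value on per-replicate accuracy differences.

    Degenerate cases: identical vectors give p = 1 by convention; a constant
    nonzero difference gives p = 0 (the difference is certain).
    """
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.shape != acc_b.shape or acc_a.size < 3:
        raise ValueError("need at least 3 paired replicates")
    diff = acc_a - acc_b
    if np.std(diff, ddof=1) == 0:
        return 1.0 if np.allclose(diff, 0) else 0.0
    return float(stats.ttest_rel(acc_a, acc_b).pvalue)
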