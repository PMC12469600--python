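"""Leave-one-out cross-validation of the full classification rule.

For each individual the allele counts, odds ratios, variant ranking, top-N
selection, scores and control-percentile threshold are rebuilt without that
individual, and only that individual is then predicted.  The procedure is
deterministic.  QC is assumed to have been applied once beforehand and is
not re-run per fold.

Allele counts are maintained incrementally: removing an individual
decrements each variant's counts by that individual's contribution, which an
exact inverse operation restores, so K full refits cost O(K x variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association_scoring import (
    AlleleCounts,
    allele_counts,
    odds_ratios_from_counts,
    _rank_order,
)
from .datamodel_io import MISSING, GenotypeDataset
from .prediction_eval import PredictionTable, tabulate

__all__ = [
    "LoocvConfig",
    "loo_predict_all",
    "update_counts_remove",
    "update_counts_add",
]


@dataclass
class LoocvConfig:
    n_variants: int
    percentile: float = 95.0
    denominator_mode: str = "per_individual"  # or "fixed"
    ranking_key: str = "or_descending"  # or "abs_log_or"
    refit_selection: bool = True  # False: keep the full-data top-N list in every fold
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")


def _contribution(genotypes_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(minor, major) allele contributions of one individual, per variant."""
    nonmiss = genotypes_row != MISSING
    minor = np.where(nonmiss, genotypes_row, 0).astype(np.int64)
    major = np.where(nonmiss, 2 - genotypes_row, 0).astype(np.int64)
    return minor, major


def update_counts_remove(
    counts: AlleleCounts, genotypes_row: np.ndarray, phenotype: str
) -> AlleleCounts:
    """Return counts with one individual's allele contribution removed."""
    minor, major = _contribution(genotypes_row)
    out = counts.copy()
    if phenotype == "case":
        out.minor_case -= minor
        out.major_case -= major
        if (out.minor_case < 0).any() or (out.major_case < 0).any():
            raise ValueError("count decremented below zero; individual not in counts")
    elif phenotype == "control":
        out.minor_control -= minor
        out.major_control -= major
        if (out.minor_control < 0).any() or (out.major_control < 0).any():
            raise ValueError("count decremented below zero; individual not in counts")
    # missing phenotype contributes to neither group
    return out


def update_counts_add(
    counts: AlleleCounts, genotypes_row: np.ndarray, phenotype: str
) -> AlleleCounts:
    """Exact inverse of :func:`update_counts_remove`."""
    minor, major = _contribution(genotypes_row)
    out = counts.copy()
    if phenotype == "case":
        out.minor_case += minor
        out.major_case += major
    elif phenotype == "control":
        out.minor_control += minor
        out.major_control += major
    return out


def _fold_scores(
    G: np.ndarray, weights: np.ndarray, cols: np.ndarray, mode: str
) -> np.ndarray:
    sub = G[:, cols]
    nonmiss = sub != MISSING
    dose = np.where(nonmiss, sub, 0).astype(float)
    numer = dose @ weights
    if mode == "per_individual":
        denom = 2.0 * nonmiss.sum(axis=1)
    else:
        denom = np.full(sub.shape[0], 2.0 * len(cols))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)


def loo_predict_all(
    dataset: GenotypeDataset, config: LoocvConfig
) -> tuple[pd.DataFrame, PredictionTable]:
    """Predict every individual from a model fit without them.

    Returns a per-sample frame (sample_id, sex, phenotype, threshold, score,
    prediction) and the aggregate decision table over all held-out
    predictions.
    """
    case = dataset.case_mask()
    ctrl = dataset.control_mask()
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("leave-one-out needs at least 2 cases and 2 controls")
    n_select = min(config.n_variants, dataset.n_variants)

    G = dataset.genotypes
    full_counts = allele_counts(dataset)
    phenos = dataset.samples["phenotype"].to_numpy()
    sample_ids = dataset.sample_ids
    ctrl_idx = np.where(ctrl)[0]

    fixed_cols = None
    if not config.refit_selection:
        odds, log_or = odds_ratios_from_counts(full_counts)
        fixed_cols = _rank_order(odds, log_or, config.ranking_key)[:n_select]

    records = []
    for j in range(dataset.n_samples):
        pheno_j = phenos[j]
        if pheno_j == "case" and case.sum() == 1:
            raise ValueError(f"removing {sample_ids[j]} leaves no cases")
        if pheno_j == "control" and ctrl.sum() == 1:
            raise ValueError(f"removing {sample_ids[j]} leaves no controls")
        fold = update_counts_remove(full_counts, G[j], pheno_j)
        odds, log_or = odds_ratios_from_counts(fold)
        if config.refit_selection:
            cols = _rank_order(odds, log_or, config.ranking_key)[:n_select]
        else:
            cols = fixed_cols
        weights = log_or[cols]

        # fold threshold from remaining controls (never including j)
        fold_ctrl = ctrl_idx[ctrl_idx != j]
        eval_idx = np.append(fold_ctrl, j)
        scores = _fold_scores(G[eval_idx], weights, cols, config.denominator_mode)
        ctrl_scores = scores[:-1]
        score_j = scores[-1]
        ctrl_scores = ctrl_scores[np.isfinite(ctrl_scores)]
        if ctrl_scores.size == 0:
            raise ValueError(f"no scorable controls in the fold for {sample_ids[j]}")
        threshold = float(
            np.percentile(ctrl_scores, config.percentile, method=config.quantile_method)
        )
        if np.isnan(score_j):
            prediction = np.nan
        else:
            prediction = "case" if score_j > threshold else "control"
        records.append(
            {
                "sample_id": sample_ids[j],
                "sex": dataset.samples["sex"].iloc[j],
                "phenotype": pheno_j,
                "threshold": threshold,
                "score": score_j,
                "prediction": prediction,
            }
        )

    frame = pd.DataFrame(records)
    preds = pd.Series(frame["prediction"].to_numpy(), index=frame["sample_id"].to_numpy())
    truth = pd.Series(frame["phenotype"].to_numpy(), index=frame["sample_id"].to_numpy())
    return frame, tabulate(preds, truth)
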