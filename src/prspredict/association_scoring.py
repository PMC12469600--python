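"""Allelic odds ratios, OR-ranked variant selection, PRS scoring, permutation test.

The polygenic risk score of individual j over a selected set of N variants is

    PRS_j = sum_i log(OR_i) * g_ij / (2 * N_j)

where OR_i is the allelic case/control odds ratio of variant i, g_ij is the
minor-allele dosage, and N_j is by default the number of selected variants
with a non-missing call in individual j (set ``denominator="fixed"`` to use N
for everyone).  Natural logarithms are used throughout; the base only
rescales scores and cannot change percentile-based classifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel_io import MISSING, GenotypeDataset

__all__ = [
    "AlleleCounts",
    "ScoreProfile",
    "allele_counts",
    "allelic_odds_ratio",
    "odds_ratios_from_counts",
    "rank_variants",
    "compute_prs",
    "permutation_test",
]


@dataclass
class AlleleCounts:
    """Per-variant minor/major allele counts split by phenotype group."""

    minor_case: np.ndarray
    major_case: np.ndarray
    minor_control: np.ndarray
    major_control: np.ndarray

    def copy(self) -> "AlleleCounts":
        return AlleleCounts(
            self.minor_case.copy(),
            self.major_case.copy(),
            self.minor_control.copy(),
            self.major_control.copy(),
        )


@dataclass
class ScoreProfile:
    """PRS values for every sample, plus the variant set that produced them."""

    n_variants: int
    variant_ids: list[str]
    scores: pd.Series  # index sample_id; NaN when all selected calls missing

    def missing_samples(self) -> list[str]:
        return list(self.scores.index[self.scores.isna()])


def allele_counts(dataset: GenotypeDataset) -> AlleleCounts:
    """Count minor/major alleles per variant in cases and controls."""
    G = dataset.genotypes
    nonmiss = (G != MISSING).astype(np.int64)
    dose = np.where(G == MISSING, 0, G).astype(np.int64)
    case = dataset.case_mask().astype(np.int64)
    ctrl = dataset.control_mask().astype(np.int64)
    minor_case = case @ dose
    minor_ctrl = ctrl @ dose
    major_case = 2 * (case @ nonmiss) - minor_case
    major_ctrl = 2 * (ctrl @ nonmiss) - minor_ctrl
    return AlleleCounts(minor_case, major_case, minor_ctrl, major_ctrl)


def allelic_odds_ratio(
    minor_case: float,
    major_case: float,
    minor_control: float,
    major_control: float,
    correction: str = "haldane",
) -> tuple[float, float]:
    """Allelic OR of a 2x2 allele-count table, with continuity correction.

    If any cell is zero (and ``correction="haldane"``), 0.5 is added to all
    four cells before computing, so the result is always finite and positive.
    Returns ``(odds_ratio, log_or)`` with natural-log weights.
    """
    cells = np.array([minor_case, major_case, minor_control, major_control], dtype=float)
    if (cells < 0).any():
        raise ValueError("allele counts must be non-negative")
    if cells[0] + cells[1] == 0 or cells[2] + cells[3] == 0:
        raise ValueError("each phenotype group needs at least one observed allele")
    if correction == "haldane" and (cells == 0).any():
        cells = cells + 0.5
    elif (cells == 0).any():
        raise ValueError("zero cell with continuity correction disabled")
    odds_ratio = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return float(odds_ratio), float(np.log(odds_ratio))


def odds_ratios_from_counts(counts: AlleleCounts) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Haldane-corrected ORs and log-ORs for every variant."""
    a = counts.minor_case.astype(float)
    b = counts.major_case.astype(float)
    c = counts.minor_control.astype(float)
    d = counts.major_control.astype(float)
    if ((a + b) == 0).any() or ((c + d) == 0).any():
        raise ValueError("a variant has zero observed alleles in one phenotype group")
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a = np.where(zero, a + 0.5, a)
    b = np.where(zero, b + 0.5, b)
    c = np.where(zero, c + 0.5, c)
    d = np.where(zero, d + 0.5, d)
    odds = (a * d) / (b * c)
    return odds, np.log(odds)


def _rank_order(odds: np.ndarray, log_or: np.ndarray, key: str) -> np.ndarray:
    if key in ("or", "or_descending"):
        return np.argsort(-odds, kind="stable")
    if key == "abs_log_or":
        return np.argsort(-np.abs(log_or), kind="stable")
    raise ValueError(f"unknown ranking key {key!r}")


def rank_variants(dataset: GenotypeDataset, key: str = "or_descending") -> pd.DataFrame:
    """Per-variant allele counts and ORs, sorted by predictive strength.

    Default ranking is raw OR descending (largest minor-allele odds ratio
    first); ``key="abs_log_or"`` ranks by |log OR| so protective variants can
    also be selected.  Ties preserve the original variant order.
    """
    if not dataset.case_mask().any() or not dataset.control_mask().any():
        raise ValueError("ranking requires at least one case and one control")
    counts = allele_counts(dataset)
    odds, log_or = odds_ratios_from_counts(counts)
    nonmiss = (dataset.genotypes != MISSING).sum(axis=0)
    dose = np.where(dataset.genotypes == MISSING, 0, dataset.genotypes).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(nonmiss > 0, dose / (2.0 * nonmiss), 0.0)
    stats = pd.DataFrame(
        {
            "variant_id": dataset.variant_ids,
            "chromosome": dataset.variants["chromosome"].to_numpy(),
            "bp": dataset.variants["bp"].to_numpy(),
            "minor_case": counts.minor_case,
            "major_case": counts.major_case,
            "minor_control": counts.minor_control,
            "major_control": counts.major_control,
            "odds_ratio": odds,
            "log_or": log_or,
            "maf": np.minimum(maf, 1 - maf),
        }
    )
    order = _rank_order(odds, log_or, key)
    stats = stats.iloc[order].reset_index(drop=True)
    stats["rank"] = np.arange(1, len(stats) + 1)
    return stats


def compute_prs(
    dataset: GenotypeDataset,
    selected_stats: pd.DataFrame,
    denominator: str = "per_individual",
) -> ScoreProfile:
    """Score every individual over the selected variants.

    ``selected_stats`` is a slice of the :func:`rank_variants` table (needs
    ``variant_id`` and ``log_or``).  With ``denominator="per_individual"``
    each score divides by twice the individual's count of non-missing
    selected calls; ``"fixed"`` divides by 2N regardless of missingness.
    An individual missing every selected call gets NaN.
    """
    if len(selected_stats) == 0:
        raise ValueError("at least one variant must be selected")
    vid_to_col = {v: i for i, v in enumerate(dataset.variant_ids)}
    try:
        cols = np.array([vid_to_col[v] for v in selected_stats["variant_id"]])
    except KeyError as exc:
        raise KeyError(f"selected variant {exc} not present in dataset") from exc
    w = selected_stats["log_or"].to_numpy(dtype=float)
    G = dataset.genotypes[:, cols]
    nonmiss = G != MISSING
    dose = np.where(nonmiss, G, 0).astype(float)
    numer = dose @ w
    if denominator == "per_individual":
        denom = 2.0 * nonmiss.sum(axis=1)
    elif denominator == "fixed":
        denom = np.full(dataset.n_samples, 2.0 * len(cols))
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)
    scores = pd.Series(values, index=dataset.sample_ids, name="prs")
    return ScoreProfile(
        n_variants=len(cols),
        variant_ids=list(selected_stats["variant_id"]),
        scores=scores,
    )


def _allelic_chi2(
    minor_case: np.ndarray,
    major_case: np.ndarray,
    minor_ctrl: np.ndarray,
    major_ctrl: np.ndarray,
) -> np.ndarray:
    """Pearson chi-square of the per-variant 2x2 allele-count tables."""
    a, b, c, d = (x.astype(float) for x in (minor_case, major_case, minor_ctrl, major_ctrl))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    return chi2


def permutation_test(
    dataset: GenotypeDataset, n_perms: int = 100_000, seed: int | None = None
) -> pd.DataFrame:
    """Family-wise adjusted single-variant p-values by max-T phenotype permutation.

    The per-variant statistic is the allelic chi-square.  Phenotype labels are
    permuted over individuals; the adjusted p for variant i is the add-one
    proportion of permutations whose maximum statistic across variants reaches
    the observed statistic of i, so p is never 0 and never below
    1/(n_perms+1).
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    case = dataset.case_mask()
    ctrl = dataset.control_mask()
    if not case.any() or not ctrl.any():
        raise ValueError("permutation test requires both cases and controls")

    G = dataset.genotypes
    known = case | ctrl
    nonmiss = ((G != MISSING) & known[:, None]).astype(np.int64)
    dose = np.where(G == MISSING, 0, G).astype(np.int64) * known[:, None]

    def stats_for(case_vec: np.ndarray) -> np.ndarray:
        cv = case_vec.astype(np.int64)
        minor_case = cv @ dose
        nm_case = cv @ nonmiss
        minor_all = dose.sum(axis=0)
        nm_all = nonmiss.sum(axis=0)
        return _allelic_chi2(
            minor_case,
            2 * nm_case - minor_case,
            minor_all - minor_case,
            2 * (nm_all - nm_case) - (minor_all - minor_case),
        )

    observed = stats_for(case)
    rng = np.random.default_rng(seed)
    labels = case[known]
    exceed = np.zeros(dataset.n_variants, dtype=np.int64)
    perm_case = np.zeros(dataset.n_samples, dtype=bool)
    for _ in range(n_perms):
        perm_case[:] = False
        perm_case[np.where(known)[0]] = rng.permutation(labels)
        max_stat = stats_for(perm_case).max()
        exceed += max_stat >= observed
    p_adj = (exceed + 1) / (n_perms + 1)
    return pd.DataFrame(
        {
            "variant_id": dataset.variant_ids,
            "chi2": observed,
            "p_adjusted": p_adj,
        }
    )
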