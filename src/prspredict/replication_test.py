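"""Monte-Carlo overlap-replication test between two top-k variant lists.

Under the null hypothesis, each stratum's top-k list is a uniform random
subset of the m candidate variants, so the overlap of the two lists is
hypergeometric with population m, k1 successes and k2 draws.  The
Monte-Carlo test draws the two subsets literally and counts the
intersection; the hypergeometric distribution provides both an exact
analytic p-value and a fast sampling path (the two must agree
distributionally).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapTestResult",
    "overlap_count",
    "replic2",
    "hypergeom_overlap_pvalue",
    "hypergeom_overlap_mean",
    "shared_top_variants",
]


@dataclass
class OverlapTestResult:
    """Outcome of the overlap-replication null simulation."""

    m_universe: int
    k1: int
    k2: int
    observed_shared: int
    n_reps: int
    empirical_p: float
    null_median: float
    null_mean: float
    seed: int
    method: str = "subset"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def overlap_count(list1, list2) -> int:
    """Size of the intersection of two lists of unique identifiers."""
    s1, s2 = set(list1), set(list2)
    if len(s1) != len(list1) or len(s2) != len(list2):
        raise ValueError("input lists must not contain duplicates")
    return len(s1 & s2)


def _check_sizes(m_universe: int, k1: int, k2: int, observed_shared: int) -> None:
    if not 0 < m_universe:
        raise ValueError("universe must be non-empty")
    if k1 > m_universe or k2 > m_universe:
        raise ValueError("subset size exceeds universe size")
    if k1 < 0 or k2 < 0:
        raise ValueError("subset sizes must be non-negative")
    if not 0 <= observed_shared <= min(k1, k2):
        raise ValueError("observed overlap must lie in [0, min(k1, k2)]")


def replic2(
    m_universe: int,
    k1: int,
    k2: int,
    observed_shared: int,
    n_reps: int = 100_000,
    seed: int | None = None,
    method: str = "subset",
) -> OverlapTestResult:
    """Monte-Carlo significance of an observed overlap between two subsets.

    Each replicate draws two independent uniform random subsets without
    replacement (sizes k1 and k2) from the m-item universe and records their
    overlap.  The empirical p-value uses the add-one estimator
    (#{overlap >= observed} + 1)/(n_reps + 1), so it is never 0.

    ``method="hypergeometric"`` samples the overlap directly from its exact
    null distribution instead of drawing subsets; the two methods agree
    distributionally.
    """
    _check_sizes(m_universe, k1, k2, observed_shared)
    if seed is None:
        raise ValueError("a seed is required")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    if method == "subset":
        overlaps = np.empty(n_reps, dtype=np.int64)
        mark = np.zeros(m_universe, dtype=bool)
        for r in range(n_reps):
            s1 = rng.choice(m_universe, k1, replace=False, shuffle=False)
            s2 = rng.choice(m_universe, k2, replace=False, shuffle=False)
            mark[s1] = True
            overlaps[r] = np.count_nonzero(mark[s2])
            mark[s1] = False
    elif method == "hypergeometric":
        overlaps = rng.hypergeometric(k1, m_universe - k1, k2, size=n_reps)
    else:
        raise ValueError(f"unknown method {method!r}")

    n_ge = int(np.count_nonzero(overlaps >= observed_shared))
    return OverlapTestResult(
        m_universe=m_universe,
        k1=k1,
        k2=k2,
        observed_shared=observed_shared,
        n_reps=n_reps,
        empirical_p=(n_ge + 1) / (n_reps + 1),
        null_median=float(np.median(overlaps)),
        null_mean=float(np.mean(overlaps)),
        seed=seed,
        method=method,
    )


def hypergeom_overlap_pvalue(
    m_universe: int, k1: int, k2: int, observed_shared: int
) -> float:
    """Exact upper-tail P(X >= observed) for the overlap of two random subsets."""
    _check_sizes(m_universe, k1, k2, observed_shared)
    return float(stats.hypergeom.sf(observed_shared - 1, m_universe, k1, k2))


def hypergeom_overlap_mean(m_universe: int, k1: int, k2: int) -> float:
    """Expected overlap k1*k2/m of two uniform random subsets."""
    _check_sizes(m_universe, k1, k2, 0)
    return k1 * k2 / m_universe


def shared_top_variants(
    ranked_stats_a: pd.DataFrame,
    ranked_stats_b: pd.DataFrame,
    k: int,
    min_or: float = 1.0,
) -> pd.DataFrame:
    """Variants in both top-k lists with OR >= min_or in BOTH strata.

    Both rankings (from ``rank_variants``) must cover the same variant
    universe.  Returns a frame with columns (chromosome, variant_id, bp,
    odds_ratio_a, odds_ratio_b) sorted by chromosome then position.
    """
    ua = set(ranked_stats_a["variant_id"])
    ub = set(ranked_stats_b["variant_id"])
    if ua != ub:
        raise ValueError(
            f"rankings cover different universes (symmetric difference of "
            f"{len(ua ^ ub)} variants)"
        )
    top_a = ranked_stats_a.head(k).set_index("variant_id")
    top_b = ranked_stats_b.head(k).set_index("variant_id")
    shared = top_a.index.intersection(top_b.index)
    keep = [
        v
        for v in shared
        if top_a.loc[v, "odds_ratio"] >= min_or and top_b.loc[v, "odds_ratio"] >= min_or
    ]
    out = pd.DataFrame(
        {
            "chromosome": top_a.loc[keep, "chromosome"].to_numpy(),
            "variant_id": keep,
            "bp": top_a.loc[keep, "bp"].to_numpy(),
            "odds_ratio_a": top_a.loc[keep, "odds_ratio"].to_numpy(),
            "odds_ratio_b": top_b.loc[keep, "odds_ratio"].to_numpy(),
        }
    )
    # natural chromosome order: numeric where possible, lexical otherwise
    def _chrom_key(c: str):
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)

    out["_ck"] = out["chromosome"].map(_chrom_key)
    out = out.sort_values(["_ck", "bp"]).drop(columns="_ck").reset_index(drop=True)
    return out
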