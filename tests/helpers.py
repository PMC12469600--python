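"""Independent oracles and fixture builders shared across test modules.

Everything here is deliberately written the dumb way (exhaustive
enumeration, per-element loops, exact rational arithmetic) and never calls
the code paths it is used to check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd

from prspredict.datamodel_io import MISSING, GenotypeDataset


def make_dataset(genotypes, sexes=None, phenotypes=None, chroms=None, bps=None):
    """Build a GenotypeDataset from a plain dosage matrix (-1 = missing)."""
    G = np.asarray(genotypes, dtype=np.int8)
    n, m = G.shape
    sexes = sexes if sexes is not None else ["male"] * n
    phenotypes = phenotypes if phenotypes is not None else ["control"] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "sex": list(sexes),
            "phenotype": list(phenotypes),
        }
    )
    variants = pd.DataFrame(
        {
            "variant_id": [f"V{j}" for j in range(m)],
            "chromosome": list(chroms) if chroms is not None else ["1"] * m,
            "bp": list(bps) if bps is not None else list(range(1, m + 1)),
            "allele_minor": ["A"] * m,
            "allele_major": ["B"] * m,
        }
    )
    return GenotypeDataset(G, samples, variants)


def random_dataset(rng, n=20, m=10, missing_rate=0.05, sex_ratio=0.5, case_ratio=0.4):
    """Random valid dataset; dosages from HWE-ish binomials, some missing."""
    maf = rng.uniform(0.1, 0.5, size=m)
    G = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    G[rng.random((n, m)) < missing_rate] = MISSING
    # keep dosages polarized to the observed minor allele so that PLINK
    # round-trips are identities (the reader re-polarizes from the data)
    for j in range(m):
        obs = G[:, j][G[:, j] != MISSING]
        if obs.size and obs.mean() > 1.0:
            G[:, j] = np.where(G[:, j] == MISSING, MISSING, 2 - G[:, j]).astype(np.int8)
    sexes = np.where(rng.random(n) < sex_ratio, "male", "female")
    phenos = np.where(rng.random(n) < case_ratio, "case", "control")
    return make_dataset(G, sexes, phenos)


# ---------------------------------------------------------------------------
# HWE enumeration oracle: exact conditional probabilities by rational
# arithmetic over all heterozygote counts compatible with the allele counts.
# ---------------------------------------------------------------------------


def hwe_enumeration_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # one allele's total; symmetry makes the choice irrelevant
    probs = {}
    for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        rare_hom = (n_a - h) // 2
        common_hom = n - rare_hom - h
        if common_hom < 0:
            continue
        num = (
            Fraction(math.factorial(n), 1)
            * 2**h
            * math.factorial(n_a)
            * math.factorial(2 * n - n_a)
        )
        den = (
            Fraction(math.factorial(common_hom), 1)
            * math.factorial(h)
            * math.factorial(rare_hom)
            * math.factorial(2 * n)
        )
        probs[h] = num / den
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


# ---------------------------------------------------------------------------
# brute-force VIF for a window of dosage columns
# ---------------------------------------------------------------------------


def brute_force_vifs(X: np.ndarray) -> np.ndarray:
    """VIFs by explicit OLS with an intercept column, one variant at a time."""
    n, m = X.shape
    vifs = np.ones(m)
    for j in range(m):
        y = X[:, j]
        if np.var(y) == 0:
            continue
        design = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


# ---------------------------------------------------------------------------
# per-individual PRS loop oracle
# ---------------------------------------------------------------------------


def prs_loop_oracle(dataset, selected_stats, denominator="per_individual"):
    """Score each individual with explicit python loops."""
    weights = dict(zip(selected_stats["variant_id"], selected_stats["log_or"]))
    col = {v: j for j, v in enumerate(dataset.variant_ids)}
    out = {}
    for i, sid in enumerate(dataset.sample_ids):
        total, n_obs = 0.0, 0
        for vid, w in weights.items():
            g = dataset.genotypes[i, col[vid]]
            if g != MISSING:
                total += w * int(g)
                n_obs += 1
        if denominator == "fixed":
            out[sid] = total / (2 * len(weights))
        else:
            out[sid] = total / (2 * n_obs) if n_obs else math.nan
    return out


# ---------------------------------------------------------------------------
# exhaustive overlap-distribution oracle for tiny universes
# ---------------------------------------------------------------------------


def overlap_tail_enumeration(m: int, k1: int, k2: int, observed: int) -> float:
    """P(|A ∩ B| >= observed) over all pairs of k-subsets of an m-set."""
    items = range(m)
    hits = total = 0
    for a in itertools.combinations(items, k1):
        sa = set(a)
        for b in itertools.combinations(items, k2):
            total += 1
            if len(sa.intersection(b)) >= observed:
                hits += 1
    return hits / total
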