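"""Synthetic case-control cohorts with sex-specific planted effect variants.

Genotypes are biallelic, in Hardy-Weinberg proportions and linkage
equilibrium (fixtures that need LD plant it explicitly).  Disease liability
is log-additive in minor-allele dosage over each sex's causal variant set:

    P(case) = logistic(intercept + sum_v beta_v * g_v)

with the intercept solved by bisection so the simulated case fraction hits
the requested prevalence.  Planted log-OR coefficients are therefore the
recovery target of the allelic odds-ratio estimator.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel_io import MISSING, GenotypeDataset

__all__ = ["SimConfig", "simulate_cohort", "plant_qc_failures"]


@dataclass
class SimConfig:
    """Parameters of the simulated cohort."""

    n_male: int = 300
    n_female: int = 300
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_effect_male: int = 0
    n_effect_female: int = 0
    n_effect_shared: int = 0
    effect_log_or_range: tuple[float, float] = (0.5, 1.5)
    prevalence_target: float = 0.33
    missing_rate: float = 0.0
    case_control_ratio: float | None = None  # target fraction of cases; None = keep all
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_effect_male + self.n_effect_female + self.n_effect_shared > self.n_variants:
            raise ValueError("more effect variants than variants")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("maf_range", "effect_log_or_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _solve_intercept(eta: np.ndarray, target: float, tol: float = 5e-3) -> float:
    """Bisection for t with mean(logistic(t + eta)) == target (within tol)."""

    def prev(t: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(t + eta)))))

    lo = -float(np.max(eta)) - 40.0
    hi = -float(np.min(eta)) + 40.0
    if not prev(lo) <= target <= prev(hi):
        raise ValueError("prevalence target unattainable for the planted effects")
    mid = 0.5 * (lo + hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if abs(prev(mid) - target) < tol / 4:
            break
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
    return mid


def simulate_cohort(config: SimConfig) -> GenotypeDataset:
    """Draw a reproducible case-control cohort per the configuration.

    Causal variant columns are the first ``n_effect_shared`` (both sexes,
    same beta), then ``n_effect_male`` male-only, then ``n_effect_female``
    female-only; the planted coefficients are recorded in the variant table
    columns ``beta_male`` and ``beta_female`` (0 for non-causal).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_male + config.n_female
    m = config.n_variants

    maf = rng.uniform(*config.maf_range, size=m)
    # HWE genotypes: dosage ~ Binomial(2, maf)
    G = rng.binomial(2, maf, size=(n, m)).astype(np.int8)

    is_male = np.zeros(n, dtype=bool)
    is_male[: config.n_male] = True

    betas = rng.uniform(*config.effect_log_or_range,
                        size=config.n_effect_shared + config.n_effect_male + config.n_effect_female)
    beta_male = np.zeros(m)
    beta_female = np.zeros(m)
    ns, nm = config.n_effect_shared, config.n_effect_male
    beta_male[:ns] = betas[:ns]
    beta_female[:ns] = betas[:ns]
    beta_male[ns : ns + nm] = betas[ns : ns + nm]
    beta_female[ns + nm : ns + nm + config.n_effect_female] = betas[ns + nm :]

    Gf = G.astype(float)
    eta = np.where(is_male, Gf @ beta_male, Gf @ beta_female)
    intercept = _solve_intercept(eta, config.prevalence_target)
    p_case = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    is_case = rng.random(n) < p_case

    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "sex": np.where(is_male, "male", "female"),
            "phenotype": np.where(is_case, "case", "control"),
        }
    )
    variants = pd.DataFrame(
        {
            "variant_id": [f"V{i:05d}" for i in range(m)],
            "chromosome": "1",
            "bp": np.arange(1, m + 1, dtype=np.int64) * 1000,
            "allele_minor": "A",
            "allele_major": "B",
            "maf_true": maf,
            "beta_male": beta_male,
            "beta_female": beta_female,
        }
    )

    keep = np.ones(n, dtype=bool)
    if config.case_control_ratio is not None:
        f = config.case_control_ratio
        n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
        if n_case and n_ctrl:
            if n_case / (n_case + n_ctrl) > f:
                target_cases = int(round(f * n_ctrl / (1 - f)))
                drop_from = np.where(is_case)[0]
                n_drop = n_case - target_cases
            else:
                target_ctrl = int(round(n_case * (1 - f) / f))
                drop_from = np.where(~is_case)[0]
                n_drop = n_ctrl - target_ctrl
            if n_drop > 0:
                keep[rng.choice(drop_from, n_drop, replace=False, shuffle=False)] = False

    if config.missing_rate > 0:
        G = G.copy()
        G[rng.random((n, m)) < config.missing_rate] = MISSING

    dataset = GenotypeDataset(G, samples, variants)
    if not keep.all():
        dataset = dataset.subset_samples(keep)
    return dataset


def plant_qc_failures(dataset: GenotypeDataset, spec: dict[str, dict]) -> GenotypeDataset:
    """Rewrite named variant columns to exhibit specific QC failure modes.

    ``spec`` maps variant_id to a dict with a ``mode`` key:

    - ``{"mode": "missing", "rate": r}`` — first ceil(r*n) calls set missing
    - ``{"mode": "monomorphic", "dosage": g}`` — constant column
    - ``{"mode": "hwe_het_deficit"}`` — common alleles, zero heterozygotes
      (alternating dosages 0 and 2)
    - ``{"mode": "low_maf", "n_minor": c}`` — c heterozygote carriers, rest 0
    - ``{"mode": "duplicate", "of": other_id}`` — exact copy of another column

    Everything else is untouched; the result is a new dataset.
    """
    G = dataset.genotypes.copy()
    col = {v: i for i, v in enumerate(dataset.variant_ids)}
    n = dataset.n_samples
    for vid, fail in spec.items():
        if vid not in col:
            raise KeyError(f"unknown variant id {vid!r}")
        j = col[vid]
        mode = fail["mode"]
        if mode == "missing":
            k = int(np.ceil(fail["rate"] * n))
            G[:k, j] = MISSING
        elif mode == "monomorphic":
            G[:, j] = np.int8(fail.get("dosage", 0))
        elif mode == "hwe_het_deficit":
            G[:, j] = np.where(np.arange(n) % 2 == 0, 0, 2).astype(np.int8)
        elif mode == "low_maf":
            G[:, j] = 0
            G[: int(fail.get("n_minor", 1)), j] = 1
        elif mode == "duplicate":
            other = fail["of"]
            if other not in col:
                raise KeyError(f"unknown variant id {other!r} to duplicate")
            G[:, j] = G[:, col[other]]
        else:
            raise ValueError(f"unknown failure mode {mode!r}")
    return GenotypeDataset(G, dataset.samples.copy(), dataset.variants.copy())
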