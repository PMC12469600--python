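"""Sequential variant QC: call rate, monomorphy, HWE in controls, MAF, LD pruning.

Filters are applied in a fixed order and each variant is attributed to the
first filter that removes it.  The Hardy-Weinberg check uses an exact
conditional test (Wigginton-style recurrence) computed in controls only; LD
pruning removes variants whose dosage is too predictable from a sliding
window of neighbors (variance inflation factor above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel_io import MISSING, GenotypeDataset

__all__ = [
    "QcConfig",
    "QcReport",
    "filter_callrate",
    "filter_monomorphic",
    "hwe_exact_test",
    "filter_hwe",
    "filter_maf",
    "ld_prune_vif",
    "run_qc",
]

_STAGES = ("callrate", "monomorphic", "hwe", "maf", "pruning")


@dataclass
class QcConfig:
    max_missing_rate: float = 0.10
    min_maf: float = 0.01
    hwe_alpha: float = 1e-3
    hwe_controls_only: bool = True
    prune_window: int = 50
    prune_step: int = 5
    vif_threshold: float = 2.0


@dataclass
class QcReport:
    """Tally of how many variants each QC stage removed, and which."""

    n_input: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(len(v) for v in self.removed.values())

    def count(self, stage: str) -> int:
        return len(self.removed.get(stage, []))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": "input", "n": self.n_input}]
        rows += [{"stage": s, "n": self.count(s)} for s in _STAGES]
        rows.append({"stage": "retained", "n": self.n_retained})
        return pd.DataFrame(rows)

    def removal_log(self) -> pd.DataFrame:
        recs = [
            {"variant_id": vid, "stage": stage}
            for stage in _STAGES
            for vid in self.removed.get(stage, [])
        ]
        return pd.DataFrame(recs, columns=["variant_id", "stage"])


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------


def filter_callrate(
    dataset: GenotypeDataset, max_missing_rate: float = 0.10
) -> tuple[GenotypeDataset, list[str]]:
    """Remove variants whose missing-call rate strictly exceeds the cutoff."""
    miss_rate = dataset.missing_mask().mean(axis=0)
    drop = miss_rate > max_missing_rate
    removed = list(dataset.variant_ids[drop])
    return dataset.subset_variants(~drop), removed


def filter_monomorphic(dataset: GenotypeDataset) -> tuple[GenotypeDataset, list[str]]:
    """Remove variants whose non-missing dosages are all identical.

    All-missing variants are classed as monomorphic and removed here too.
    """
    G = dataset.genotypes
    miss = G == MISSING
    nonmiss = (~miss).sum(axis=0)
    dose = np.where(miss, 0, G)
    mn = np.where(miss, np.int8(3), G).min(axis=0)
    mx = dose.max(axis=0)
    drop = (nonmiss == 0) | (mn == mx)
    removed = list(dataset.variant_ids[drop])
    return dataset.subset_variants(~drop), removed


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count.  Returns a p-value in (0, 1].
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype must be observed")

    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # count of the rarer allele
    # probabilities over heterozygote counts of matching parity, via the
    # recurrence P(h+2)/P(h) = (n_rare-h)(2n-n_rare-h)/((h+2)(h+1)).
    # Seed at the modal count and recurse outward so ratios stay bounded.
    h_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    mode = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    mode_idx = int(np.clip((mode - h_values[0]) // 2, 0, h_values.size - 1))
    probs = np.empty(h_values.size, dtype=float)
    probs[mode_idx] = 1.0
    for i in range(mode_idx + 1, h_values.size):
        h = h_values[i - 1]
        probs[i] = probs[i - 1] * (
            (n_rare - h) * (2 * n - n_rare - h) / ((h + 2.0) * (h + 1.0))
        )
    for i in range(mode_idx - 1, -1, -1):
        h = h_values[i + 1]
        probs[i] = probs[i + 1] * (
            h * (h - 1.0) / ((n_rare - h + 2.0) * (2 * n - n_rare - h + 2.0))
        )
    probs /= probs.sum()
    obs_idx = int(np.searchsorted(h_values, n_Aa))
    p = probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def filter_hwe(
    dataset: GenotypeDataset, alpha: float = 1e-3, use_controls_only: bool = True
) -> tuple[GenotypeDataset, list[str]]:
    """Remove variants violating Hardy-Weinberg proportions (controls only)."""
    if use_controls_only:
        mask = dataset.control_mask()
        if not mask.any():
            raise ValueError("filter_hwe requires at least one control")
        G = dataset.genotypes[mask]
    else:
        G = dataset.genotypes
    drop = np.zeros(dataset.n_variants, dtype=bool)
    if alpha > 0:
        for j in range(dataset.n_variants):
            g = G[:, j]
            g = g[g != MISSING]
            if g.size == 0:
                continue
            counts = np.bincount(g, minlength=3)
            p = hwe_exact_test(counts[0], counts[1], counts[2])
            drop[j] = p < alpha
    removed = list(dataset.variant_ids[drop])
    return dataset.subset_variants(~drop), removed


def filter_maf(
    dataset: GenotypeDataset, min_maf: float = 0.01
) -> tuple[GenotypeDataset, list[str]]:
    """Remove variants with minor allele frequency strictly below the cutoff."""
    G = dataset.genotypes
    miss = G == MISSING
    nonmiss = (~miss).sum(axis=0)
    dose = np.where(miss, 0, G).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(nonmiss > 0, dose / (2.0 * nonmiss), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    drop = maf < min_maf
    removed = list(dataset.variant_ids[drop])
    return dataset.subset_variants(~drop), removed


def _window_vifs(X: np.ndarray) -> np.ndarray:
    """VIF = 1/(1-R^2) of each column regressed on the others (with intercept).

    Columns are centered copies with missing values mean-imputed upstream.
    Exact collinearity yields ``inf``.
    """
    m = X.shape[1]
    vifs = np.ones(m)
    Xc = X - X.mean(axis=0)
    sstot = (Xc**2).sum(axis=0)
    for j in range(m):
        if sstot[j] <= 0:
            vifs[j] = 1.0
            continue
        others = np.delete(Xc, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, Xc[:, j], rcond=None)
        resid = Xc[:, j] - others @ beta
        r2 = 1.0 - (resid**2).sum() / sstot[j]
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def ld_prune_vif(
    dataset: GenotypeDataset,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> tuple[GenotypeDataset, list[str]]:
    """Windowed VIF-based LD pruning.

    A window of ``window`` consecutive retained variants slides along each
    chromosome in steps of ``step``.  Within a window, while any variant has
    VIF above the threshold, the variant with the largest VIF is removed
    (ties resolved toward the larger variant index).  Windows never span
    chromosomes.  Missing dosages are mean-imputed within the window.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    G = dataset.genotypes.astype(float)
    G[dataset.genotypes == MISSING] = np.nan
    keep = np.ones(dataset.n_variants, dtype=bool)
    chroms = dataset.variants["chromosome"].to_numpy()

    for chrom in pd.unique(chroms):
        chrom_idx = np.where(chroms == chrom)[0]
        start = 0
        while True:
            kept = chrom_idx[keep[chrom_idx]]
            if start >= len(kept):
                break
            win = kept[start : start + window]
            if len(win) >= 2:
                X = G[:, win].copy()
                col_mean = np.nanmean(X, axis=0)
                nan_r, nan_c = np.where(np.isnan(X))
                X[nan_r, nan_c] = col_mean[nan_c]
                active = list(range(len(win)))
                while len(active) >= 2:
                    vifs = _window_vifs(X[:, active])
                    worst = np.max(vifs)
                    if not worst > vif_threshold:
                        break
                    # ties -> larger variant index removed
                    cand = np.where(vifs >= worst)[0]
                    drop_local = int(cand.max())
                    keep[win[active[drop_local]]] = False
                    del active[drop_local]
            if start + window >= len(kept):
                break
            start += step
    removed = list(dataset.variant_ids[~keep])
    return dataset.subset_variants(keep), removed


# ---------------------------------------------------------------------------
# chain
# ---------------------------------------------------------------------------


def run_qc(
    dataset: GenotypeDataset, config: QcConfig | None = None
) -> tuple[GenotypeDataset, QcReport]:
    """Apply all filters in order: call rate, monomorphy, HWE, MAF, pruning."""
    config = config or QcConfig()
    report = QcReport(n_input=dataset.n_variants)

    dataset, report.removed["callrate"] = filter_callrate(dataset, config.max_missing_rate)
    dataset, report.removed["monomorphic"] = filter_monomorphic(dataset)
    dataset, report.removed["hwe"] = filter_hwe(
        dataset, config.hwe_alpha, config.hwe_controls_only
    )
    dataset, report.removed["maf"] = filter_maf(dataset, config.min_maf)
    dataset, report.removed["pruning"] = ld_prune_vif(
        dataset, config.prune_window, config.prune_step, config.vif_threshold
    )
    return dataset, report
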