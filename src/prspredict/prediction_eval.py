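"""Percentile-threshold classification, decision-table metrics, ROC sweep and AUC.

An individual is predicted to be a case when their risk score strictly
exceeds a chosen percentile (default 95th) of the control score
distribution.  Predictions against known phenotypes populate a 2x2 decision
table (a = cases predicted case, b = cases predicted control, c = controls
predicted case, d = controls predicted control) from which PPV, NPV, the
table odds ratio and accuracy follow.

Accuracy is the proportion of correct predictions, (a+d)/(a+b+c+d).

Sweeping the number of top-ranked variants N yields a ragged (FPR, TPR)
series; ``smooth_roc`` repeatedly applies overlapping 3-point moving
averages until the curve lies on or above the diagonal and the TPR sequence
is non-decreasing, after which the trapezoidal AUC is computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association_scoring import compute_prs
from .datamodel_io import GenotypeDataset

__all__ = [
    "PredictionTable",
    "RocSeries",
    "SmoothingError",
    "control_threshold",
    "classify",
    "tabulate",
    "sweep_grid",
    "smooth_roc",
    "compute_auc",
    "DEFAULT_GRID",
]

DEFAULT_GRID = (5, 10, 20, 50, 100, 200, 500, 1000, 2000, 5000, 10000, 20000, 50000)


class SmoothingError(RuntimeError):
    """ROC smoothing failed to reach a conforming curve within max_iter."""


@dataclass
class PredictionTable:
    """2x2 decision table of known phenotype vs prediction, plus metrics.

    Metrics with a zero denominator are ``None`` (undefined) rather than NaN;
    a table odds ratio with an empty off-diagonal is ``math.inf``.
    """

    a: int  # cases predicted case
    b: int  # cases predicted control
    c: int  # controls predicted case
    d: int  # controls predicted control
    n_excluded: int = 0  # samples dropped for missing predictions

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def ppv(self) -> float | None:
        return self.a / (self.a + self.c) if self.a + self.c else None

    @property
    def npv(self) -> float | None:
        return self.d / (self.b + self.d) if self.b + self.d else None

    @property
    def acc(self) -> float | None:
        return (self.a + self.d) / self.total if self.total else None

    @property
    def tpr(self) -> float | None:
        return self.a / (self.a + self.b) if self.a + self.b else None

    @property
    def fpr(self) -> float | None:
        return self.c / (self.c + self.d) if self.c + self.d else None

    @property
    def odds_ratio(self) -> float | None:
        if self.a + self.b == 0 or self.c + self.d == 0:
            return None
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else None
        return (self.a * self.d) / (self.b * self.c)

    @property
    def misclassified(self) -> int:
        return self.b + self.c

    @property
    def misclassification_rate(self) -> float | None:
        return self.misclassified / self.total if self.total else None

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "ppv": self.ppv, "npv": self.npv, "acc": self.acc,
            "odds_ratio": self.odds_ratio,
            "misclassified": self.misclassified,
            "misclassification_rate": self.misclassification_rate,
        }


@dataclass
class RocSeries:
    """(N, TPR, FPR) triples over a variant-count grid, raw and smoothed."""

    grid: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    smoothed_tpr: np.ndarray | None = None
    smoothed_fpr: np.ndarray | None = None
    auc: float | None = None
    n_iterations: int | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"N": self.grid, "tpr": self.tpr, "fpr": self.fpr})
        if self.smoothed_tpr is not None:
            frame["smoothed_tpr"] = self.smoothed_tpr
            frame["smoothed_fpr"] = self.smoothed_fpr
        return frame


def control_threshold(
    scores: pd.Series,
    control_ids: np.ndarray | list,
    percentile: float = 95.0,
    method: str = "linear",
) -> float:
    """Percentile of the control score distribution.

    ``method`` is the quantile convention: ``"linear"`` interpolates between
    order statistics (default); ``"nearest"`` takes the nearest rank.
    """
    vals = scores.loc[list(control_ids)].dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("threshold requires at least one non-missing control score")
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown quantile method {method!r}")
    return float(np.percentile(vals, percentile, method=method))


def classify(scores: pd.Series, threshold: float) -> pd.Series:
    """Predict "case" when score strictly exceeds the threshold, else "control".

    A missing score yields a missing prediction (NaN).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = pd.Series(
        np.where(scores.to_numpy(dtype=float) > threshold, "case", "control"),
        index=scores.index,
        dtype=object,
    )
    out[scores.isna()] = np.nan
    return out


def tabulate(predictions: pd.Series, true_phenotypes: pd.Series) -> PredictionTable:
    """Cross-tabulate predictions against known phenotypes.

    Samples with a missing prediction or a missing/unknown true phenotype are
    excluded and counted in ``n_excluded``.
    """
    truth = true_phenotypes.reindex(predictions.index)
    valid = predictions.notna() & truth.isin(["case", "control"])
    pred, truth = predictions[valid], truth[valid]
    a = int(((truth == "case") & (pred == "case")).sum())
    b = int(((truth == "case") & (pred == "control")).sum())
    c = int(((truth == "control") & (pred == "case")).sum())
    d = int(((truth == "control") & (pred == "control")).sum())
    return PredictionTable(a, b, c, d, n_excluded=int((~valid).sum()))


def evaluate_at_n(
    dataset: GenotypeDataset,
    ranked_stats: pd.DataFrame,
    n_variants: int,
    percentile: float = 95.0,
    denominator: str = "per_individual",
    quantile_method: str = "linear",
) -> PredictionTable:
    """Score with the top-N ranked variants, threshold on controls, tabulate."""
    profile = compute_prs(dataset, ranked_stats.head(n_variants), denominator=denominator)
    ctrl_ids = dataset.sample_ids[dataset.control_mask()]
    thr = control_threshold(profile.scores, ctrl_ids, percentile, quantile_method)
    preds = classify(profile.scores, thr)
    truth = pd.Series(
        dataset.samples["phenotype"].to_numpy(), index=dataset.sample_ids
    )
    return tabulate(preds, truth)


def sweep_grid(
    dataset: GenotypeDataset,
    grid: list[int] | tuple[int, ...],
    ranked_stats: pd.DataFrame,
    percentile: float = 95.0,
    denominator: str = "per_individual",
    quantile_method: str = "linear",
) -> tuple[RocSeries, dict[int, PredictionTable]]:
    """Evaluate the classifier at each variant count N of the grid.

    Grid values exceeding the number of ranked variants are clipped (with a
    warning); duplicate clipped values collapse to one evaluation.
    """
    m = len(ranked_stats)
    clipped: list[int] = []
    for n in grid:
        if n > m:
            warnings.warn(f"grid value {n} exceeds {m} ranked variants; clipped", stacklevel=2)
            n = m
        if n not in clipped:
            clipped.append(n)
    tables: dict[int, PredictionTable] = {}
    for n in clipped:
        tables[n] = evaluate_at_n(
            dataset, ranked_stats, n, percentile, denominator, quantile_method
        )
    ns = np.array(sorted(tables))
    tpr = np.array([tables[n].tpr for n in ns], dtype=float)
    fpr = np.array([tables[n].fpr for n in ns], dtype=float)
    return RocSeries(grid=ns, tpr=tpr, fpr=fpr), tables


def _moving_average_pass(x: np.ndarray) -> np.ndarray:
    """One pass of overlapping 3-point moving averages; endpoints fixed."""
    if x.size < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


def _conforms(tpr: np.ndarray, fpr: np.ndarray, tol: float = 1e-9) -> bool:
    above_diag = np.all(tpr >= fpr - tol)
    monotone = np.all(np.diff(tpr) >= -tol)
    return bool(above_diag and monotone)


def smooth_roc(series: RocSeries, max_iter: int = 1000) -> RocSeries:
    """Smooth the ROC series until it is a proper curve, then attach the AUC.

    Points are first ordered by increasing FPR; both rate sequences then get
    repeated 3-point moving-average passes (endpoints held fixed) until the
    TPR sequence lies on or above the FPR sequence and is non-decreasing.
    Raises :class:`SmoothingError` if the conditions are not met within
    ``max_iter`` passes.
    """
    if series.grid.size == 0:
        raise ValueError("cannot smooth an empty series")
    order = np.argsort(series.fpr, kind="stable")
    tpr = series.tpr[order].astype(float)
    fpr = series.fpr[order].astype(float)
    iterations = 0
    while not _conforms(tpr, fpr):
        if iterations >= max_iter:
            raise SmoothingError(
                f"smoothing did not converge in {max_iter} passes; "
                f"residual TPR dip {np.diff(tpr).min():.3g}, "
                f"max FPR excess {(fpr - tpr).max():.3g}"
            )
        tpr = _moving_average_pass(tpr)
        fpr = _moving_average_pass(fpr)
        iterations += 1
    out = RocSeries(
        grid=series.grid[order],
        tpr=series.tpr[order],
        fpr=series.fpr[order],
        smoothed_tpr=tpr,
        smoothed_fpr=fpr,
        n_iterations=iterations,
    )
    out.auc = compute_auc(out)
    return out


def compute_auc(series: RocSeries) -> float:
    """Trapezoidal area under the curve through (0,0), the points, and (1,1).

    Uses the smoothed series when present.  Points are sorted by FPR and
    duplicate FPR values have their TPRs averaged.
    """
    tpr = series.smoothed_tpr if series.smoothed_tpr is not None else series.tpr
    fpr = series.smoothed_fpr if series.smoothed_fpr is not None else series.fpr
    frame = pd.DataFrame({"fpr": fpr, "tpr": tpr}).groupby("fpr", as_index=False).mean()
    x = np.concatenate(([0.0], frame["fpr"].to_numpy(), [1.0]))
    y = np.concatenate(([0.0], frame["tpr"].to_numpy(), [1.0]))
    return float(np.trapezoid(y, x))


def tables_to_frame(tables: dict[int, PredictionTable]) -> pd.DataFrame:
    """Per-N metrics table (one row per grid value), TSV-ready."""
    rows = []
    for n in sorted(tables):
        t = tables[n]
        rows.append({"N": n, **t.to_dict()})
    return pd.DataFrame(rows)
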