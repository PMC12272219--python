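"""Prediction-accuracy metrics and between-method comparison statistics.

Accuracy is summarized by Pearson's correlation, the coefficient of
determination (COD) and mean absolute error. COD is 1 − SS_res/SS_tot with the
total sum of squares taken about the mean of the evaluated sample itself, so
COD = 0 means "no better than predicting the sample mean" and negative values
mean worse than that. Method comparisons use a paired bootstrap over
(phenotype, repeat) cells, Benjamini–Hochberg FDR over the pooled comparison
grid, and Cohen's D effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvalRecord",
    "ComparisonResult",
    "pearson",
    "cod",
    "mae",
    "aggregate",
    "bootstrap_compare",
    "fdr_bh",
    "cohens_d",
    "phenotype_overlap_analysis",
    "records_to_frame",
]


def _as_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return y, yhat


def pearson(y, yhat) -> float:
    """Product-moment correlation; errors on constant input."""
    y, yhat = _as_pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    return float(yc @ pc / np.sqrt((yc @ yc) * (pc @ pc)))


def cod(y, yhat) -> float:
    """Coefficient of determination 1 − Σ(y−ŷ)²/Σ(y−ȳ)², ȳ over the evaluated sample."""
    y, yhat = _as_pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("COD undefined for constant target")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def mae(y, yhat) -> float:
    y, yhat = _as_pair(y, yhat)
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - yhat)))


@dataclass
class EvalRecord:
    """Accuracy of one method on one phenotype in one K-shot repeat."""

    method: str
    K: int
    repeat_index: int
    phenotype: str
    pearson_r: float
    cod: float
    mae: float
    n_test: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError(f"pearson_r out of range: {self.pearson_r}")
        if self.n_test < 2:
            raise ValueError("n_test must be >= 2")


def records_to_frame(records: Sequence[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def aggregate(records: Sequence[EvalRecord], metric: str = "pearson_r") -> pd.DataFrame:
    """Mean metric across phenotypes per (method, K, repeat).

    The aggregation order is fixed: average across phenotypes first; the
    distribution over repeats is what downstream comparisons operate on.
    Raises if the (method, K, repeat, phenotype) grid is incomplete.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    if metric not in ("pearson_r", "cod", "mae"):
        raise ValueError(f"unknown metric {metric!r}")
    counts = df.groupby(["method", "K", "repeat_index"])["phenotype"].nunique()
    n_phen = df["phenotype"].nunique()
    missing = counts[counts != n_phen]
    if len(missing):
        raise ValueError(f"incomplete grid cells (expected {n_phen} phenotypes each):\n{missing}")
    out = (df.groupby(["method", "K", "repeat_index"])[metric]
             .mean().rename("value").reset_index())
    return out


@dataclass
class ComparisonResult:
    """Paired bootstrap comparison of two methods at one K."""

    method_a: str
    method_b: str
    K: int
    metric: str
    mean_difference: float
    p_value: float
    cohens_d: float
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def _paired_matrix(records: Sequence[EvalRecord], method: str, K: int,
                   metric: str) -> pd.DataFrame:
    df = records_to_frame(records)
    sub = df[(df["method"] == method) & (df["K"] == K)]
    if sub.empty:
        raise ValueError(f"no records for method {method!r} at K={K}")
    return sub.pivot(index="repeat_index", columns="phenotype", values=metric)


def bootstrap_compare(records: Sequence[EvalRecord], method_a: str, method_b: str,
                      K: int, metric: str = "pearson_r", n_boot: int = 1000,
                      seed: int = 0) -> ComparisonResult:
    """Two-sided paired bootstrap of the mean metric difference A − B.

    Phenotypes and repeats are resampled with replacement jointly for both
    methods; p = 2·min(P(diff ≤ 0), P(diff ≥ 0)) floored at 1/n_boot.
    """
    a = _paired_matrix(records, method_a, K, metric)
    b = _paired_matrix(records, method_b, K, metric)
    if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
        raise ValueError("records of the two methods are not paired over (repeat, phenotype)")
    if a.isna().any().any() or b.isna().any().any():
        raise ValueError("unpaired (missing) cells in the comparison grid")
    diff = a.to_numpy() - b.to_numpy()  # repeats × phenotypes
    n_rep, n_phen = diff.shape
    rng = np.random.default_rng(seed)
    rep_idx = rng.integers(0, n_rep, size=(n_boot, n_rep))
    phe_idx = rng.integers(0, n_phen, size=(n_boot, n_phen))
    boot_means = np.empty(n_boot)
    for i in range(n_boot):
        boot_means[i] = diff[np.ix_(rep_idx[i], phe_idx[i])].mean()
    frac_le = np.mean(boot_means <= 0)
    frac_ge = np.mean(boot_means >= 0)
    p = max(min(2.0 * min(frac_le, frac_ge), 1.0), 1.0 / n_boot)
    d = cohens_d(a.to_numpy().mean(axis=1), b.to_numpy().mean(axis=1))
    return ComparisonResult(method_a, method_b, K, metric,
                            float(diff.mean()), float(p), d)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up over a pooled p-value vector → rejection flags."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = q * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresholds
    flags = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.nonzero(passed)[0]))
        flags[order[: k + 1]] = True
    return flags


def cohens_d(a, b) -> float:
    """Standardized mean difference with df-weighted pooled sample std."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def phenotype_overlap_analysis(meta_train_table, meta_test_table,
                               improvements: dict[str, float]) -> pd.DataFrame:
    """Pair each meta-test phenotype's top |correlation| with any meta-training
    phenotype (over shared participants) against its prediction improvement.

    Only applicable when the two tables share participants (within-dataset
    mode); rows are meta-test phenotypes.
    """
    shared = [p for p in meta_train_table.participant_ids
              if p in set(meta_test_table.participant_ids)]
    if not shared:
        raise ValueError("no shared participants between the tables")
    tr = meta_train_table.subset(participant_ids=shared)
    te = meta_test_table.subset(participant_ids=shared)
    rows = []
    for j, name in enumerate(te.phenotype_names):
        yj = te.values[:, j]
        oj = te.observed[:, j]
        best = 0.0
        for i in range(tr.n_phenotypes):
            both = oj & tr.observed[:, i]
            if both.sum() < 3:
                continue
            r = abs(pearson(yj[both], tr.values[both, i]))
            best = max(best, r)
        rows.append({"phenotype": name, "max_abs_corr": best,
                     "improvement": improvements.get(name, np.nan)})
    return pd.DataFrame(rows)
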