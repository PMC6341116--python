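"""Count-based differential expression with the study's selection rule.

A deliberately simple, documented stand-in for a full negative-binomial
GLM pipeline: median-of-ratios size factors, log-ratio fold changes of
normalized group means, a two-sample t-test on log2-transformed
normalized counts, Benjamini-Hochberg adjustment over all tested genes,
and the selection rule adjusted p <= 0.05 AND |fold change| > 1.5 (both
directions). An externally produced DE table can be dropped in at any
point downstream; only the columns matter.

The default test pools the group variances (classic Student t). At the
triplicate design this pipeline targets, the Welch-Satterthwaite
approximation is markedly conservative (empirical size ~0.036 at nominal
0.05 even for exactly normal data), whereas the pooled test holds its
size; Welch remains available via ``equal_var=False`` for designs with
genuinely heteroscedastic groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "FilterConfig",
    "size_factors",
    "de_test",
    "bh_adjust",
    "select_de",
    "rank_genes",
    "run_de",
]

DE_TABLE_COLUMNS = ["gene", "base_mean", "log2fc", "p", "padj", "rank"]


class NormalizationError(ValueError):
    """No gene is expressed in every sample, so median-of-ratios is undefined."""


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample integer counts with a two-group design.

    ``groups`` maps sample id to 0 (control) or 1 (treated).
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # (n_genes, n_samples) non-negative ints
    groups: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing group labels: {missing}")

    @property
    def group_vector(self) -> np.ndarray:
        return np.array([self.groups[s] for s in self.samples], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)


@dataclass(frozen=True)
class FilterConfig:
    """The DE selection thresholds: adjusted p and linear fold change."""

    alpha: float = 0.05
    fc_threshold: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")


def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors.

    s_j = median over genes of K_gj / geomean_g, where geomean_g is the
    geometric mean of gene g across samples; genes with any zero count are
    excluded from the median.
    """
    K = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    K = K.astype(float)
    positive = np.all(K > 0, axis=1)
    if not np.any(positive):
        raise NormalizationError("no gene has positive counts in every sample")
    Kpos = K[positive]
    geomean = np.exp(np.log(Kpos).mean(axis=1, keepdims=True))
    return np.median(Kpos / geomean, axis=0)


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Two-sided t p-values row-wise; degenerate rows (zero variance in
    both groups) get p = 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant rows
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def de_test(
    counts: CountMatrix,
    factors: np.ndarray | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene fold change and raw two-sample-t p-value.

    Counts are normalized by the size factors; the log2 fold change is the
    log-ratio of the treated to control means of normalized counts (a
    pseudocount of 0.5 is added to BOTH means only when either is zero, so
    positive data keep exact ratios). The p-value is a two-sample t on
    log2(normalized + 1): pooled-variance by default (see module
    docstring), Welch with ``equal_var=False``.

    Returns a DataFrame with columns gene, base_mean, log2fc, p.
    """
    x = counts.group_vector
    if np.sum(x == 0) < 2 or np.sum(x == 1) < 2:
        raise ValueError("each group needs >= 2 samples for Welch's t-test")
    s = size_factors(counts) if factors is None else np.asarray(factors, dtype=float)
    norm = counts.counts / s[None, :]

    mean_ctrl = norm[:, x == 0].mean(axis=1)
    mean_trt = norm[:, x == 1].mean(axis=1)
    zero = (mean_ctrl == 0) | (mean_trt == 0)
    mc = np.where(zero, mean_ctrl + 0.5, mean_ctrl)
    mt = np.where(zero, mean_trt + 0.5, mean_trt)
    log2fc = np.log2(mt / mc)

    logn = np.log2(norm + 1.0)
    p = _two_sample_t(logn[:, x == 1], logn[:, x == 0], equal_var)

    return pd.DataFrame(
        {
            "gene": counts.genes,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "p": p,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def rank_genes(de_table: pd.DataFrame) -> pd.DataFrame:
    """Attach the significance ranking the landscape sweeps over.

    Ascending raw p; ties broken by larger |log2fc|, then gene id. Returns
    a copy with a ``rank`` column (1 = most significant), sorted by rank.
    """
    df = de_table.copy()
    df["_absfc"] = -df["log2fc"].abs()
    df = df.sort_values(["p", "_absfc", "gene"], kind="stable").drop(columns="_absfc")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def select_de(de_table: pd.DataFrame, config: FilterConfig = FilterConfig()) -> set[str]:
    """Genes passing the selection rule, both directions.

    Kept iff padj <= alpha AND |log2fc| > log2(fc_threshold); the fold-
    change comparison is strict, the p comparison inclusive.
    """
    if "padj" not in de_table:
        raise ValueError("DE table has no adjusted p-values; run bh_adjust first")
    keep = (de_table["padj"] <= config.alpha) & (
        de_table["log2fc"].abs() > np.log2(config.fc_threshold)
    )
    return set(de_table.loc[keep, "gene"])


def run_de(counts: CountMatrix) -> pd.DataFrame:
    """Full DE stage: normalize, test, adjust, rank.

    Returns the ranked DE table with columns gene, base_mean, log2fc, p,
    padj, rank.
    """
    df = de_test(counts)
    df["padj"] = bh_adjust(df["p"].to_numpy())
    return rank_genes(df)[DE_TABLE_COLUMNS]
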