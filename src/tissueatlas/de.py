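"""Differential expression between muscle developmental stages.

Counts are normalized with median-of-ratios size factors, fold changes
are computed with a 0.5 pseudocount, and significance comes from a
negative-binomial Wald test on the log fold change: Var(K) = mu +
alpha * mu^2, the delta method propagates that variance to the log of
the group mean, and the Wald z statistic is referred to the standard
normal.  Dispersion alpha is either supplied or pooled across features
by method of moments; a single-replicate design cannot estimate it and
must supply one.

This is a deliberately transparent stand-in for a full GLM framework:
the scientific content downstream (the log2FC >= 1, FDR < 0.05 calls
and the stage-overlap patterns) depends only on calibrated p-values,
which the null-simulation tests verify directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "PatternPartition",
    "normalize_library",
    "estimate_dispersion",
    "de_test",
    "bh_fdr",
    "call_de",
    "overlap_patterns",
]

_PSEUDOCOUNT = 0.5


def normalize_library(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    The reference is the per-feature geometric mean over samples,
    computed on features with all-positive counts; each sample's factor
    is the median of its ratios to the reference.  If no feature is
    positive in every sample, falls back to column-sum factors
    (normalized to geometric mean 1) with a warning.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        logger.warning(
            "no feature positive in all samples; falling back to column-sum size factors"
        )
        colsum = arr.sum(axis=0)
        if (colsum == 0).any():
            raise ValueError("cannot compute size factors: empty sample column")
        factors = colsum / np.exp(np.mean(np.log(colsum)))
        return pd.Series(factors, index=counts.columns)
    sub = arr[allpos]
    logref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - logref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def estimate_dispersion(norm_counts: np.ndarray, group_sizes: list[int]) -> float:
    """Pooled method-of-moments NB dispersion from within-group moments.

    alpha_i = (s^2 - xbar) / xbar^2 per feature and group; the pooled
    estimate is the median over positive values, floored at 1e-8.
    """
    vals = []
    start = 0
    for size in group_sizes:
        block = norm_counts[:, start : start + size]
        start += size
        if size < 2:
            continue
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / (m * m)
        vals.append(a[np.isfinite(a) & (a > 0)])
    if not vals or not len(np.concatenate(vals)):
        raise ValueError(
            "cannot estimate dispersion from these groups; supply a fixed value"
        )
    return max(float(np.median(np.concatenate(vals))), 1e-8)


def de_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    dispersion: float | str = "estimate",
) -> pd.DataFrame:
    """NB Wald test of condition B versus A, feature by feature.

    ``counts_a`` / ``counts_b`` hold the replicate columns of the two
    conditions over a shared feature index.  Returns a table with
    ``base_mean_a``, ``base_mean_b`` (size-factor-normalized means),
    ``log2fc`` (B over A, pseudocount 0.5), ``p`` and BH-adjusted
    ``fdr``.

    With one column per condition there is no replicate information:
    ``dispersion`` must then be a number, not ``"estimate"``.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("condition matrices must share a feature index")
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if n_a < 1 or n_b < 1:
        raise ValueError("each condition needs at least one column")
    if dispersion == "estimate" and (n_a < 2 or n_b < 2):
        raise ValueError(
            "single-replicate design: per-feature dispersion cannot be estimated; "
            "supply a fixed dispersion value"
        )
    joint = pd.concat([counts_a, counts_b], axis=1)
    factors = normalize_library(joint)
    norm = joint.to_numpy(dtype=float) / factors.to_numpy()
    if dispersion == "estimate":
        alpha = estimate_dispersion(norm, [n_a, n_b])
    else:
        alpha = float(dispersion)
        if alpha <= 0:
            raise ValueError("dispersion must be > 0")
    mean_a = norm[:, :n_a].mean(axis=1)
    mean_b = norm[:, n_a:].mean(axis=1)
    log2fc = np.log2(mean_b + _PSEUDOCOUNT) - np.log2(mean_a + _PSEUDOCOUNT)
    # delta method: Var(log2(mean + c)) ~ Var(mean) / ((mean + c) ln 2)^2
    var_a = (mean_a + alpha * mean_a**2) / n_a
    var_b = (mean_b + alpha * mean_b**2) / n_b
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_a / ((mean_a + _PSEUDOCOUNT) * ln2) ** 2
        + var_b / ((mean_b + _PSEUDOCOUNT) * ln2) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
            "fdr": bh_fdr(p),
        },
        index=counts_a.index,
    )


def bh_fdr(p: np.ndarray | list[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05) -> pd.Series:
    """Classify each feature as 'up', 'down' or 'ns' from the DE table."""
    sig = table["fdr"] < fdr_max
    call = pd.Series("ns", index=table.index, dtype=object)
    call[sig & (table["log2fc"] >= lfc_min)] = "up"
    call[sig & (table["log2fc"] <= -lfc_min)] = "down"
    return call


@dataclass
class PatternPartition:
    """Dynamic-pattern classes over two consecutive stage comparisons."""

    up_up: set[str] = field(default_factory=set)
    up_down: set[str] = field(default_factory=set)
    down_up: set[str] = field(default_factory=set)
    down_down: set[str] = field(default_factory=set)
    first_only_up: set[str] = field(default_factory=set)
    first_only_down: set[str] = field(default_factory=set)
    second_only_up: set[str] = field(default_factory=set)
    second_only_down: set[str] = field(default_factory=set)

    def monotone_through(self) -> set[str]:
        """Features moving in one direction throughout both comparisons."""
        return self.up_up | self.down_down

    def sizes(self) -> dict[str, int]:
        return {
            name: len(getattr(self, name))
            for name in (
                "up_up", "up_down", "down_up", "down_down",
                "first_only_up", "first_only_down",
                "second_only_up", "second_only_down",
            )
        }


def overlap_patterns(calls_first: pd.Series, calls_second: pd.Series) -> PatternPartition:
    """Partition DE calls from two comparisons into dynamic patterns.

    ``calls_*`` map feature -> {'up', 'down', 'ns'} for the first
    (e.g. D0 vs D30) and second (D30 vs D240) comparison; features
    significant in both land in the four two-way classes, features
    significant once in the single-comparison classes.
    """
    idx = calls_first.index.union(calls_second.index)
    a = calls_first.reindex(idx, fill_value="ns")
    b = calls_second.reindex(idx, fill_value="ns")
    part = PatternPartition()
    for feat in idx:
        ca, cb = a[feat], b[feat]
        if ca == "ns" and cb == "ns":
            continue
        if ca != "ns" and cb != "ns":
            getattr(part, f"{ca}_{cb}").add(feat)
        elif ca != "ns":
            getattr(part, f"first_only_{ca}").add(feat)
        else:
            getattr(part, f"second_only_{cb}").add(feat)
    return part
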