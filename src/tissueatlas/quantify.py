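"""Abundance normalization and sample-similarity structure.

mRNA counts are normalized to RPKM (reads per kilobase of transcript
per million mapped reads); mature-miRNA counts to reads per million
mapped miRNA reads.  Mature miRNAs are all ~22 nt, so the small-RNA
"TPM" carries no length term by default; a length-aware mode is
available for completeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "compute_rpkm",
    "compute_tpm_per_million",
    "flag_expressed",
    "tissue_similarity",
]


@dataclass
class NormalizedMatrix:
    """A features x samples abundance matrix with its normalization tag.

    ``method`` is ``"RPKM"`` or ``"TPM"``; ``lengths`` (nt per feature)
    is carried only for length-normalized matrices.
    """

    values: pd.DataFrame
    method: Literal["RPKM", "TPM"]
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise ValueError("normalized values must be finite and non-negative")


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> NormalizedMatrix:
    """RPKM[g,s] = counts[g,s] * 1e9 / (colsum[s] * length[g]).

    ``lengths`` gives transcript length in nt per feature; every counted
    feature must have a positive length.  A zero-depth sample yields an
    all-zero column rather than NaN.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing transcript length for: {missing.tolist()[:5]}")
    lens = lengths.reindex(counts.index).astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0].tolist()[:5]
        raise ValueError(f"non-positive transcript length for: {bad}")
    colsum = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rpkm = counts * 1e9 / colsum
    rpkm = rpkm.div(lens, axis=0)
    rpkm[counts.columns[colsum == 0]] = 0.0
    return NormalizedMatrix(rpkm, "RPKM", lengths=lens)


def compute_tpm_per_million(counts: pd.DataFrame) -> NormalizedMatrix:
    """Reads per million mapped reads: TPM[m,s] = counts[m,s] * 1e6 / colsum[s].

    Every non-empty sample column of the output sums to 1e6; zero-depth
    columns yield zeros.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    colsum = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpm = counts * 1e6 / colsum
    tpm[counts.columns[colsum == 0]] = 0.0
    return NormalizedMatrix(tpm, "TPM")


def flag_expressed(
    norm: NormalizedMatrix, threshold: float = 0.1
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag cells with abundance strictly above ``threshold``.

    Returns the per-cell boolean matrix and the per-feature any-sample
    flag (a feature is "expressed" if it clears the threshold in at
    least one sample).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    per_cell = norm.values > threshold
    return per_cell, per_cell.any(axis=1)


def tissue_similarity(
    norm: NormalizedMatrix, linkage_method: str = "average"
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Pairwise Pearson correlation of samples on log2(x + 1) abundance.

    Returns the symmetric sample correlation matrix (unit diagonal) and
    the average-linkage hierarchical clustering of the samples on
    distance 1 - r (a scipy linkage matrix).  Samples that are constant
    after the log transform have undefined correlations: their entries
    are NaN and they are excluded from clustering with a warning.
    """
    if norm.values.shape[1] < 2:
        raise ValueError("tissue similarity needs at least 2 samples")
    logx = np.log2(norm.values + 1.0)
    # a constant column can carry ~1e-16 numerical std; treat it as zero
    sd = logx.std(axis=0, ddof=1)
    constant = sd.index[sd <= 1e-12]
    corr = logx.corr(method="pearson")  # pandas leaves NaN for zero-variance cols
    np.fill_diagonal(corr.values, 1.0)
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    for s in constant:
        corr.loc[s, s] = 1.0
    if len(constant):
        logger.warning(
            "%d constant sample(s) excluded from clustering: %s",
            len(constant), list(constant),
        )
    usable = corr.index.difference(constant)
    tree = None
    if len(usable) >= 2:
        sub = corr.loc[usable, usable].to_numpy()
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        tree = linkage(squareform(dist, checks=False), method=linkage_method)
    return corr, tree
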