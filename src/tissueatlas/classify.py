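"""Universal / tissue-associated / tissue-specific classification.

The three categories follow the atlas rules:

* universal mRNA — RPKM strictly above a floor (default 10) in every
  tissue;
* universal miRNA — TPM strictly above 1 in every tissue AND
  across-tissue coefficient of variation below 0.5;
* tissue-associated — across-tissue z-score >= 1.5 in that tissue with
  abundance >= 1 there;
* tissue-specific — abundance >= 10 in the tissue and greater than
  10-fold the mean abundance of all *other* tissues.

All statistics use the sample (n-1) standard deviation.  For the fold
rule the comparison mean is the leave-one-out mean; when that mean is 0
the fold condition is vacuously satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import NormalizedMatrix

__all__ = [
    "ClassificationResult",
    "find_universal_mrna",
    "find_universal_mirna",
    "find_tissue_associated",
    "find_tissue_specific",
]


@dataclass
class ClassificationResult:
    """Feature sets per category, with the statistic that earned each call."""

    universal: set[str] = field(default_factory=set)
    associated: dict[str, pd.Series] = field(default_factory=dict)  # tissue -> z per feature
    specific: dict[str, pd.Series] = field(default_factory=dict)    # tissue -> fold per feature
    parameters: dict = field(default_factory=dict)

    def associated_ids(self, tissue: str) -> set[str]:
        return set(self.associated.get(tissue, pd.Series(dtype=float)).index)

    def specific_ids(self, tissue: str) -> set[str]:
        return set(self.specific.get(tissue, pd.Series(dtype=float)).index)

    def all_specific_ids(self) -> set[str]:
        out: set[str] = set()
        for s in self.specific.values():
            out |= set(s.index)
        return out


def _values(expr: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    return expr.values if isinstance(expr, NormalizedMatrix) else expr


def find_universal_mrna(rpkm: NormalizedMatrix | pd.DataFrame, min_value: float = 10.0) -> set[str]:
    """Features whose abundance strictly exceeds ``min_value`` in every tissue."""
    v = _values(rpkm)
    mask = (v > min_value).all(axis=1)
    return set(v.index[mask])


def find_universal_mirna(
    tpm: NormalizedMatrix | pd.DataFrame,
    min_value: float = 1.0,
    cv_max: float = 0.5,
) -> set[str]:
    """Features above ``min_value`` everywhere with CV (sd/mean) below ``cv_max``.

    The CV uses the sample standard deviation (n-1 denominator) across
    tissue columns.  A constant profile has CV 0 and qualifies if it
    clears the floor.
    """
    v = _values(tpm)
    if v.shape[1] < 2:
        raise ValueError("universal-miRNA rule needs >= 2 tissue columns")
    floor = (v > min_value).all(axis=1)
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv = cv.fillna(np.inf)
    cv[(sd == 0) & (mean > 0)] = 0.0
    return set(v.index[floor & (cv < cv_max)])


def find_tissue_associated(
    expr: NormalizedMatrix | pd.DataFrame,
    z_min: float = 1.5,
    expr_min: float = 1.0,
) -> dict[str, pd.Series]:
    """Per tissue, features with across-tissue z-score >= ``z_min`` there.

    z_t = (x_t - mean) / sd with the n-1 standard deviation over tissue
    columns; the feature must also satisfy x_t >= ``expr_min``.  A
    feature may be associated with several tissues; zero-variance
    profiles are associated with none.
    """
    v = _values(expr)
    if v.shape[1] < 3:
        raise ValueError("tissue association needs >= 3 tissue columns")
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    ok_sd = sd > 0
    z = v.sub(mean, axis=0).div(sd.where(ok_sd), axis=0)
    out: dict[str, pd.Series] = {}
    for tissue in v.columns:
        hit = ok_sd & (z[tissue] >= z_min) & (v[tissue] >= expr_min)
        if hit.any():
            out[tissue] = z.loc[hit, tissue]
    return out


def find_tissue_specific(
    expr: NormalizedMatrix | pd.DataFrame,
    fold: float = 10.0,
    expr_min: float = 10.0,
) -> dict[str, pd.Series]:
    """Per tissue, features >= ``expr_min`` there and > ``fold`` x the mean of the rest.

    The comparison mean leaves the candidate tissue out.  When every
    other tissue is 0 the fold condition holds vacuously.  The reported
    statistic is x_t / leave-one-out mean (inf when that mean is 0).
    """
    v = _values(expr)
    if v.shape[1] < 2:
        raise ValueError("tissue specificity needs >= 2 tissue columns")
    n = v.shape[1]
    total = v.sum(axis=1)
    out: dict[str, pd.Series] = {}
    for tissue in v.columns:
        loo_mean = (total - v[tissue]) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = v[tissue] / loo_mean
        ratio[loo_mean == 0] = np.inf
        hit = (v[tissue] >= expr_min) & ((v[tissue] > fold * loo_mean) | (loo_mean == 0))
        if hit.any():
            out[tissue] = ratio[hit]
    return out


def classify_atlas(
    expr: NormalizedMatrix | pd.DataFrame,
    *,
    kind: str = "mrna",
    universal_min: float = 10.0,
    universal_cv_max: float = 0.5,
    z_min: float = 1.5,
    associated_expr_min: float = 1.0,
    fold: float = 10.0,
    specific_expr_min: float = 10.0,
) -> ClassificationResult:
    """Run all three classifiers on one tissue-panel matrix."""
    if kind == "mrna":
        universal = find_universal_mrna(expr, universal_min)
    elif kind == "mirna":
        universal = find_universal_mirna(expr, universal_min, universal_cv_max)
    else:
        raise ValueError(f"kind must be 'mrna' or 'mirna', got {kind!r}")
    return ClassificationResult(
        universal=universal,
        associated=find_tissue_associated(expr, z_min, associated_expr_min),
        specific=find_tissue_specific(expr, fold, specific_expr_min),
        parameters={
            "kind": kind,
            "universal_min": universal_min,
            "universal_cv_max": universal_cv_max,
            "z_min": z_min,
            "associated_expr_min": associated_expr_min,
            "fold": fold,
            "specific_expr_min": specific_expr_min,
        },
    )
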