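"""Intragenic miRNA / host-gene co-expression pairs.

A miRNA is an intragenic candidate of a protein-coding gene when its
locus is fully contained in the gene span on the same strand.  The
five filters applied are: (1) containment, (2) same strand, (3) the
miRNA is single-copy in the genome, (4) both partners are expressed
(abundance >= 0.1) in at least five tissues, and (5) their expression
profiles correlate at r > 0.6 with p < 0.05 (two-sided t test on the
Pearson coefficient).  The filters are pure predicates over a
candidate, so they commute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureAnnotation
from .quantify import NormalizedMatrix

__all__ = [
    "HostPairCandidate",
    "find_intragenic_candidates",
    "filter_single_copy",
    "filter_expression_breadth",
    "filter_host_correlation",
    "find_host_pairs",
]


@dataclass
class HostPairCandidate:
    """One intragenic miRNA / host-gene pair with its per-criterion flags."""

    mirna_id: str
    gene_id: str
    containment: bool = True
    same_strand: bool = True
    copy_count: int = 1
    breadth_mirna: int | None = None
    breadth_gene: int | None = None
    r: float | None = None
    p: float | None = None
    r_defined: bool = True

    @property
    def passed(self) -> bool:
        return (
            self.containment
            and self.same_strand
            and self.copy_count == 1
            and self.breadth_mirna is not None
            and self.breadth_gene is not None
            and self._breadth_ok
            and self._corr_ok
        )

    # thresholds recorded at filter time
    _breadth_ok: bool = False
    _corr_ok: bool = False


def find_intragenic_candidates(
    mirnas: FeatureAnnotation,
    genes: FeatureAnnotation,
    include_partial: bool = False,
) -> list[HostPairCandidate]:
    """All (miRNA locus, gene) pairs with full containment and equal strand.

    Containment is interval containment on the same chromosome with
    0-based half-open coordinates: mirna.start >= gene.start and
    mirna.end <= gene.end.  With ``include_partial`` every overlapping
    pair is emitted with its ``containment`` flag, so containment can be
    applied as a standalone filter.
    """
    out: list[HostPairCandidate] = []
    gene_rows = genes.of_type("gene")
    mir_rows = mirnas.of_type("miRNA")
    by_chrom = dict(tuple(gene_rows.groupby("chrom", sort=False)))
    for m in mir_rows.itertuples(index=False):
        for g in by_chrom.get(m.chrom, pd.DataFrame()).itertuples(index=False):
            overlaps = m.start < g.end and g.start < m.end
            contained = m.start >= g.start and m.end <= g.end
            if not (contained or (include_partial and overlaps)):
                continue
            out.append(
                HostPairCandidate(
                    mirna_id=m.name,
                    gene_id=g.name,
                    containment=contained,
                    same_strand=(m.strand == g.strand),
                    copy_count=mirnas.copy_count(m.name),
                )
            )
    return out


def filter_containment(candidates: list[HostPairCandidate]) -> list[HostPairCandidate]:
    """Keep fully contained miRNA loci (criterion 1)."""
    return [c for c in candidates if c.containment]


def filter_same_strand(candidates: list[HostPairCandidate]) -> list[HostPairCandidate]:
    """Keep pairs transcribed from the same DNA strand (criterion 2)."""
    return [c for c in candidates if c.same_strand]


def filter_single_copy(
    candidates: list[HostPairCandidate], mirnas: FeatureAnnotation
) -> list[HostPairCandidate]:
    """Keep candidates whose miRNA has exactly one genomic locus."""
    for c in candidates:
        c.copy_count = mirnas.copy_count(c.mirna_id)
    return [c for c in candidates if c.copy_count == 1]


def filter_expression_breadth(
    candidates: list[HostPairCandidate],
    mirna_tpm: NormalizedMatrix | pd.DataFrame,
    mrna_rpkm: NormalizedMatrix | pd.DataFrame,
    min_tissues: int = 5,
    threshold: float = 0.1,
) -> list[HostPairCandidate]:
    """Keep pairs where both partners reach ``threshold`` in >= ``min_tissues``.

    The breadth comparison is inclusive (value >= threshold), matching
    the stated ">= 0.1" criterion, unlike the strict any-sample
    expressed flag.
    """
    tpm = mirna_tpm.values if isinstance(mirna_tpm, NormalizedMatrix) else mirna_tpm
    rpkm = mrna_rpkm.values if isinstance(mrna_rpkm, NormalizedMatrix) else mrna_rpkm
    kept = []
    for c in candidates:
        if c.mirna_id not in tpm.index:
            raise KeyError(f"candidate miRNA {c.mirna_id!r} absent from the miRNA matrix")
        if c.gene_id not in rpkm.index:
            raise KeyError(f"candidate gene {c.gene_id!r} absent from the mRNA matrix")
        c.breadth_mirna = int((tpm.loc[c.mirna_id] >= threshold).sum())
        c.breadth_gene = int((rpkm.loc[c.gene_id] >= threshold).sum())
        c._breadth_ok = c.breadth_mirna >= min_tissues and c.breadth_gene >= min_tissues
        if c._breadth_ok:
            kept.append(c)
    return kept


def correlation_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p from t = r * sqrt((n-2)/(1-r^2))."""
    n = len(x)
    if n < 3:
        raise ValueError("correlation test needs >= 3 samples")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def filter_host_correlation(
    candidates: list[HostPairCandidate],
    mirna_tpm: NormalizedMatrix | pd.DataFrame,
    mrna_rpkm: NormalizedMatrix | pd.DataFrame,
    r_min: float = 0.6,
    p_max: float = 0.05,
) -> list[HostPairCandidate]:
    """Attach Pearson r and p over shared samples; keep p < p_max and r > r_min.

    Zero-variance profiles make r undefined: the pair fails with
    ``r_defined=False``.
    """
    tpm = mirna_tpm.values if isinstance(mirna_tpm, NormalizedMatrix) else mirna_tpm
    rpkm = mrna_rpkm.values if isinstance(mrna_rpkm, NormalizedMatrix) else mrna_rpkm
    shared = [s for s in tpm.columns if s in set(rpkm.columns)]
    if len(shared) < 3:
        raise ValueError("correlation test needs >= 3 shared samples")
    kept = []
    for c in candidates:
        x = tpm.loc[c.mirna_id, shared].to_numpy(dtype=float)
        y = rpkm.loc[c.gene_id, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            c.r, c.p, c.r_defined, c._corr_ok = None, None, False, False
            continue
        c.r, c.p = correlation_with_p(x, y)
        c._corr_ok = c.p < p_max and c.r > r_min
        if c._corr_ok:
            kept.append(c)
    return kept


def find_host_pairs(
    mirnas: FeatureAnnotation,
    genes: FeatureAnnotation,
    mirna_tpm: NormalizedMatrix | pd.DataFrame,
    mrna_rpkm: NormalizedMatrix | pd.DataFrame,
    min_tissues: int = 5,
    breadth_threshold: float = 0.1,
    r_min: float = 0.6,
    p_max: float = 0.05,
) -> tuple[list[HostPairCandidate], list[HostPairCandidate]]:
    """Run the full five-criterion pipeline.

    Returns ``(passed, all_candidates)`` where ``all_candidates`` holds
    every containment candidate with its flags filled in (for
    reporting), strand violations included.
    """
    candidates = find_intragenic_candidates(mirnas, genes)
    survivors = filter_same_strand(candidates)
    survivors = filter_single_copy(survivors, mirnas)
    survivors = filter_expression_breadth(
        survivors, mirna_tpm, mrna_rpkm, min_tissues, breadth_threshold
    )
    survivors = filter_host_correlation(survivors, mirna_tpm, mrna_rpkm, r_min, p_max)
    return survivors, candidates


def host_pair_table(candidates: list[HostPairCandidate]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": c.mirna_id,
            "gene_id": c.gene_id,
            "containment": c.containment,
            "same_strand": c.same_strand,
            "copy_count": c.copy_count,
            "breadth_mirna": c.breadth_mirna,
            "breadth_gene": c.breadth_gene,
            "r": np.nan if c.r is None else c.r,
            "p": np.nan if c.p is None else c.p,
            "passed": c.passed,
        }
        for c in sorted(candidates, key=lambda c: (c.mirna_id, c.gene_id))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "gene_id", "containment", "same_strand", "copy_count",
            "breadth_mirna", "breadth_gene", "r", "p", "passed",
        ],
    )
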