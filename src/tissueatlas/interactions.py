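"""miRNA-target interaction screening.

Candidate repressive interactions are (miRNA, mRNA) pairs whose
expression profiles are negatively correlated (Pearson r < -0.5).
Each screened pair must then carry a canonical seed site in the
target's 3'UTR — an exact Watson-Crick match to miRNA seed positions
2-7/2-8, with the 8mer > 7mer-m8 > 7mer-A1 site hierarchy and no G:U
pairing in the seed — and may optionally be required to form a stable
duplex under a reduced nearest-neighbor hybridization model.  Pairs
that additionally stay anti-correlated across the three muscle
developmental stages form the persistent set.

Sequence conventions: all sequences are 5'->3' uppercase RNA.  A site
is anchored at the UTR position ``q`` opposite miRNA position 1; since
the duplex is antiparallel, miRNA position k pairs with UTR position
q - (k - 1), so the seed match lies 5' of ``q`` on the target.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SequenceSet
from .quantify import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSite",
    "DuplexResult",
    "InteractionRecord",
    "screen_negative_correlation",
    "find_seed_sites",
    "duplex_mfe",
    "assemble_interactions",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_RNA = frozenset("ACGU")

# site-type hierarchy, strongest first
SITE_TIERS = ("8mer", "7mer-m8", "7mer-A1")


def _check_rna(seq: str, label: str) -> str:
    s = seq.upper().replace("T", "U")
    for i, ch in enumerate(s):
        if ch not in _RNA:
            raise ValueError(f"{label}: non-nucleotide symbol {ch!r} at position {i}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def screen_negative_correlation(
    mirna_expr: NormalizedMatrix | pd.DataFrame,
    mrna_expr: NormalizedMatrix | pd.DataFrame,
    r_max: float = -0.5,
    sample_set: list[str] | None = None,
) -> pd.DataFrame:
    """All (miRNA, gene) pairs with Pearson r strictly below ``r_max``.

    Correlations run over ``sample_set`` columns (default: the shared
    columns of the two matrices, in miRNA-matrix order).  Features with
    zero variance over those columns are excluded with a logged count.
    Returns a table with columns ``mirna_id``, ``gene_id``, ``r``.
    """
    mi = mirna_expr.values if isinstance(mirna_expr, NormalizedMatrix) else mirna_expr
    mr = mrna_expr.values if isinstance(mrna_expr, NormalizedMatrix) else mrna_expr
    if sample_set is None:
        sample_set = [s for s in mi.columns if s in set(mr.columns)]
    if len(sample_set) < 3:
        raise ValueError("correlation screen needs >= 3 shared samples")
    a = mi[sample_set].to_numpy(dtype=float)
    b = mr[sample_set].to_numpy(dtype=float)
    sd_a, sd_b = a.std(axis=1), b.std(axis=1)
    keep_a, keep_b = sd_a > 0, sd_b > 0
    dropped = int((~keep_a).sum() + (~keep_b).sum())
    if dropped:
        logger.info("screen: excluded %d zero-variance profile(s)", dropped)
    a, b = a[keep_a], b[keep_b]
    mir_ids = mi.index[keep_a]
    gene_ids = mr.index[keep_b]
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame(columns=["mirna_id", "gene_id", "r"])
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    corr = az @ bz.T / a.shape[1]
    ii, jj = np.nonzero(corr < r_max)
    out = pd.DataFrame(
        {
            "mirna_id": mir_ids[ii],
            "gene_id": gene_ids[jj],
            "r": corr[ii, jj],
        }
    )
    return out.sort_values(["r", "mirna_id", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# seed sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-match site on a 3'UTR.

    ``utr_position`` is the 0-based offset of the site's 5'-most target
    nucleotide; ``matched_span`` is the half-open UTR interval covered
    by the site; ``site_type`` is the highest tier the position
    supports (8mer > 7mer-m8 > 7mer-A1).
    """

    utr_position: int
    site_type: str
    matched_span: tuple[int, int]


def find_seed_sites(mirna_seq: str, utr_seq: str) -> list[SeedSite]:
    """Scan a 3'UTR for canonical seed sites of one miRNA.

    For each anchor ``q`` (UTR index opposite miRNA position 1):

    * 8mer — UTR[q-7..q-1] is the exact Watson-Crick complement of
      miRNA positions 8..2 (antiparallel) and UTR[q] == 'A';
    * 7mer-m8 — the same seed 2-8 match, any (or no) nucleotide at q;
    * 7mer-A1 — seed 2-7 match (UTR[q-6..q-1]) plus UTR[q] == 'A'.

    The 'A' of A1-type sites is a sequence requirement on the target,
    not a pairing requirement, so it need not complement the miRNA.
    Only the highest tier is reported per anchor.  G:U pairs never
    count as seed matches.
    """
    m = _check_rna(mirna_seq, "miRNA")
    u = _check_rna(utr_seq, "UTR")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    match28 = reverse_complement(m[1:8])  # pairs UTR[q-7..q-1], 5'->3'
    match27 = reverse_complement(m[1:7])  # pairs UTR[q-6..q-1]
    comp_m8 = _COMPLEMENT[m[7]]
    found: dict[int, SeedSite] = {}
    # seed 2-8 matches; the anchor q may equal len(u): a 7mer-m8 site can
    # end flush with the UTR 3' end
    p = u.find(match28)
    while p >= 0:
        q = p + 7
        if q < len(u) and u[q] == "A":
            found[q] = SeedSite(q - 7, "8mer", (q - 7, q + 1))
        else:
            found[q] = SeedSite(q - 7, "7mer-m8", (q - 7, q))
        p = u.find(match28, p + 1)
    # seed 2-7 matches with a target 'A' opposite position 1, unless the
    # anchor already carries a 2-8 match (reported above at higher tier)
    p = u.find(match27)
    while p >= 0:
        q = p + 6
        if q < len(u) and u[q] == "A" and not (q >= 7 and u[q - 7] == comp_m8):
            found[q] = SeedSite(q - 6, "7mer-A1", (q - 6, q + 1))
        p = u.find(match27, p + 1)
    return [found[q] for q in sorted(found)]


# ---------------------------------------------------------------------------
# duplex hybridization energy
# ---------------------------------------------------------------------------

# admissible base pairs: Watson-Crick plus G:U wobble
_PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

# reduced nearest-neighbor stack table: the energy of stacking pair p2
# directly on pair p1 is -(w(p1) + w(p2)) kcal/mol, a pair-additive
# reduction of the Turner parameters that keeps G:C > A:U > G:U
# ordering and is symmetric under reading the duplex from either side
_PAIR_WEIGHT = {
    ("G", "C"): 1.6, ("C", "G"): 1.6,
    ("A", "U"): 1.1, ("U", "A"): 1.1,
    ("G", "U"): 0.5, ("U", "G"): 0.5,
}

INITIATION = 4.1      # duplex initiation, kcal/mol
LOOP_OPEN = 4.0       # bulge/internal-loop opening
LOOP_EXTEND = 0.5     # per unpaired nucleotide inside a loop
MAX_TARGET_WINDOW = 60


@dataclass
class DuplexResult:
    """Minimum-free-energy intermolecular duplex.

    ``pairing`` lists (miRNA position, target position) base pairs,
    both 0-based, strictly increasing in the miRNA coordinate and
    strictly decreasing in the target coordinate (antiparallel).
    ``mfe`` is 0 with empty pairing when no stabilizing duplex exists.
    """

    mfe: float
    pairing: list[tuple[int, int]] = field(default_factory=list)


def _stack_energy(p1: tuple[str, str], p2: tuple[str, str]) -> float:
    return -(_PAIR_WEIGHT[p1] + _PAIR_WEIGHT[p2])


def duplex_mfe(mirna_seq: str, target_window: str) -> DuplexResult:
    """Best intermolecular duplex between a miRNA and a target window.

    Dynamic programming over antiparallel, non-crossing pairings with
    no intramolecular structure.  Energy model: +4.1 initiation, stack
    terms from the reduced nearest-neighbor table for adjacent pairs,
    +4.0 loop opening plus +0.5 per unpaired nucleotide between
    non-adjacent pairs.  Dangling ends are free.  If the best duplex
    is not stabilizing (energy > 0), returns mfe 0 with no pairs.
    """
    a = _check_rna(mirna_seq, "miRNA")
    b = _check_rna(target_window, "target")
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(b) > MAX_TARGET_WINDOW:
        raise ValueError(
            f"target window of {len(b)} nt exceeds the {MAX_TARGET_WINDOW} nt guard"
        )
    n, m = len(a), len(b)
    INF = float("inf")
    # E[i][j]: best energy of a duplex whose 3'-most miRNA pair is (i, j);
    # D[i][j]: min over earlier pairs (pi <= i, pj >= j) of
    #   E[pi][pj] + LOOP_EXTEND * ((i - pi) + (pj - j)),
    # maintained as a running prefix-min so each cell is O(1)
    E = [[INF] * m for _ in range(n)]
    D = [[INF] * m for _ in range(n)]
    Dptr: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    pairable = [[(a[i], b[j]) in _PAIRABLE for j in range(m)] for i in range(n)]
    best_e, best_cell = INF, None
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if pairable[i][j]:
                best = INITIATION
                origin: tuple[int, int] | None = None
                if i > 0 and j < m - 1:
                    if pairable[i - 1][j + 1] and E[i - 1][j + 1] < INF:
                        cand = E[i - 1][j + 1] + _stack_energy(
                            (a[i - 1], b[j + 1]), (a[i], b[j])
                        )
                        if cand < best:
                            best, origin = cand, (i - 1, j + 1)
                    if D[i - 1][j + 1] < INF:
                        cand = D[i - 1][j + 1] + LOOP_OPEN
                        if cand < best:
                            best, origin = cand, Dptr[i - 1][j + 1]
                E[i][j] = best
                back[(i, j)] = origin
                if best < best_e:
                    best_e, best_cell = best, (i, j)
            # prefix-min update for D
            d, ptr = E[i][j], ((i, j) if E[i][j] < INF else None)
            if i > 0 and D[i - 1][j] + LOOP_EXTEND < d:
                d, ptr = D[i - 1][j] + LOOP_EXTEND, Dptr[i - 1][j]
            if j < m - 1 and D[i][j + 1] + LOOP_EXTEND < d:
                d, ptr = D[i][j + 1] + LOOP_EXTEND, Dptr[i][j + 1]
            D[i][j], Dptr[i][j] = d, ptr
    if best_cell is None or best_e > 0:
        return DuplexResult(0.0, [])
    pairs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = best_cell
    while cur is not None:
        pairs.append(cur)
        cur = back[cur]
    pairs.reverse()
    return DuplexResult(float(best_e), pairs)


def best_site_mfe(
    mirna_seq: str, utr_seq: str, sites: list[SeedSite], flank: int = 17
) -> float:
    """Lowest duplex energy over windows around each seed site.

    The window spans the site plus ``flank`` nt of 5' UTR context (where
    the miRNA 3' end can pair) and 3 nt of 3' context, capped at the DP
    guard length.
    """
    best = 0.0
    u = _check_rna(utr_seq, "UTR")
    for site in sites:
        lo = max(0, site.matched_span[0] - flank)
        hi = min(len(u), site.matched_span[1] + 3)
        window = u[lo:hi]
        if not window:
            continue
        res = duplex_mfe(mirna_seq, window)
        best = min(best, res.mfe)
    return best


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class InteractionRecord:
    """A screened miRNA-mRNA pair with site, energy and persistence calls."""

    mirna_id: str
    gene_id: str
    r: float
    r_stages: float | None
    sites: list[SeedSite] = field(default_factory=list)
    best_mfe: float = 0.0
    passed_screen: bool = False
    passed_sites: bool = False
    passed_persistence: bool = False


def assemble_interactions(
    screened: pd.DataFrame,
    mirna_seqs: SequenceSet,
    utr_seqs: SequenceSet,
    mirna_stage_expr: pd.DataFrame | None = None,
    mrna_stage_expr: pd.DataFrame | None = None,
    r_max: float = -0.5,
    mfe_filter: bool = False,
    mfe_max: float = -15.0,
) -> list[InteractionRecord]:
    """Attach seed sites, duplex energy and stage persistence to screened pairs.

    ``screened`` is the table from :func:`screen_negative_correlation`.
    Pairs missing a mature-miRNA or 3'UTR sequence are dropped with a
    logged count.  ``passed_sites`` requires at least one canonical
    seed site (and ``best_mfe <= mfe_max`` when ``mfe_filter``);
    ``passed_persistence`` requires the stage-wise correlation (over
    the developmental-stage columns of the ``*_stage_expr`` matrices,
    e.g. D0/D30/D240) to fall below ``r_max`` as well.  The final
    reported set is the records with ``passed_screen and passed_sites``;
    output is sorted by r ascending, ties by (miRNA, gene).
    """
    records: list[InteractionRecord] = []
    missing = 0
    for row in screened.itertuples(index=False):
        if row.mirna_id not in mirna_seqs or row.gene_id not in utr_seqs:
            missing += 1
            continue
        sites = find_seed_sites(mirna_seqs[row.mirna_id], utr_seqs[row.gene_id])
        mfe = (
            best_site_mfe(mirna_seqs[row.mirna_id], utr_seqs[row.gene_id], sites)
            if sites
            else 0.0
        )
        r_stages = None
        if mirna_stage_expr is not None and mrna_stage_expr is not None:
            if (
                row.mirna_id in mirna_stage_expr.index
                and row.gene_id in mrna_stage_expr.index
            ):
                x = mirna_stage_expr.loc[row.mirna_id].to_numpy(dtype=float)
                y = mrna_stage_expr.loc[row.gene_id].to_numpy(dtype=float)
                if x.std() > 0 and y.std() > 0:
                    r_stages = float(np.corrcoef(x, y)[0, 1])
        passed_sites = bool(sites) and (not mfe_filter or mfe <= mfe_max)
        records.append(
            InteractionRecord(
                mirna_id=row.mirna_id,
                gene_id=row.gene_id,
                r=float(row.r),
                r_stages=r_stages,
                sites=sites,
                best_mfe=mfe,
                passed_screen=row.r < r_max,
                passed_sites=passed_sites,
                passed_persistence=r_stages is not None and r_stages < r_max,
            )
        )
    if missing:
        logger.info("assemble: dropped %d pair(s) lacking sequences", missing)
    records.sort(key=lambda rec: (rec.r, rec.mirna_id, rec.gene_id))
    return records


def interaction_table(records: list[InteractionRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": rec.mirna_id,
            "gene_id": rec.gene_id,
            "r": rec.r,
            "r_stages": np.nan if rec.r_stages is None else rec.r_stages,
            "n_sites": len(rec.sites),
            "best_site_type": rec.sites[0].site_type if rec.sites else "",
            "best_mfe": rec.best_mfe,
            "passed_screen": rec.passed_screen,
            "passed_sites": rec.passed_sites,
            "passed_persistence": rec.passed_persistence,
        }
        for rec in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "gene_id", "r", "r_stages", "n_sites", "best_site_type",
            "best_mfe", "passed_screen", "passed_sites", "passed_persistence",
        ],
    )


def site_table(records: list[InteractionRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": rec.mirna_id,
            "gene_id": rec.gene_id,
            "utr_position": s.utr_position,
            "site_type": s.site_type,
            "span_start": s.matched_span[0],
            "span_end": s.matched_span[1],
        }
        for rec in records
        for s in rec.sites
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "utr_position", "site_type", "span_start", "span_end"],
    )
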