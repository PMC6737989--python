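"""Synthetic multi-tissue mRNA/miRNA atlas with planted ground truth.

The generator emulates the study design every downstream stage expects:
nine tissues with skeletal muscle sampled at three developmental stages
(D0, D30, D240), negative-binomial counts, planted universally
expressed genes, planted tissue-specific genes at a controlled fold,
intragenic same-strand single-copy miRNAs co-expressed with their host
genes, and planted repressor miRNA-target pairs that are anti-correlated
across the muscle stages and carry genuine canonical seed sites in the
target 3'UTR (decoy pairs are anti-correlated but carry a scrambled,
site-free UTR).

Expression is planted on the normalized scale (expected RPKM for genes,
expected TPM for miRNAs); background features are rescaled per sample so
the planted values survive normalization exactly in expectation, and
counts are drawn as gamma-Poisson mixtures with the designed mean and
dispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interactions import find_seed_sites, reverse_complement
from .io import (
    FeatureAnnotation,
    SequenceSet,
    read_annotation,
    read_count_matrix,
    read_fasta,
    write_annotation,
    write_count_matrix,
    write_fasta,
)

__all__ = ["SimulationDesign", "TruthBundle", "simulate_atlas", "write_fixture_bundle", "read_fixture_bundle"]

DEFAULT_TISSUES = (
    "fat", "heart", "kidney", "liver", "lung", "muscle", "ovary", "spleen", "testis"
)
DEFAULT_STAGES = ("muscle_D0", "muscle_D30", "muscle_D240")

_RNA = "ACGU"


@dataclass(frozen=True)
class SimulationDesign:
    """Design parameters of one synthetic atlas.

    ``library_depth`` / ``mirna_library_depth`` are expected mapped
    reads per sample; ``nb_dispersion`` is the NB dispersion alpha in
    Var = mu + alpha mu^2 (0 gives Poisson counts); fold and fraction
    semantics follow the planted-truth definitions in the module
    docstring.
    """

    tissue_names: tuple[str, ...] = DEFAULT_TISSUES
    stage_names: tuple[str, ...] = DEFAULT_STAGES
    n_genes: int = 5000
    n_mirnas: int = 300
    frac_universal: float = 0.006
    n_specific_per_tissue: int = 20
    n_associated_per_tissue: int = 10
    specific_fold_planted: float = 50.0
    frac_intragenic_mirna: float = 0.1
    n_repressor_pairs: int = 10
    n_decoy_pairs: int = 10
    plant_host_violations: bool = True
    nb_dispersion: float = 0.1
    library_depth: float = 2e7
    mirna_library_depth: float = 2e6
    gene_length_range: tuple[int, int] = (500, 5000)
    utr_length: int = 500
    mirna_length: int = 22
    specificity_cutoff: float = 10.0   # planted fold must exceed this
    seed: int = 0

    @property
    def sample_names(self) -> list[str]:
        cols = []
        for t in self.tissue_names:
            if t == "muscle":
                cols.extend(self.stage_names)
            else:
                cols.append(t)
        return cols

    @property
    def tissue_panel(self) -> dict[str, str]:
        """Map tissue -> the sample column representing it in the atlas panel."""
        panel = {}
        for t in self.tissue_names:
            panel[t] = self.stage_names[-1] if t == "muscle" else t
        return panel

    def validate(self) -> None:
        for name in ("frac_universal", "frac_intragenic_mirna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "n_mirnas", "utr_length", "mirna_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.specific_fold_planted <= self.specificity_cutoff:
            raise ValueError(
                "planted specific fold must exceed the specificity cutoff "
                f"({self.specific_fold_planted} <= {self.specificity_cutoff}): "
                "recovery would be ill-posed"
            )
        if self.gene_length_range[0] < self.utr_length // 2 + 100:
            raise ValueError("gene_length_range too short for the UTR model")
        n_univ = int(round(self.frac_universal * self.n_genes))
        n_planted_genes = (
            n_univ
            + len(self.tissue_names) * (self.n_specific_per_tissue + self.n_associated_per_tissue)
            + self.n_repressor_pairs
            + self.n_decoy_pairs
        )
        if n_planted_genes > self.n_genes:
            raise ValueError(
                f"design infeasible: {n_planted_genes} planted genes > n_genes={self.n_genes}"
            )
        n_intragenic = int(round(self.frac_intragenic_mirna * self.n_mirnas))
        n_planted_mirnas = (
            n_intragenic
            + self.n_repressor_pairs
            + self.n_decoy_pairs
            + (5 if self.plant_host_violations else 0)
        )
        if n_planted_mirnas > self.n_mirnas:
            raise ValueError(
                f"design infeasible: {n_planted_mirnas} planted miRNAs > n_mirnas={self.n_mirnas}"
            )
        if n_intragenic + (5 if self.plant_host_violations else 0) > self.n_genes - n_planted_genes:
            raise ValueError("design infeasible: not enough background genes to host miRNAs")


@dataclass
class TruthBundle:
    """Planted ground-truth labels for recovery testing."""

    universal_ids: set[str] = field(default_factory=set)
    specific_ids: dict[str, set[str]] = field(default_factory=dict)
    associated_ids: dict[str, set[str]] = field(default_factory=dict)
    host_pairs: set[tuple[str, str]] = field(default_factory=set)
    repressor_pairs: set[tuple[str, str, int, str]] = field(default_factory=set)
    decoy_pairs: set[tuple[str, str]] = field(default_factory=set)
    host_violations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    universal_mirna_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        rep = {(m, g) for m, g, _, _ in self.repressor_pairs}
        if rep & self.decoy_pairs:
            raise ValueError("repressor and decoy pair sets must be disjoint")
        seen: set[str] = set()
        for tissue, ids in self.specific_ids.items():
            overlap = seen & ids
            if overlap:
                raise ValueError(f"specific genes planted in two tissues: {overlap}")
            seen |= ids

    def to_json(self) -> str:
        return json.dumps(
            {
                "universal_ids": sorted(self.universal_ids),
                "specific_ids": {t: sorted(s) for t, s in self.specific_ids.items()},
                "associated_ids": {t: sorted(s) for t, s in self.associated_ids.items()},
                "host_pairs": sorted(map(list, self.host_pairs)),
                "repressor_pairs": sorted(map(list, self.repressor_pairs)),
                "decoy_pairs": sorted(map(list, self.decoy_pairs)),
                "host_violations": {
                    k: sorted(map(list, v)) for k, v in self.host_violations.items()
                },
                "universal_mirna_ids": sorted(self.universal_mirna_ids),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthBundle":
        d = json.loads(text)
        return cls(
            universal_ids=set(d["universal_ids"]),
            specific_ids={t: set(v) for t, v in d["specific_ids"].items()},
            associated_ids={t: set(v) for t, v in d["associated_ids"].items()},
            host_pairs={tuple(p) for p in d["host_pairs"]},
            repressor_pairs={(m, g, int(q), s) for m, g, q, s in d["repressor_pairs"]},
            decoy_pairs={tuple(p) for p in d["decoy_pairs"]},
            host_violations={k: {tuple(p) for p in v} for k, v in d["host_violations"].items()},
            universal_mirna_ids=set(d["universal_mirna_ids"]),
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with Var = mu + alpha mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(np.clip(mean, 0, None))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.clip(mean, 0, None) * dispersion)
    return rng.poisson(lam)


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_RNA), size=length))


def _site_sequence(rng: np.random.Generator, mirna: str) -> tuple[str, str]:
    """A canonical target site (sequence, type) for a miRNA, type drawn uniformly."""
    site_type = rng.choice(["8mer", "7mer-m8", "7mer-A1"])
    if site_type == "8mer":
        seq = reverse_complement(mirna[1:8]) + "A"
    elif site_type == "7mer-m8":
        seq = reverse_complement(mirna[1:8])
        # avoid an accidental upgrade to 8mer at this position
    else:
        seq = reverse_complement(mirna[1:7]) + "A"
    return seq, str(site_type)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate_atlas(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, FeatureAnnotation, SequenceSet, TruthBundle]:
    """Build one synthetic atlas.

    Returns ``(mrna_counts, mirna_counts, annotation, sequences, truth)``.
    ``sequences`` holds mature miRNAs under their miRNA IDs and 3'UTRs
    under ``<gene_id>_3UTR``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    samples = design.sample_names
    n_samples = len(samples)
    tissues = list(design.tissue_names)
    panel = design.tissue_panel
    stage_cols = list(design.stage_names)
    muscle_cols = set(stage_cols)

    gene_ids = [f"gene_{i:05d}" for i in range(design.n_genes)]
    mirna_ids = [f"mir_{i:04d}" for i in range(design.n_mirnas)]
    lengths = rng.integers(
        design.gene_length_range[0], design.gene_length_range[1] + 1, size=design.n_genes
    ).astype(float)

    # ----- allocate planted roles ------------------------------------
    n_univ = int(round(design.frac_universal * design.n_genes))
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = gene_ids[cursor : cursor + n]
        cursor += n
        return out

    universal_genes = take(n_univ)
    specific_genes = {t: take(design.n_specific_per_tissue) for t in tissues}
    associated_genes = {t: take(design.n_associated_per_tissue) for t in tissues}
    repressor_targets = take(design.n_repressor_pairs)
    decoy_targets = take(design.n_decoy_pairs)
    background_genes = gene_ids[cursor:]

    n_intragenic = int(round(design.frac_intragenic_mirna * design.n_mirnas))
    mcursor = 0

    def mtake(n: int) -> list[str]:
        nonlocal mcursor
        out = mirna_ids[mcursor : mcursor + n]
        mcursor += n
        return out

    intragenic_mirnas = mtake(n_intragenic)
    violation_mirnas = mtake(5) if design.plant_host_violations else []
    repressor_mirnas = mtake(design.n_repressor_pairs)
    decoy_mirnas = mtake(design.n_decoy_pairs)
    background_mirnas = mirna_ids[mcursor:]

    # hosts for intragenic and violation miRNAs come from the background pool
    n_hosts = n_intragenic + len(violation_mirnas)
    host_genes = background_genes[:n_hosts]
    host_of = dict(zip(intragenic_mirnas + violation_mirnas, host_genes))

    # ----- planted expected-RPKM matrix -------------------------------
    rpkm = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    col_of_tissue = {t: panel[t] for t in tissues}

    # background genes: lognormal base x per-tissue jitter, with two
    # forced low tissues so no background gene is universally expressed
    bg = list(background_genes)
    base = np.minimum(rng.lognormal(np.log(5.0), 1.0, size=len(bg)), 40.0)
    # miRNA host genes (the first rows of the background block) get a
    # wider cross-tissue profile and one extra silent tissue so
    # host/miRNA co-expression is not drowned by counting noise
    jit_sigma = np.full(len(bg), 0.4)
    jit_sigma[:n_hosts] = 1.0
    jitter = rng.lognormal(0.0, jit_sigma[:, None], size=(len(bg), len(tissues)))
    prof = base[:, None] * jitter
    for k in range(len(bg)):
        n_dips = 3 if k < n_hosts else 2
        dip_idx = rng.choice(len(tissues), size=n_dips, replace=False)
        prof[k, dip_idx] *= 0.001  # effectively silenced in those tissues
    for ti, t in enumerate(tissues):
        rpkm.loc[bg, col_of_tissue[t]] = prof[:, ti]
    # muscle stages: jitter around the muscle tissue value
    mt = tissues.index("muscle")
    for col in stage_cols:
        if col == col_of_tissue["muscle"]:
            continue
        rpkm.loc[bg, col] = prof[:, mt] * rng.lognormal(0.0, 0.3, size=len(bg))

    # universal genes: high and flat in every sample
    if universal_genes:
        lvl = rng.uniform(80.0, 200.0, size=len(universal_genes))
        flat = lvl[:, None] * rng.lognormal(0.0, 0.05, size=(len(universal_genes), n_samples))
        rpkm.loc[universal_genes] = flat

    # tissue-specific genes: off-tissue baseline b, planted tissue 50 x b
    for t in tissues:
        ids = specific_genes[t]
        if not ids:
            continue
        b = rng.uniform(1.5, 3.0, size=len(ids))
        rpkm.loc[ids, :] = np.repeat(b[:, None], n_samples, axis=1)
        hit_cols = stage_cols if t == "muscle" else [col_of_tissue[t]]
        for col in hit_cols:
            rpkm.loc[ids, col] = design.specific_fold_planted * b

    # tissue-associated genes: one tissue elevated 5-fold (z ~ 2.4, well
    # above the 1.5 cutoff yet far below the 10-fold specificity rule)
    for t in tissues:
        ids = associated_genes[t]
        if not ids:
            continue
        b = rng.uniform(3.0, 6.0, size=len(ids))
        rpkm.loc[ids, :] = np.repeat(b[:, None], n_samples, axis=1) * rng.lognormal(
            0.0, 0.1, size=(len(ids), n_samples)
        )
        hit_cols = stage_cols if t == "muscle" else [col_of_tissue[t]]
        for col in hit_cols:
            rpkm.loc[ids, col] = 5.0 * b

    # ----- miRNA expected-TPM matrix ----------------------------------
    tpm = pd.DataFrame(0.0, index=mirna_ids, columns=samples)
    bgm = list(background_mirnas)
    mbase = rng.lognormal(np.log(50.0), 1.2, size=len(bgm))
    mjit = rng.lognormal(0.0, 0.6, size=(len(bgm), n_samples))
    tpm.loc[bgm] = mbase[:, None] * mjit

    # a handful of universal miRNAs: flat and high (CV well below 0.5)
    n_univ_mir = min(10, len(bgm))
    universal_mirnas = bgm[:n_univ_mir]
    if universal_mirnas:
        lvl = rng.uniform(800.0, 2000.0, size=n_univ_mir)
        tpm.loc[universal_mirnas] = lvl[:, None] * rng.lognormal(
            0.0, 0.05, size=(n_univ_mir, n_samples)
        )

    # intragenic miRNAs track their host's profile (scaled, small noise)
    for mid in intragenic_mirnas:
        host = host_of[mid]
        scale = rng.uniform(20.0, 60.0)
        tpm.loc[mid] = (
            rpkm.loc[host].to_numpy() * scale * rng.lognormal(0.0, 0.05, size=n_samples)
        )

    # violation miRNAs: antisense and multi-copy still track the host
    # (they fail on annotation, not expression); narrow-breadth is
    # silenced outside 3 tissues; low-correlation gets an independent
    # profile; partial-overlap tracks the host too
    violations: dict[str, tuple[str, str]] = {}
    if design.plant_host_violations:
        reasons = ["antisense", "multi_copy", "partial_overlap", "narrow_breadth", "low_correlation"]
        for mid, reason in zip(violation_mirnas, reasons):
            host = host_of[mid]
            violations[mid] = (reason, host)
            scale = rng.uniform(20.0, 60.0)
            prof_m = rpkm.loc[host].to_numpy() * scale * rng.lognormal(0.0, 0.1, size=n_samples)
            if reason == "narrow_breadth":
                prof_m = np.zeros(n_samples)
                keep = rng.choice(n_samples, size=3, replace=False)
                prof_m[keep] = rng.uniform(50.0, 200.0, size=3)
            elif reason == "low_correlation":
                # anti-image of the host profile: population r is negative,
                # so criterion 5 (r > 0.6) can never pass by chance
                h = rpkm.loc[host].to_numpy()
                prof_m = (h.max() + h.min() - h) * rng.uniform(20.0, 60.0)
            tpm.loc[mid] = prof_m

    # repressor / decoy miRNAs: the miRNA decreases across the muscle
    # stages and varies across tissues; the target is an exact affine
    # anti-image of the miRNA profile over EVERY sample, so the
    # population Pearson r is -1 on any column subset (stages included)
    # and only counting noise moves it off -1
    def plant_anticorrelated(mirs: list[str], targets: list[str]) -> None:
        for mid, gid in zip(mirs, targets):
            top = rng.uniform(400.0, 1000.0)
            prof_m = np.exp(rng.uniform(np.log(top / 16.0), np.log(top), size=n_samples))
            prof_m[[samples.index(c) for c in stage_cols]] = (top, top / 4.0, top / 16.0)
            tpm.loc[mid] = prof_m
            lo, hi = rng.uniform(5.0, 15.0), rng.uniform(120.0, 250.0)
            slope = (hi - lo) / (top - top / 16.0)
            rpkm.loc[gid] = hi - slope * (prof_m - top / 16.0)

    plant_anticorrelated(repressor_mirnas, repressor_targets)
    plant_anticorrelated(decoy_mirnas, decoy_targets)

    # ----- annotation --------------------------------------------------
    chroms = [f"chr{i}" for i in range(1, 10)]
    rows: list[tuple[str, str, int, int, str, str]] = []
    gene_span: dict[str, tuple[str, int, int, str]] = {}
    cur_pos = {c: 1000 for c in chroms}
    gap = 3000
    for gi, gid in enumerate(gene_ids):
        chrom = chroms[gi % len(chroms)]
        start = cur_pos[chrom]
        end = start + int(lengths[gi])
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((gid, chrom, start, end, strand, "gene"))
        gene_span[gid] = (chrom, start, end, strand)
        cur_pos[chrom] = end + gap

    def place_inside(host: str, same_strand: bool = True) -> tuple[str, int, int, str]:
        chrom, s, e, strand = gene_span[host]
        mlen = design.mirna_length
        start = int(rng.integers(s + 10, e - mlen - 10))
        mstrand = strand if same_strand else ("-" if strand == "+" else "+")
        return chrom, start, start + mlen, mstrand

    for mid in intragenic_mirnas:
        chrom, s, e, strand = place_inside(host_of[mid])
        rows.append((mid, chrom, s, e, strand, "miRNA"))

    for mid, (reason, host) in violations.items():
        if reason == "antisense":
            chrom, s, e, strand = place_inside(host, same_strand=False)
            rows.append((mid, chrom, s, e, strand, "miRNA"))
        elif reason == "partial_overlap":
            gchrom, gs, ge, gstrand = gene_span[host]
            s = gs - design.mirna_length // 2  # straddles the gene start
            rows.append((mid, gchrom, s, s + design.mirna_length, gstrand, "miRNA"))
        else:
            chrom, s, e, strand = place_inside(host)
            rows.append((mid, chrom, s, e, strand, "miRNA"))
            if reason == "multi_copy":
                other = chroms[(chroms.index(chrom) + 1) % len(chroms)]
                far = cur_pos[other] + 500_000  # well clear of later intergenic loci
                rows.append((mid, other, far, far + design.mirna_length, "+", "miRNA"))

    # intergenic single-copy loci for every remaining miRNA
    placed = set(intragenic_mirnas) | set(violations)
    for mid in mirna_ids:
        if mid in placed:
            continue
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = cur_pos[chrom] + int(rng.integers(500, 2000))
        rows.append((mid, chrom, start, start + design.mirna_length, "+", "miRNA"))
        cur_pos[chrom] = start + design.mirna_length + 500

    annotation = FeatureAnnotation(
        pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand", "feature_type"])
    )

    # ----- sequences ----------------------------------------------------
    seqs: dict[str, str] = {}
    for mid in mirna_ids:
        seqs[mid] = _random_rna(rng, design.mirna_length)

    utr: dict[str, str] = {
        gid: _random_rna(rng, design.utr_length) for gid in gene_ids
    }
    repressor_truth: set[tuple[str, str, int, str]] = set()
    for mid, gid in zip(repressor_mirnas, repressor_targets):
        site, site_type = _site_sequence(rng, seqs[mid])
        pos = int(rng.integers(10, design.utr_length - len(site) - 10))
        u = utr[gid]
        utr[gid] = u[:pos] + site + u[pos + len(site):]
        # the 7mer-m8 planting must not gain a chance 3' A (tier upgrade)
        if site_type == "7mer-m8" and utr[gid][pos + len(site)] == "A":
            utr[gid] = utr[gid][: pos + len(site)] + "C" + utr[gid][pos + len(site) + 1 :]
        # a 7mer-A1 must not gain a chance position-8 match 5' of the site
        # (that would re-anchor it as a seed 2-8 match one base upstream)
        comp_m8 = reverse_complement(seqs[mid][7])
        if site_type == "7mer-A1" and utr[gid][pos - 1] == comp_m8:
            repl = "A" if comp_m8 != "A" else "C"
            utr[gid] = utr[gid][: pos - 1] + repl + utr[gid][pos:]
        repressor_truth.add((mid, gid, pos, site_type))

    # decoys: scrub the UTR until the scanner finds nothing for the miRNA
    for mid, gid in zip(decoy_mirnas, decoy_targets):
        for _ in range(50):
            if not find_seed_sites(seqs[mid], utr[gid]):
                break
            utr[gid] = _random_rna(rng, design.utr_length)
        else:
            raise RuntimeError("could not scrub decoy UTR free of seed sites")

    # mature miRNAs under their IDs, 3'UTRs under their gene IDs
    sequences = SequenceSet.from_pairs(
        [(mid, seqs[mid]) for mid in mirna_ids]
        + [(gid, utr[gid]) for gid in gene_ids]
    )

    # ----- counts -------------------------------------------------------
    # rescale background genes so each column's sum of rpkm x length is
    # 1e9: expected column depth then equals library_depth and every
    # planted RPKM value is preserved in expectation
    wl = rpkm.mul(lengths, axis=0)
    planted_gene_set = set(gene_ids) - set(bg)
    planted_rows = rpkm.index.isin(planted_gene_set)
    planted_sum = wl.loc[planted_rows].sum(axis=0)
    bg_sum = wl.loc[~planted_rows].sum(axis=0)
    scale = (1e9 - planted_sum) / bg_sum
    if (scale <= 0).any():
        raise ValueError("design infeasible: planted expression exceeds the column budget")
    rpkm.loc[~planted_rows] = rpkm.loc[~planted_rows].mul(scale, axis=1)

    mean_counts = rpkm.mul(lengths, axis=0) * design.library_depth / 1e9
    mrna_counts = pd.DataFrame(
        nb_counts(rng, mean_counts.to_numpy(), design.nb_dispersion),
        index=gene_ids, columns=samples,
    )

    # same per-column budget trick for miRNA TPM (sum to 1e6)
    # planted miRNAs keep their TPM in expectation; the universal ones are
    # drawn from the background pool but are planted values too
    planted_mirna_set = (set(mirna_ids) - set(bgm)) | set(universal_mirnas)
    planted_mrows = tpm.index.isin(planted_mirna_set)
    p_sum = tpm.loc[planted_mrows].sum(axis=0)
    b_sum = tpm.loc[~planted_mrows].sum(axis=0)
    mscale = (1e6 - p_sum) / b_sum
    if (mscale <= 0).any():
        raise ValueError("design infeasible: planted miRNA expression exceeds the TPM budget")
    tpm.loc[~planted_mrows] = tpm.loc[~planted_mrows].mul(mscale, axis=1)

    mirna_mean = tpm * design.mirna_library_depth / 1e6
    mirna_counts = pd.DataFrame(
        nb_counts(rng, mirna_mean.to_numpy(), design.nb_dispersion),
        index=mirna_ids, columns=samples,
    )

    truth = TruthBundle(
        universal_ids=set(universal_genes),
        specific_ids={t: set(v) for t, v in specific_genes.items()},
        associated_ids={t: set(v) for t, v in associated_genes.items()},
        host_pairs={(mid, host_of[mid]) for mid in intragenic_mirnas},
        repressor_pairs=repressor_truth,
        decoy_pairs=set(zip(decoy_mirnas, decoy_targets)),
        host_violations={
            reason: {(mid, host)} for mid, (reason, host) in violations.items()
        } if violations else {},
        universal_mirna_ids=set(universal_mirnas),
    )
    # merge violation sets sharing a reason (future-proofing)
    merged: dict[str, set[tuple[str, str]]] = {}
    for mid, (reason, host) in violations.items():
        merged.setdefault(reason, set()).add((mid, host))
    truth.host_violations = merged

    return mrna_counts, mirna_counts, annotation, sequences, truth


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    mrna_counts: pd.DataFrame,
    mirna_counts: pd.DataFrame,
    annotation: FeatureAnnotation,
    sequences: SequenceSet,
    truth: TruthBundle,
    outdir: str | Path,
    gene_lengths: pd.Series | None = None,
) -> dict[str, Path]:
    """Write the atlas as GTF + FASTA x2 + TSV x2 (+ lengths TSV) + truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna_counts": out / "mrna_counts.tsv",
        "mirna_counts": out / "mirna_counts.tsv",
        "annotation": out / "annotation.gtf",
        "mirna_fasta": out / "mature_mirnas.fa",
        "utr_fasta": out / "utr3.fa",
        "truth": out / "truth.json",
    }
    write_count_matrix(mrna_counts, paths["mrna_counts"])
    write_count_matrix(mirna_counts, paths["mirna_counts"])
    write_annotation(annotation, paths["annotation"])
    mir_names = set(annotation.of_type("miRNA")["name"])
    gene_names = set(annotation.of_type("gene")["name"])
    mirs = {k: v for k, v in sequences.sequences.items() if k in mir_names}
    utrs = {k: v for k, v in sequences.sequences.items() if k in gene_names}
    write_fasta(mirs, paths["mirna_fasta"])
    write_fasta(utrs, paths["utr_fasta"])
    paths["truth"].write_text(truth.to_json())
    if gene_lengths is not None:
        paths["gene_lengths"] = out / "gene_lengths.tsv"
        gene_lengths.rename("length").to_csv(paths["gene_lengths"], sep="\t", index_label="feature_id")
    return paths


def read_fixture_bundle(outdir: str | Path):
    """Re-read a bundle written by :func:`write_fixture_bundle`."""
    out = Path(outdir)
    mrna = read_count_matrix(out / "mrna_counts.tsv")
    mirna = read_count_matrix(out / "mirna_counts.tsv")
    annotation = read_annotation(out / "annotation.gtf")
    seqs = read_fasta(out / "mature_mirnas.fa")
    utrs = read_fasta(out / "utr3.fa")
    merged = SequenceSet({**seqs.sequences, **utrs.sequences})
    truth = TruthBundle.from_json((out / "truth.json").read_text())
    return mrna, mirna, annotation, merged, truth


def gene_lengths_from_design(design: SimulationDesign) -> pd.Series:
    """The per-gene transcript lengths a design generates (same RNG stream)."""
    rng = np.random.default_rng(design.seed)
    lengths = rng.integers(
        design.gene_length_range[0], design.gene_length_range[1] + 1, size=design.n_genes
    ).astype(float)
    return pd.Series(lengths, index=[f"gene_{i:05d}" for i in range(design.n_genes)])
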