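"""End-to-end pipeline: quantify -> classify -> network -> host pairs -> DE -> interactions.

``run_pipeline`` chains every stage over one input bundle (count
matrices, gene lengths, GTF annotation, mature-miRNA and 3'UTR FASTA)
and writes one TSV per result table plus a JSON run summary recording
the package version, seed, cutoffs and per-stage feature counts.

Sample layout convention: the three muscle developmental stages appear
as columns named ``muscle_D0``, ``muscle_D30``, ``muscle_D240``; every
other column is one tissue.  The atlas tissue panel is the non-stage
columns plus the last stage (adult muscle); the developmental analyses
(DE, interaction persistence) use the three stage columns.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_atlas
from .config import PipelineConfig
from .de import call_de, de_test, overlap_patterns
from .hostpairs import find_host_pairs, host_pair_table
from .interactions import (
    assemble_interactions,
    interaction_table,
    screen_negative_correlation,
    site_table,
)
from .io import (
    FeatureAnnotation,
    SequenceSet,
    read_annotation,
    read_count_matrix,
    read_fasta,
    write_result_table,
)
from .network import build_correlation_graph, label_clusters, mcl_cluster
from .quantify import compute_rpkm, compute_tpm_per_million, flag_expressed

logger = logging.getLogger(__name__)

STAGE_COLS = ("muscle_D0", "muscle_D30", "muscle_D240")

__all__ = ["run_pipeline", "STAGE_COLS", "atlas_panel"]


def atlas_panel(columns: list[str], stage_cols: tuple[str, ...] = STAGE_COLS) -> list[str]:
    """Tissue-panel columns: every non-stage column plus the last stage."""
    panel = [c for c in columns if c not in stage_cols]
    if stage_cols[-1] in columns:
        # keep original column order, muscle in its sampled position
        panel = [c for c in columns if c not in stage_cols or c == stage_cols[-1]]
    return panel


def _classification_tables(result) -> dict[str, pd.DataFrame]:
    uni = pd.DataFrame({"feature_id": sorted(result.universal)})
    assoc = pd.DataFrame(
        [
            {"feature_id": fid, "tissue": tissue, "z": z}
            for tissue, series in sorted(result.associated.items())
            for fid, z in series.sort_index().items()
        ],
        columns=["feature_id", "tissue", "z"],
    )
    spec = pd.DataFrame(
        [
            {"feature_id": fid, "tissue": tissue, "fold": fold}
            for tissue, series in sorted(result.specific.items())
            for fid, fold in series.sort_index().items()
        ],
        columns=["feature_id", "tissue", "fold"],
    )
    return {"universal": uni, "associated": assoc, "specific": spec}


def run_pipeline(
    mrna_counts_path: str | Path,
    mirna_counts_path: str | Path,
    gene_lengths_path: str | Path,
    annotation_path: str | Path,
    mirna_fasta_path: str | Path,
    utr_fasta_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    network_max_nodes: int = 800,
    de_dispersion: float = 0.1,
) -> dict:
    """Execute all pipeline stages; returns the run-summary dict.

    Any stage failure aborts with the stage name prepended to the
    cause.  ``network_max_nodes`` caps the co-expression graph at the
    most-variable expressed genes so Markov clustering stays tractable;
    ``de_dispersion`` is the fixed NB dispersion used for the
    single-library stage comparisons.
    """
    config = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    # ----- load ---------------------------------------------------------
    with stage("load"):
        mrna_counts = read_count_matrix(mrna_counts_path)
        mirna_counts = read_count_matrix(mirna_counts_path)
        lengths = pd.read_csv(gene_lengths_path, sep="\t", index_col=0)["length"]
        annotation = read_annotation(annotation_path)
        mirna_seqs = read_fasta(mirna_fasta_path)
        utr_seqs = read_fasta(utr_fasta_path)
    summary["stages"]["load"] = {
        "genes": len(mrna_counts), "mirnas": len(mirna_counts),
        "annotation_records": len(annotation),
    }

    # ----- quantify -----------------------------------------------------
    with stage("quantify"):
        rpkm = compute_rpkm(mrna_counts, lengths)
        tpm = compute_tpm_per_million(mirna_counts)
        _, gene_expressed = flag_expressed(rpkm, config.expressed_threshold)
        _, mirna_expressed = flag_expressed(tpm, config.expressed_threshold)
        write_result_table(
            rpkm.values.reset_index().rename(columns={"index": "feature_id"}),
            out / "rpkm.tsv",
        )
        write_result_table(
            tpm.values.reset_index().rename(columns={"index": "feature_id"}),
            out / "tpm.tsv",
        )
    summary["stages"]["quantify"] = {
        "expressed_genes": int(gene_expressed.sum()),
        "expressed_mirnas": int(mirna_expressed.sum()),
    }

    panel = atlas_panel(list(mrna_counts.columns))
    rpkm_panel = rpkm.values[panel]
    tpm_panel = tpm.values[panel]

    # ----- classify -----------------------------------------------------
    with stage("classify"):
        gene_cls = classify_atlas(
            rpkm_panel.loc[gene_expressed],
            kind="mrna",
            universal_min=config.universal_mrna_min,
            z_min=config.associated_z_min,
            associated_expr_min=config.associated_expr_min,
            fold=config.specific_fold,
            specific_expr_min=config.specific_expr_min,
        )
        mirna_cls = classify_atlas(
            tpm_panel.loc[mirna_expressed],
            kind="mirna",
            universal_min=config.universal_mirna_min,
            universal_cv_max=config.universal_mirna_cv_max,
            z_min=config.associated_z_min,
            associated_expr_min=config.associated_expr_min,
            fold=config.specific_fold,
            specific_expr_min=config.specific_expr_min,
        )
        for kind, cls in (("mrna", gene_cls), ("mirna", mirna_cls)):
            for name, table in _classification_tables(cls).items():
                write_result_table(table, out / f"{kind}_{name}.tsv")
    summary["stages"]["classify"] = {
        "universal_mrna": len(gene_cls.universal),
        "universal_mirna": len(mirna_cls.universal),
        "specific_mrna": len(gene_cls.all_specific_ids()),
        "specific_mirna": len(mirna_cls.all_specific_ids()),
    }

    # ----- network ------------------------------------------------------
    with stage("network"):
        expressed_rpkm = rpkm_panel.loc[gene_expressed]
        if len(expressed_rpkm) > network_max_nodes:
            variability = expressed_rpkm.std(axis=1) / (expressed_rpkm.mean(axis=1) + 1e-9)
            keep = variability.nlargest(network_max_nodes).index
            expressed_rpkm = expressed_rpkm.loc[sorted(keep)]
        graph = build_correlation_graph(expressed_rpkm, config.network_r_min)
        clusters = mcl_cluster(graph, inflation=config.mcl_inflation)
        clusters = label_clusters(clusters, expressed_rpkm)
        write_result_table(graph.edge_table(), out / "network_edges.tsv", correlation_cols=("r",))
        member_rows = [
            {"feature_id": f, "cluster": i, "label": clusters.labels.get(i, "")}
            for i, members in enumerate(clusters.clusters)
            for f in sorted(members)
        ]
        write_result_table(
            pd.DataFrame(member_rows, columns=["feature_id", "cluster", "label"]),
            out / "network_clusters.tsv",
        )
    summary["stages"]["network"] = {
        "nodes": graph.graph.number_of_nodes(),
        "edges": graph.graph.number_of_edges(),
        "clusters": len(clusters.clusters),
        "singletons": len(clusters.singletons),
        "mcl_converged": clusters.converged,
    }

    # ----- host pairs ---------------------------------------------------
    with stage("hostpairs"):
        # breadth and correlation run over all 11 libraries (9 tissues
        # with muscle sampled at three stages)
        passed, candidates = find_host_pairs(
            annotation, annotation, tpm.values, rpkm.values,
            min_tissues=config.host_min_tissues,
            breadth_threshold=config.expressed_threshold,
            r_min=config.host_r_min,
            p_max=config.host_p_max,
        )
        write_result_table(
            host_pair_table(candidates), out / "host_pairs.tsv", correlation_cols=("r",)
        )
    summary["stages"]["hostpairs"] = {
        "candidates": len(candidates), "passed": len(passed),
    }

    # ----- differential expression over muscle stages -------------------
    stage_cols = [c for c in STAGE_COLS if c in mrna_counts.columns]
    de_summary = {}
    patterns = None
    if len(stage_cols) == 3:
        with stage("de"):
            calls = {}
            for label, (a, b) in {
                "D0_vs_D30": (stage_cols[0], stage_cols[1]),
                "D30_vs_D240": (stage_cols[1], stage_cols[2]),
            }.items():
                table = de_test(
                    mrna_counts[[a]], mrna_counts[[b]], dispersion=de_dispersion
                )
                table["call"] = call_de(table, config.de_lfc_min, config.de_fdr_max)
                write_result_table(
                    table.reset_index().rename(columns={"index": "feature_id"}),
                    out / f"de_{label}.tsv",
                )
                calls[label] = table["call"]
                de_summary[label] = {
                    "up": int((table["call"] == "up").sum()),
                    "down": int((table["call"] == "down").sum()),
                }
            patterns = overlap_patterns(calls["D0_vs_D30"], calls["D30_vs_D240"])
            pattern_rows = [
                {"feature_id": f, "pattern": name}
                for name, members in patterns.sizes().items()
                for f in sorted(getattr(patterns, name))
            ]
            write_result_table(
                pd.DataFrame(pattern_rows, columns=["feature_id", "pattern"]),
                out / "de_patterns.tsv",
            )
            de_summary["patterns"] = patterns.sizes()
    summary["stages"]["de"] = de_summary

    # ----- interaction screen -------------------------------------------
    with stage("interact"):
        # screen across the full library panel; persistence is judged on
        # the three developmental-stage columns separately
        screened = screen_negative_correlation(
            tpm.values, rpkm.values, config.interact_r_max, sample_set=None
        )
        records = assemble_interactions(
            screened, mirna_seqs, utr_seqs,
            mirna_stage_expr=tpm.values[stage_cols] if stage_cols else None,
            mrna_stage_expr=rpkm.values[stage_cols] if stage_cols else None,
            r_max=config.interact_r_max,
            mfe_filter=config.mfe_filter,
            mfe_max=config.mfe_max,
        )
        final = [r for r in records if r.passed_screen and r.passed_sites]
        persistent = [r for r in final if r.passed_persistence]
        write_result_table(
            interaction_table(records), out / "interactions.tsv",
            correlation_cols=("r", "r_stages"),
        )
        write_result_table(site_table(final), out / "interaction_sites.tsv")
    summary["stages"]["interact"] = {
        "screened": len(screened),
        "with_sites": len(final),
        "persistent": len(persistent),
    }

    summary["completed_stages"] = [
        "load", "quantify", "classify", "network", "hostpairs", "de", "interact"
    ]
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
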