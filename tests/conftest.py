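import numpy as np
import pandas as pd
import pytest

from tissueatlas.simulate import (
    SimulationDesign,
    gene_lengths_from_design,
    simulate_atlas,
)

TISSUE_9 = ["fat", "heart", "kidney", "liver", "lung", "muscle", "ovary", "spleen", "testis"]


@pytest.fixture(scope="session")
def default_atlas():
    """One full-size synthetic atlas (default design, seed 0)."""
    design = SimulationDesign(seed=0)
    mrna, mirna, annotation, sequences, truth = simulate_atlas(design)
    return {
        "design": design,
        "mrna": mrna,
        "mirna": mirna,
        "annotation": annotation,
        "sequences": sequences,
        "truth": truth,
        "lengths": gene_lengths_from_design(design),
    }


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down design for fast pipeline-level tests."""
    return SimulationDesign(
        seed=11, n_genes=800, n_mirnas=80, n_specific_per_tissue=5,
        n_associated_per_tissue=3, n_repressor_pairs=5, n_decoy_pairs=5,
    )


@pytest.fixture(scope="session")
def small_atlas(small_design):
    mrna, mirna, annotation, sequences, truth = simulate_atlas(small_design)
    return {
        "design": small_design,
        "mrna": mrna,
        "mirna": mirna,
        "annotation": annotation,
        "sequences": sequences,
        "truth": truth,
        "lengths": gene_lengths_from_design(small_design),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


HOST_SAMPLES = [f"t{i}" for i in range(11)]


def build_host_fixture():
    """Constructed annotation + expression with one true intragenic pair
    and one violation of each kind (antisense, partial overlap,
    multi-copy, narrow breadth)."""
    from tissueatlas.io import FeatureAnnotation

    genes = [
        ("HOST1", "chr1", 100, 5000, "+", "gene"),
        ("HOST2", "chr1", 10000, 15000, "+", "gene"),
        ("HOST3", "chr2", 100, 5000, "-", "gene"),
        ("HOST4", "chr2", 10000, 15000, "+", "gene"),
        ("HOST5", "chr3", 100, 5000, "+", "gene"),
    ]
    mirnas = [
        ("mir_ok", "chr1", 150, 172, "+", "miRNA"),
        ("mir_anti", "chr1", 10100, 10122, "-", "miRNA"),
        ("mir_partial", "chr2", 90, 112, "-", "miRNA"),
        ("mir_multi", "chr2", 10100, 10122, "+", "miRNA"),
        ("mir_multi", "chr5", 999, 1021, "+", "miRNA"),
        ("mir_narrow", "chr3", 150, 172, "+", "miRNA"),
    ]
    ann = FeatureAnnotation(
        pd.DataFrame(genes + mirnas,
                     columns=["name", "chrom", "start", "end", "strand", "feature_type"])
    )
    base = np.array([5, 9, 2, 14, 7, 11, 3, 8, 13, 6, 10], dtype=float)
    rpkm = pd.DataFrame(
        {h: base * (k + 1) for k, h in enumerate(["HOST1", "HOST2", "HOST3", "HOST4", "HOST5"])},
        index=HOST_SAMPLES,
    ).T
    tpm = pd.DataFrame(
        {
            "mir_ok": base * 30,
            "mir_anti": base * 20,
            "mir_partial": base * 20,
            "mir_multi": base * 20,
            "mir_narrow": [0, 0, 0, 50, 0, 80, 0, 0, 20, 0, 0],
        },
        index=HOST_SAMPLES,
    ).T
    return ann, tpm, rpkm


def profile_frame(rows: dict[str, list[float]], columns: list[str] | None = None) -> pd.DataFrame:
    cols = columns or TISSUE_9[: len(next(iter(rows.values())))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols, dtype=float)
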