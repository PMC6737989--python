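"""Generate the synthetic multi-tissue atlas analysed by the later steps.

Nine tissues with skeletal muscle sampled at postnatal stages D0 / D30 /
D240, 5,000 genes and 300 miRNAs with negative-binomial counts, and
planted truth: 30 universal genes, 20 tissue-specific genes per tissue
at 50-fold, intragenic host/miRNA pairs (plus labelled violations), and
10 repressor + 10 decoy miRNA-target pairs.

Writes the fixture bundle (counts, GTF, FASTA, truth JSON) to
results/atlas/.
"""

from pathlib import Path

from tissueatlas.simulate import (
    SimulationDesign,
    gene_lengths_from_design,
    simulate_atlas,
    write_fixture_bundle,
)

OUTDIR = Path("results/atlas")
SEED = 0


def main() -> None:
    design = SimulationDesign(seed=SEED)
    mrna, mirna, annotation, sequences, truth = simulate_atlas(design)
    paths = write_fixture_bundle(
        mrna, mirna, annotation, sequences, truth, OUTDIR,
        gene_lengths=gene_lengths_from_design(design),
    )
    print(f"atlas: {mrna.shape[0]} genes x {mrna.shape[1]} samples, "
          f"{mirna.shape[0]} miRNAs, {len(annotation)} annotation records")
    print(f"planted: {len(truth.universal_ids)} universal genes, "
          f"{sum(len(s) for s in truth.specific_ids.values())} specific genes, "
          f"{len(truth.host_pairs)} host pairs, "
          f"{len(truth.repressor_pairs)} repressor and {len(truth.decoy_pairs)} decoy pairs")
    for name, path in sorted(paths.items()):
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
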