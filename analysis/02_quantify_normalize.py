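"""Normalize the atlas counts and measure tissue similarity.

mRNA counts become RPKM, miRNA counts reads-per-million TPM; features
above 0.1 in at least one library are flagged expressed, and sample
relatedness is summarized as Pearson correlation of log2(RPKM + 1).

Writes results/rpkm.tsv, results/tpm.tsv, results/sample_correlation.tsv.
"""

from pathlib import Path

import pandas as pd

from tissueatlas.io import read_count_matrix, write_result_table
from tissueatlas.quantify import (
    compute_rpkm,
    compute_tpm_per_million,
    flag_expressed,
    tissue_similarity,
)

ATLAS = Path("results/atlas")
RESULTS = Path("results")


def main() -> None:
    mrna = read_count_matrix(ATLAS / "mrna_counts.tsv")
    mirna = read_count_matrix(ATLAS / "mirna_counts.tsv")
    lengths = pd.read_csv(ATLAS / "gene_lengths.tsv", sep="\t", index_col=0)["length"]

    rpkm = compute_rpkm(mrna, lengths)
    tpm = compute_tpm_per_million(mirna)
    _, genes_expressed = flag_expressed(rpkm, 0.1)
    _, mirnas_expressed = flag_expressed(tpm, 0.1)
    corr, _ = tissue_similarity(rpkm)

    write_result_table(rpkm.values.reset_index(names="feature_id"), RESULTS / "rpkm.tsv")
    write_result_table(tpm.values.reset_index(names="feature_id"), RESULTS / "tpm.tsv")
    write_result_table(
        corr.reset_index(names="sample"), RESULTS / "sample_correlation.tsv",
        correlation_cols=tuple(corr.columns),
    )

    print(f"expressed: {int(genes_expressed.sum())}/{len(mrna)} genes, "
          f"{int(mirnas_expressed.sum())}/{len(mirna)} miRNAs (abundance > 0.1 anywhere)")
    stage_r = corr.loc["muscle_D30", "muscle_D240"]
    cross_r = corr.loc["testis", "muscle_D240"]
    print(f"sample similarity: muscle_D30 vs muscle_D240 r = {stage_r:.3f}; "
          f"testis vs muscle_D240 r = {cross_r:.3f}")


if __name__ == "__main__":
    main()
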