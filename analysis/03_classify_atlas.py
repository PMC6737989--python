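"""Classify genes and miRNAs as universal / tissue-associated / tissue-specific.

Rules: universal mRNA RPKM > 10 in every tissue; universal miRNA TPM > 1
everywhere with CV < 0.5; associated z >= 1.5 with abundance >= 1;
specific abundance >= 10 and > 10x the mean of the other tissues.  The
panel is the nine tissues with muscle represented by its D240 library.

Writes one TSV per category and reports recovery of the planted truth.
"""

import json
from pathlib import Path

import pandas as pd

from tissueatlas.classify import classify_atlas
from tissueatlas.io import read_count_matrix, write_result_table
from tissueatlas.pipeline import atlas_panel
from tissueatlas.quantify import compute_rpkm, compute_tpm_per_million
from tissueatlas.simulate import TruthBundle

ATLAS = Path("results/atlas")
RESULTS = Path("results")


def main() -> None:
    mrna = read_count_matrix(ATLAS / "mrna_counts.tsv")
    mirna = read_count_matrix(ATLAS / "mirna_counts.tsv")
    lengths = pd.read_csv(ATLAS / "gene_lengths.tsv", sep="\t", index_col=0)["length"]
    truth = TruthBundle.from_json((ATLAS / "truth.json").read_text())

    panel = atlas_panel(list(mrna.columns))
    rpkm = compute_rpkm(mrna, lengths).values[panel]
    tpm = compute_tpm_per_million(mirna).values[panel]

    gene_cls = classify_atlas(rpkm, kind="mrna")
    mirna_cls = classify_atlas(tpm, kind="mirna", universal_min=1.0)

    for kind, cls in (("mrna", gene_cls), ("mirna", mirna_cls)):
        write_result_table(pd.DataFrame({"feature_id": sorted(cls.universal)}),
                           RESULTS / f"{kind}_universal.tsv")
        for label, mapping, stat in (("associated", cls.associated, "z"),
                                     ("specific", cls.specific, "fold")):
            rows = [{"feature_id": f, "tissue": t, stat: v}
                    for t, s in sorted(mapping.items()) for f, v in s.sort_index().items()]
            write_result_table(pd.DataFrame(rows, columns=["feature_id", "tissue", stat]),
                               RESULTS / f"{kind}_{label}.tsv")

    n_spec = sum(len(s) for s in gene_cls.specific.values())
    print(f"mRNA: {len(gene_cls.universal)} universal, "
          f"{sum(len(s) for s in gene_cls.associated.values())} associated calls, "
          f"{n_spec} tissue-specific calls")
    print(f"miRNA: {len(mirna_cls.universal)} universal, "
          f"{sum(len(s) for s in mirna_cls.specific.values())} tissue-specific calls")

    planted_univ = truth.universal_ids
    recovered = gene_cls.universal & planted_univ
    tp = fp = 0
    for col, series in gene_cls.specific.items():
        tissue = "muscle" if col == "muscle_D240" else col
        got = set(series.index)
        tp += len(got & truth.specific_ids[tissue])
        fp += len(got - truth.specific_ids[tissue])
    planted_total = sum(len(s) for s in truth.specific_ids.values())
    summary = {
        "universal_planted_recovered": f"{len(recovered)}/{len(planted_univ)}",
        "specific_sensitivity": round(tp / planted_total, 4),
        "specific_precision": round(tp / (tp + fp), 4) if tp + fp else None,
    }
    (RESULTS / "classification_recovery.json").write_text(json.dumps(summary, indent=1))
    print("planted-truth recovery:", summary)


if __name__ == "__main__":
    main()
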