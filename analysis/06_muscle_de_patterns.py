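"""Differential expression across muscle development and its dynamic patterns.

Compares D0 vs D30 and D30 vs D240 with the NB Wald test (single
libraries per stage, fixed dispersion 0.1), calls features at
log2FC >= 1 and FDR < 0.05, and partitions the calls into the
up/down dynamic pattern classes across the two comparisons.

Writes results/de_D0_vs_D30.tsv, results/de_D30_vs_D240.tsv,
results/de_patterns.tsv.
"""

from pathlib import Path

from tissueatlas.de import call_de, de_test, overlap_patterns
from tissueatlas.io import read_count_matrix, write_result_table
from tissueatlas.pipeline import STAGE_COLS

import pandas as pd

ATLAS = Path("results/atlas")
RESULTS = Path("results")
DISPERSION = 0.1


def main() -> None:
    mrna = read_count_matrix(ATLAS / "mrna_counts.tsv")
    d0, d30, d240 = STAGE_COLS

    calls = {}
    for label, (a, b) in {"D0_vs_D30": (d0, d30), "D30_vs_D240": (d30, d240)}.items():
        table = de_test(mrna[[a]], mrna[[b]], dispersion=DISPERSION)
        table["call"] = call_de(table, 1.0, 0.05)
        write_result_table(table.reset_index(names="feature_id"),
                           RESULTS / f"de_{label}.tsv")
        calls[label] = table["call"]
        up, down = (table["call"] == "up").sum(), (table["call"] == "down").sum()
        print(f"{label}: {up} up, {down} down (of {len(table)} genes)")

    patterns = overlap_patterns(calls["D0_vs_D30"], calls["D30_vs_D240"])
    rows = [{"feature_id": f, "pattern": name}
            for name in patterns.sizes() for f in sorted(getattr(patterns, name))]
    write_result_table(pd.DataFrame(rows, columns=["feature_id", "pattern"]),
                       RESULTS / "de_patterns.tsv")
    print("dynamic patterns:", patterns.sizes())
    print(f"monotone throughout D0->D240: {len(patterns.monotone_through())} genes")


if __name__ == "__main__":
    main()
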