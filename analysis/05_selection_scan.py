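#!/usr/bin/env python
"""Per-gene F_ST between wild and selection populations, top-1% scan and
presence-frequency divergence.

Each gene's presence state is a haploid biallelic marker; differentiation
is measured by the Weir-Cockerham variance-component estimator, genes at
or above the empirical top-1% quantile are flagged, and the direction of
the frequency shift is tabulated for the flagged genes.
"""

from __future__ import annotations

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from pavpan import PAVMatrix, SampleSheet, frequency_divergence, fst_global, fst_per_gene, top_fraction


def main() -> None:
    ensure_dirs()
    matrix = PAVMatrix.from_tsv(SCRATCH / "pav_matrix.tsv")
    sheet = SampleSheet.from_tsv(SCRATCH / "cohort" / "samples.tsv")
    truth = pd.read_csv(SCRATCH / "cohort" / "truth_genes.tsv", sep="\t")

    records = fst_per_gene(matrix, sheet, estimator="weir_cockerham")
    threshold, records = top_fraction(records, fraction=0.01)
    records.to_csv(SCRATCH / "fst.tsv", sep="\t", index=False)
    theta, se = fst_global(matrix, sheet)

    divergence = frequency_divergence(matrix, sheet)
    top = records[records["top_flag"]].merge(divergence, on="gene_id")
    top = top.merge(truth[["gene_id", "selected_flag"]], on="gene_id")
    top.sort_values("fst", ascending=False).to_csv(
        RESULTS / "05_top_fst_genes.tsv", sep="\t", index=False
    )

    summary = pd.DataFrame(
        {
            "quantity": [
                "genome_wide_fst",
                "genome_wide_fst_se",
                "top1pct_threshold",
                "n_top_genes",
                "n_top_increased_in_selection",
                "n_top_decreased_in_selection",
                "n_top_truly_selection_shifted",
            ],
            "value": [
                round(theta, 4),
                round(se, 4),
                round(threshold, 4),
                len(top),
                int((top["direction"] == 1).sum()),
                int((top["direction"] == -1).sum()),
                int(top["selected_flag"].sum()),
            ],
        }
    )
    summary.to_csv(RESULTS / "05_fst_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nstrongest differentiated genes:")
    cols = ["gene_id", "p_wild", "p_selection", "fst", "selected_flag"]
    print(top.sort_values("fst", ascending=False).head(8)[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
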