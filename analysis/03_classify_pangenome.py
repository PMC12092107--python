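#!/usr/bin/env python
"""Partition the pan-genome into core/softcore/shell/cloud and draw the
saturation curves.

Classifies every gene of the called matrix by occupancy (core = all 268,
softcore >97%, shell 1-97%, cloud <1%), tabulates the genome-window
distribution of the classes, and computes core/pan rarefaction over 100
random accession orderings.
"""

from __future__ import annotations

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from pavpan import PAVMatrix, chromosome_density, classify_matrix, saturation


def main() -> None:
    ensure_dirs()
    matrix = PAVMatrix.from_tsv(SCRATCH / "pav_matrix.tsv")
    table, counts = classify_matrix(matrix)
    table.to_csv(SCRATCH / "classification.tsv", sep="\t", index=False)
    counts.to_csv(RESULTS / "03_class_counts.tsv", sep="\t")
    frac = counts / counts.sum()
    print("pan-genome composition:")
    for label, n in counts.items():
        print(f"  {label:18s} {n:5d}  ({frac[label]:.2%})")

    density = chromosome_density(table, matrix.gene_meta, window=2000)
    density.to_csv(RESULTS / "03_class_density.tsv", sep="\t", index=False)

    curve = saturation(matrix, n_permutations=100, seed=1)
    df = curve.to_frame()
    df.to_csv(RESULTS / "03_saturation.tsv", sep="\t", index=False)
    checkpoints = df[df["n"].isin([1, 10, 50, 100, 200, 268])]
    print("\nsaturation (mean over 100 orderings):")
    print(checkpoints.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
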