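#!/usr/bin/env python
"""Genetic structure from gene content: PCA, p-distances and the NJ tree.

Runs PCA on the standardized presence matrix, computes pairwise
p-distances, builds the neighbour-joining tree, and quantifies how well
PC1 separates the wild and selection populations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from pavpan import PAVMatrix, SampleSheet, nj_tree, pav_distance, pav_pca, write_newick


def main() -> None:
    ensure_dirs()
    matrix = PAVMatrix.from_tsv(SCRATCH / "pav_matrix.tsv")
    sheet = SampleSheet.from_tsv(SCRATCH / "cohort" / "samples.tsv")
    pops = sheet.population_of(matrix.sample_ids)

    pca = pav_pca(matrix, k=10)
    coords = pca.to_frame()
    coords["population"] = pops
    coords.to_csv(SCRATCH / "pca_coordinates.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"component": np.arange(1, 11), "explained": pca.explained.round(4)}
    ).to_csv(RESULTS / "04_pca_explained.tsv", sep="\t", index=False)

    wild = pops == "wild"
    side = pca.coordinates[:, 0] > 0
    sep = max((side == wild).mean(), (side == ~wild).mean())

    dist = pav_distance(matrix)
    dist.to_phylip(SCRATCH / "distance.phy")
    within_wild = dist.values[np.ix_(wild, wild)][np.triu_indices(wild.sum(), 1)]
    within_sel = dist.values[np.ix_(~wild, ~wild)][np.triu_indices((~wild).sum(), 1)]
    between = dist.values[np.ix_(wild, ~wild)].ravel()

    tree = nj_tree(dist)
    write_newick(tree, SCRATCH / "nj_tree.nwk")

    summary = pd.DataFrame(
        {
            "quantity": [
                "pc1_explained",
                "pc1_population_separation",
                "mean_distance_within_wild",
                "mean_distance_within_selection",
                "mean_distance_between",
                "nj_negative_branches_clamped",
            ],
            "value": [
                round(float(pca.explained[0]), 4),
                round(float(sep), 4),
                round(float(within_wild.mean()), 4),
                round(float(within_sel.mean()), 4),
                round(float(between.mean()), 4),
                tree.negative_branch_clamped,
            ],
        }
    )
    summary.to_csv(RESULTS / "04_structure_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
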