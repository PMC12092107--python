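"""Occupancy-based pan-genome classification and saturation curves.

Genes are binned by the fraction f of accessions carrying them:

* **core**      f = 1 (present in every accession)
* **softcore**  0.97 < f < 1
* **shell**     0.01 <= f <= 0.97
* **cloud**     0 < f < 0.01

Core takes precedence over the softcore band (otherwise a gene present in
all accessions would satisfy both); the shell bounds are inclusive so that,
in a 268-accession cohort, occupancy 259 (96.64%) and 3 (1.12%) are shell
while 260 (97.01%) is softcore and 2 (0.75%) is cloud. A gene observed in
no accession is labelled ``absent_everywhere`` and excluded from the
four-way partition.

Saturation curves are prefix-of-permutation rarefaction: for each random
ordering of accessions and each prefix size n, core(n) counts genes present
in all n prefix accessions and pan(n) genes present in at least one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, PRESENT, PAVMatrix, PavError

logger = logging.getLogger(__name__)

LABELS = ("core", "softcore", "shell", "cloud")
ABSENT_EVERYWHERE = "absent_everywhere"

SOFTCORE_MIN_FRACTION = 0.97
SHELL_MIN_FRACTION = 0.01


def classify_gene(occupancy: int, n_total: int) -> str:
    """Label one gene from its accession occupancy count."""
    if n_total < 1:
        raise PavError("n_total must be >= 1")
    if not (0 <= occupancy <= n_total):
        raise PavError(f"occupancy {occupancy} outside [0, {n_total}]")
    if occupancy == 0:
        return ABSENT_EVERYWHERE
    f = occupancy / n_total
    if occupancy == n_total:
        return "core"
    if f > SOFTCORE_MIN_FRACTION:
        return "softcore"
    if f >= SHELL_MIN_FRACTION:
        return "shell"
    return "cloud"


def classify_matrix(
    matrix: PAVMatrix, missing_policy: str = "as_absent"
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every gene of a PAV matrix.

    missing_policy:
      * ``as_absent`` — missing cells count as absent; denominator is the
        full sample count;
      * ``drop_from_denominator`` — per-gene denominator is the number of
        non-missing calls.

    Returns (per-gene table, label count summary).
    """
    if matrix.n_genes == 0:
        raise PavError("empty matrix")
    if missing_policy not in ("as_absent", "drop_from_denominator"):
        raise PavError(f"unknown missing_policy {missing_policy!r}")
    present = (matrix.calls == PRESENT).sum(axis=1)
    if missing_policy == "as_absent":
        denom = np.full(matrix.n_genes, matrix.n_samples)
    else:
        denom = (matrix.calls != MISSING).sum(axis=1)
        denom = np.maximum(denom, 1)
    labels = [classify_gene(int(o), int(n)) for o, n in zip(present, denom)]
    n_absent = labels.count(ABSENT_EVERYWHERE)
    if n_absent:
        logger.info("classify_matrix: %d genes observed in no accession", n_absent)
    table = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "occupancy": present,
            "n_classifiable": denom,
            "frequency": present / denom,
            "label": labels,
        }
    )
    counts = table["label"].value_counts().reindex(list(LABELS) + [ABSENT_EVERYWHERE], fill_value=0)
    counts.name = "n_genes"
    return table, counts


@dataclass
class SaturationCurve:
    """Mean core/pan gene counts over random accession orderings."""

    n: np.ndarray  # subset sizes 1..N
    core_mean: np.ndarray
    pan_mean: np.ndarray
    core_ci: np.ndarray  # (N, 2) percentile bounds
    pan_ci: np.ndarray
    n_permutations: int
    seed: int

    @property
    def variable_mean(self) -> np.ndarray:
        return self.pan_mean - self.core_mean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n,
                "core_mean": self.core_mean,
                "core_lo": self.core_ci[:, 0],
                "core_hi": self.core_ci[:, 1],
                "pan_mean": self.pan_mean,
                "pan_lo": self.pan_ci[:, 0],
                "pan_hi": self.pan_ci[:, 1],
                "variable_mean": self.variable_mean,
            }
        )


def saturation(
    matrix: PAVMatrix,
    n_permutations: int = 100,
    seed: int = 1,
    ci: tuple[float, float] = (2.5, 97.5),
    exhaustive: bool = False,
) -> SaturationCurve:
    """Prefix-of-permutation core/pan rarefaction (missing treated as absent).

    With ``exhaustive=True`` every ordering of the accessions is enumerated
    (only sensible for <= 8 samples); the means are then the exact subset
    expectations and ``n_permutations``/``seed`` are ignored.
    """
    if n_permutations < 1:
        raise PavError("n_permutations must be >= 1")
    present = matrix.calls == PRESENT  # genes x samples, bool
    N = matrix.n_samples
    if exhaustive:
        if N > 8:
            raise PavError("exhaustive enumeration is limited to 8 samples")
        from itertools import permutations as _perms

        perms = [np.array(p) for p in _perms(range(N))]
        n_permutations = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(N) for _ in range(n_permutations)]
    core = np.empty((n_permutations, N), dtype=np.int64)
    pan = np.empty((n_permutations, N), dtype=np.int64)
    for p, perm in enumerate(perms):
        sub = present[:, perm]
        core[p] = np.logical_and.accumulate(sub, axis=1).sum(axis=0)
        pan[p] = np.logical_or.accumulate(sub, axis=1).sum(axis=0)
    lo, hi = ci
    return SaturationCurve(
        n=np.arange(1, N + 1),
        core_mean=core.mean(axis=0),
        pan_mean=pan.mean(axis=0),
        core_ci=np.stack(np.percentile(core, [lo, hi], axis=0), axis=1),
        pan_ci=np.stack(np.percentile(pan, [lo, hi], axis=0), axis=1),
        n_permutations=n_permutations,
        seed=seed,
    )


def chromosome_density(
    classes: pd.DataFrame, gene_meta: pd.DataFrame, window: int = 1_000_000
) -> pd.DataFrame:
    """Label counts per genomic window (plotting-ready table).

    ``classes`` is the per-gene table from :func:`classify_matrix`; genes on
    unplaced sequence are pooled into a single ``novel`` bin.
    """
    if window < 1:
        raise PavError("window must be >= 1")
    meta = gene_meta.loc[classes["gene_id"]]
    novel = (meta["source"] == "novel").to_numpy()
    chrom = np.where(novel, "novel", meta["chrom"].to_numpy())
    win = np.where(novel, 0, (meta["start"].to_numpy().astype(np.int64) - 1) // window)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "window": win,
            "window_start": win * window + 1,
            "label": classes["label"].to_numpy(),
        }
    )
    out = (
        df.groupby(["chrom", "window", "window_start", "label"], observed=True)
        .size()
        .rename("n_genes")
        .reset_index()
        .sort_values(["chrom", "window", "label"])
        .reset_index(drop=True)
    )
    return out
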