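"""Core in-memory containers shared across the pipeline.

The central object is :class:`PAVMatrix`, a genes-by-samples table of
presence/absence/missing calls plus per-gene location metadata. Calls are
stored as a compact ``int8`` array (1 = present, 0 = absent, -1 = missing);
gene metadata lives in a pandas DataFrame indexed by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PRESENT: int = 1
ABSENT: int = 0
MISSING: int = -1

#: metadata columns every PAVMatrix carries per gene
GENE_META_COLUMNS = ("chrom", "start", "end", "source")


class PavError(ValueError):
    """Domain error raised for contract violations in the PAV pipeline."""


@dataclass
class PAVMatrix:
    """Genes x samples presence/absence/missing call matrix.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    sample_ids
        Ordered, unique sample identifiers (columns).
    calls
        ``int8`` array of shape (n_genes, n_samples) with values in
        {1 (present), 0 (absent), -1 (missing)}.
    gene_meta
        DataFrame indexed by gene id with columns ``chrom`` (str),
        ``start``/``end`` (1-based inclusive gene span, int) and ``source``
        (``"reference"`` for placed genes, ``"novel"`` for genes on
        unplaced sequence).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise PavError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise PavError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PavError("duplicate sample ids")
        bad = ~np.isin(self.calls, (PRESENT, ABSENT, MISSING))
        if bad.any():
            raise PavError("calls must be in {1, 0, -1}")
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(
                {
                    "chrom": pd.Series(["novel"] * len(self.gene_ids), dtype=object),
                    "start": 0,
                    "end": 0,
                    "source": "novel",
                },
                index=pd.Index(self.gene_ids, name="gene_id"),
            )
        else:
            self.gene_meta = self.gene_meta.loc[self.gene_ids]

    # -- basic views ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def presence(self) -> np.ndarray:
        """Float matrix with 1.0 present, 0.0 absent, NaN missing."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def is_missing(self) -> np.ndarray:
        return self.calls == MISSING

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame (genes x samples, int8)."""
        return pd.DataFrame(
            self.calls, index=pd.Index(self.gene_ids, name="gene_id"), columns=self.sample_ids
        )

    # -- subsetting -----------------------------------------------------

    def subset_genes(self, keep: np.ndarray | list) -> "PAVMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return PAVMatrix(
            [self.gene_ids[i] for i in idx],
            self.sample_ids,
            self.calls[idx],
            self.gene_meta.iloc[idx],
        )

    def subset_samples(self, keep: list[str]) -> "PAVMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in keep], dtype=int)
        return PAVMatrix(self.gene_ids, list(keep), self.calls[:, idx], self.gene_meta)

    # -- I/O helpers (TSV; VCF/HapMap live in io_formats) ---------------

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        meta = self.gene_meta[list(GENE_META_COLUMNS)]
        pd.concat([meta, df], axis=1).to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "PAVMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        meta = df[list(GENE_META_COLUMNS)]
        calls = df.drop(columns=list(GENE_META_COLUMNS))
        return cls(list(df.index), list(calls.columns), calls.to_numpy(dtype=np.int8), meta)


@dataclass
class SampleSheet:
    """Accession metadata: population label (wild/selection) and region."""

    table: pd.DataFrame

    POPULATIONS = ("wild", "selection")

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "population"):
            if col not in t.columns:
                raise PavError(f"sample sheet missing column {col!r}")
        if "region" not in t.columns:
            t = t.assign(region="other")
        if t["sample_id"].duplicated().any():
            raise PavError("duplicate sample_id in sample sheet")
        if t["population"].isna().any():
            raise PavError("population must be non-null")
        bad = set(t["population"]) - set(self.POPULATIONS)
        if bad:
            raise PavError(f"unknown population labels: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def population_of(self, sample_ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.table["sample_id"], self.table["population"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise PavError(f"samples absent from sheet: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))
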