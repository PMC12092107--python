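"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are fixed here and nowhere else:

* GFF3 annotation is 1-based inclusive (as the format mandates);
* per-base depth tracks are BED-style 0-based half-open (mosdepth
  per-base dialect: ``chrom  start  end  depth`` with equal-depth runs);
* all internal interval arithmetic downstream is 0-based half-open.

Presence/absence matrices are serialized as haploid VCFv4.2 (REF=G for the
present allele, ALT=A for the absent allele, genotype ``0``/``1``/``.``)
and as a HapMap genotype table with single-letter G/A/N calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam

from .matrix import ABSENT, MISSING, PRESENT, GENE_META_COLUMNS, PAVMatrix, PavError

logger = logging.getLogger(__name__)


class GffParseError(PavError):
    pass


class BedParseError(PavError):
    pass


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class CdsAnnotation:
    """CDS intervals of one gene.

    ``cds_intervals`` are kept verbatim as 1-based inclusive (start, end)
    pairs, possibly overlapping across isoforms; union semantics are applied
    downstream when coverage is computed.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e in self.cds_intervals:
            if s > e:
                raise PavError(f"{self.gene_id}: CDS interval start {s} > end {e}")

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive (min start, max end) over all CDS intervals."""
        return (
            min(s for s, _ in self.cds_intervals),
            max(e for _, e in self.cds_intervals),
        )


def _validate_gff_lines(path: Path) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(f"{path}: line {ln}: expected 9 tab-separated fields, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GffParseError(f"{path}: line {ln}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GffParseError(f"{path}: line {ln}: bad interval {start}..{end}")


def read_gff_cds(path) -> list[CdsAnnotation]:
    """Parse a GFF3 and return one :class:`CdsAnnotation` per gene.

    CDS features are attached to a gene through their ``Parent`` chain
    (CDS -> mRNA -> gene) or, failing that, a ``gene_id`` attribute. CDS
    features with no resolvable gene are skipped; the number skipped is
    logged as a warning. Intervals are kept verbatim (no merging).
    """
    path = Path(path)
    _validate_gff_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, CdsAnnotation] = {}
    order: list[str] = []
    n_skipped = 0
    for cds in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = None
        for parent in db.parents(cds, featuretype="gene"):
            gene_id = parent.id
            break
        if gene_id is None:
            gene_id = cds.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            n_skipped += 1
            continue
        ann = genes.get(gene_id)
        if ann is None:
            ann = CdsAnnotation(gene_id, cds.seqid, cds.strand or ".", [])
            genes[gene_id] = ann
            order.append(gene_id)
        elif ann.chrom != cds.seqid:
            raise GffParseError(f"gene {gene_id}: CDS on multiple chromosomes")
        ann.cds_intervals.append((cds.start, cds.end))
    if n_skipped:
        logger.warning("read_gff_cds: skipped %d CDS features without a resolvable gene", n_skipped)
    return [genes[g] for g in order]


def write_gff_cds(annotations: list[CdsAnnotation], path) -> None:
    """Write gene/mRNA/CDS GFF3 lines for a set of single-isoform genes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            lo, hi = ann.span
            gid = ann.gene_id
            fh.write(f"{ann.chrom}\tpavpan\tgene\t{lo}\t{hi}\t.\t{ann.strand}\t.\tID={gid}\n")
            fh.write(f"{ann.chrom}\tpavpan\tmRNA\t{lo}\t{hi}\t.\t{ann.strand}\t.\tID={gid}.t1;Parent={gid}\n")
            for i, (s, e) in enumerate(ann.cds_intervals, 1):
                fh.write(
                    f"{ann.chrom}\tpavpan\tCDS\t{s}\t{e}\t.\t{ann.strand}\t0\t"
                    f"ID={gid}.cds{i};Parent={gid}.t1\n"
                )


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------


@dataclass
class DepthTrack:
    """Run-length encoded per-base depth over one sample's genome.

    ``records`` maps chromosome -> (starts, ends, depths) as int64 arrays in
    BED half-open coordinates, sorted and non-overlapping within each
    chromosome. Depth is defined as 0 anywhere no record covers.
    """

    records: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads < 0:
            raise BedParseError("total_mapped_reads must be non-negative")
        clean = {}
        for chrom, (s, e, d) in self.records.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            d = np.asarray(d, dtype=np.int64)
            if (d < 0).any():
                raise BedParseError(f"{chrom}: negative depth")
            if (e <= s).any():
                raise BedParseError(f"{chrom}: interval with end <= start")
            order = np.argsort(s, kind="stable")
            s, e, d = s[order], e[order], d[order]
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                raise BedParseError(f"{chrom}: overlapping depth records")
            clean[chrom] = (s, e, d)
        self.records = clean

    def depth_at(self, chrom: str, pos: int) -> int:
        """Depth at a single 0-based position (reference oracle; O(log n))."""
        if chrom not in self.records:
            return 0
        s, e, d = self.records[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < e[i]:
            return int(d[i])
        return 0

    def mean_depth(self) -> float:
        """Depth-weighted mean over the track footprint (QC covariate)."""
        tot = span = 0
        for s, e, d in self.records.values():
            lens = e - s
            tot += int((lens * d).sum())
            span += int(lens.sum())
        return tot / span if span else 0.0


def read_depth_bed(path, total_mapped_reads: int) -> DepthTrack:
    """Read a 4-column per-base depth BED (mosdepth per-base dialect)."""
    if total_mapped_reads <= 0 and total_mapped_reads != 0:
        raise BedParseError("total_mapped_reads must be positive (or 0 for an empty sample)")
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": np.int64},
        comment="#",
    )
    if (df["depth"] < 0).any():
        raise BedParseError(f"{path}: negative depth")
    if (df["end"] <= df["start"]).any():
        raise BedParseError(f"{path}: record with end <= start")
    records = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        records[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["depth"].to_numpy(),
        )
    return DepthTrack(records, total_mapped_reads)


def write_depth_bed(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.records:
            s, e, d = track.records[chrom]
            for row in zip(s.tolist(), e.tolist(), d.tolist()):
                fh.write(f"{chrom}\t{row[0]}\t{row[1]}\t{row[2]}\n")


# ---------------------------------------------------------------------------
# PAV matrix <-> VCF
# ---------------------------------------------------------------------------

_CALL_TO_GT = {PRESENT: (0,), ABSENT: (1,), MISSING: (None,)}


def write_pav_vcf(matrix: PAVMatrix, path) -> None:
    """Write the matrix as haploid VCFv4.2: REF=G present, ALT=A absent.

    Genes without location metadata (``source == "novel"``) are placed on a
    pseudo-contig ``novel`` at a running offset and flagged ``NOVEL`` in
    INFO so downstream tools never lose them. The gene's annotated end is
    stored under INFO/GEND for exact round-tripping.
    """
    header = pysam.VariantHeader()
    meta = matrix.gene_meta
    contigs = [c for c in pd.unique(meta.loc[meta["source"] != "novel", "chrom"])]
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    header.add_line("##contig=<ID=novel>")
    header.info.add("GEND", 1, "Integer", "1-based inclusive gene end")
    header.info.add("NOVEL", 0, "Flag", "Gene located on unplaced (novel) sequence")
    header.formats.add("GT", 1, "String", "Haploid presence genotype: 0=present(G), 1=absent(A)")
    for s in matrix.sample_ids:
        header.add_sample(s)
    novel_offset = 1
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, gid in enumerate(matrix.gene_ids):
            row = meta.iloc[i]
            novel = row["source"] == "novel"
            if novel:
                start1, end1, chrom = novel_offset, novel_offset + max(int(row["end"]) - int(row["start"]), 0), "novel"
                novel_offset = end1 + 1
            else:
                chrom, start1, end1 = row["chrom"], int(row["start"]), int(row["end"])
            rec = vf.new_record(contig=chrom, start=start1 - 1, alleles=("G", "A"), id=gid)
            rec.info["GEND"] = end1
            if novel:
                rec.info["NOVEL"] = True
            for j, sid in enumerate(matrix.sample_ids):
                rec.samples[sid]["GT"] = _CALL_TO_GT[int(matrix.calls[i, j])]
            vf.write(rec)


def read_pav_vcf(path) -> PAVMatrix:
    """Inverse of :func:`write_pav_vcf`."""
    gene_ids, rows, meta_rows = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            gene_ids.append(rec.id)
            calls = np.empty(len(samples), dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                allele = gt[0] if gt else None
                calls[j] = MISSING if allele is None else (PRESENT if allele == 0 else ABSENT)
            rows.append(calls)
            novel = "NOVEL" in rec.info
            meta_rows.append(
                {
                    "chrom": rec.contig,
                    "start": rec.pos,
                    "end": int(rec.info["GEND"]) if "GEND" in rec.info else rec.pos,
                    "source": "novel" if novel else "reference",
                }
            )
    meta = pd.DataFrame(meta_rows, index=pd.Index(gene_ids, name="gene_id"))
    return PAVMatrix(gene_ids, samples, np.vstack(rows) if rows else np.empty((0, len(samples)), np.int8), meta)


# ---------------------------------------------------------------------------
# PAV matrix <-> HapMap
# ---------------------------------------------------------------------------

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]
_CALL_TO_LETTER = {PRESENT: "G", ABSENT: "A", MISSING: "N"}
_LETTER_TO_CALL = {v: k for k, v in _CALL_TO_LETTER.items()}


def write_hapmap(matrix: PAVMatrix, path) -> None:
    """HapMap genotype table: present = 'G', absent = 'A', missing = 'N'."""
    meta = matrix.gene_meta
    out = pd.DataFrame(
        {
            "rs#": matrix.gene_ids,
            "alleles": "G/A",
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["start"].to_numpy(),
            "strand": "+",
            "assembly#": "NA",
            "center": "NA",
            "protLSID": "NA",
            "assayLSID": "NA",
            "panelLSID": "NA",
            "QCcode": "NA",
        }
    )
    letters = np.array(["A", "G"], dtype="<U1")
    genotypes = np.where(
        matrix.calls == MISSING, "N", letters[np.clip(matrix.calls, 0, 1)]
    )
    out = pd.concat(
        [out, pd.DataFrame(genotypes, columns=matrix.sample_ids)], axis=1
    )
    out.to_csv(path, sep="\t", index=False)


def read_hapmap(path) -> PAVMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = [c for c in df.columns if c not in _HAPMAP_META]
    calls = np.empty((len(df), len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        calls[:, j] = [_LETTER_TO_CALL[x] for x in df[s]]
    meta = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["pos"].astype(int).to_numpy(),
            "end": df["pos"].astype(int).to_numpy(),
            "source": np.where(df["chrom"].to_numpy() == "novel", "novel", "reference"),
        },
        index=pd.Index(df["rs#"], name="gene_id"),
    )
    return PAVMatrix(list(df["rs#"]), samples, calls, meta)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def write_newick(tree, path) -> None:
    """Write an NJ tree (or bare skbio TreeNode) as Newick with branch lengths."""
    node = getattr(tree, "tree", tree)
    node.write(str(path), format="newick")
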