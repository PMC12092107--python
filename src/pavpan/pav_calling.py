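"""Coverage-based gene presence/absence genotyping.

A gene is called *present* in an accession when the breadth of coverage
over the union of its CDS intervals — the fraction of CDS bases covered at
depth >= ``min_depth`` — is at least the presence threshold (default 0.95,
inclusive). "Coverage" here is breadth, a dimensionless fraction, which is
the only quantity a 0.95 cutoff is sensible for; the read-count-normalized
mean depth is computed alongside as a QC covariate but never enters the
call.

Breadth is held as an exact ratio of two integers (covered bases over CDS
union length) until the comparison, which is performed on exact rationals,
so the >= 0.95 boundary cannot be blurred by floating-point rounding.

A cell is *missing* (rather than absent) when the accession fails sample
QC: zero mapped reads, or genome-wide mean depth below a configurable
floor (default 1x).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .io_formats import CdsAnnotation, DepthTrack
from .matrix import ABSENT, MISSING, PRESENT, PAVMatrix, PavError

DEFAULT_PRESENCE_THRESHOLD = 0.95
DEFAULT_SCALE_CONSTANT = 1e6  # norm_depth is depth per million mapped reads


@dataclass
class GeneCoverage:
    """Coverage of one gene's CDS union in one accession."""

    sample_id: str
    gene_id: str
    cds_length: int
    covered_bases: int
    depth_sum: int  # sum of per-base depth over the CDS union
    norm_depth: float  # mean depth x (scale_constant / total_mapped_reads)

    def __post_init__(self) -> None:
        if not (0 <= self.covered_bases <= self.cds_length):
            raise PavError(
                f"{self.gene_id}/{self.sample_id}: covered_bases {self.covered_bases} "
                f"outside [0, {self.cds_length}]"
            )

    @property
    def breadth(self) -> float:
        return self.covered_bases / self.cds_length

    @property
    def breadth_exact(self) -> Fraction:
        return Fraction(self.covered_bases, self.cds_length)


def cds_union(annotation: CdsAnnotation) -> tuple[np.ndarray, int]:
    """Collapse a gene's CDS intervals to disjoint, sorted half-open intervals.

    Returns (intervals, total_length) where intervals is an (k, 2) int array
    in 0-based half-open coordinates and total_length counts each genomic
    base once (overlapping isoform CDS collapsed).
    """
    if not annotation.cds_intervals:
        raise PavError(f"{annotation.gene_id}: empty CDS list")
    iv = np.array(
        [(s - 1, e) for s, e in annotation.cds_intervals], dtype=np.int64
    )  # GFF 1-based inclusive -> half-open
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = np.array(merged, dtype=np.int64)
    return out, int((out[:, 1] - out[:, 0]).sum())


def _interval_coverage(
    track: DepthTrack, chrom: str, intervals: np.ndarray, min_depth: int
) -> tuple[int, int]:
    """(covered bases at depth >= min_depth, depth sum) over disjoint intervals.

    Works by interval intersection against the run-length encoded track —
    whole chromosomes are never materialized per-base.
    """
    if chrom not in track.records:
        return 0, 0
    s, e, d = track.records[chrom]
    lens = e - s
    pass_len = np.where(d >= min_depth, lens, 0)
    cum_pass = np.concatenate(([0], np.cumsum(pass_len)))
    cum_depth = np.concatenate(([0], np.cumsum(lens * d)))
    qs, qe = intervals[:, 0], intervals[:, 1]
    i0 = np.searchsorted(e, qs, side="right")
    i1 = np.searchsorted(s, qe, side="left")
    covered = cum_pass[i1] - cum_pass[i0]
    depth_sum = cum_depth[i1] - cum_depth[i0]
    has = i1 > i0
    if has.any():
        first = i0[has]
        last = i1[has] - 1
        left_clip = np.clip(qs[has] - s[first], 0, lens[first])
        right_clip = np.clip(e[last] - qe[has], 0, lens[last])
        covered_h = covered[has]
        covered_h -= np.where(d[first] >= min_depth, left_clip, 0)
        covered_h -= np.where(d[last] >= min_depth, right_clip, 0)
        covered[has] = covered_h
        depth_sum_h = depth_sum[has]
        depth_sum_h -= left_clip * d[first]
        depth_sum_h -= right_clip * d[last]
        depth_sum[has] = depth_sum_h
    return int(covered.sum()), int(depth_sum.sum())


def gene_coverage(
    track: DepthTrack,
    annotation: CdsAnnotation,
    min_depth: int = 1,
    scale_constant: float = DEFAULT_SCALE_CONSTANT,
    sample_id: str = "",
) -> GeneCoverage:
    """Breadth and normalized depth of one gene in one accession."""
    if min_depth < 1:
        raise PavError("min_depth must be >= 1")
    intervals, length = cds_union(annotation)
    covered, depth_sum = _interval_coverage(track, annotation.chrom, intervals, min_depth)
    if track.total_mapped_reads > 0:
        norm = (depth_sum / length) * (scale_constant / track.total_mapped_reads)
    else:
        norm = 0.0
    return GeneCoverage(sample_id, annotation.gene_id, length, covered, depth_sum, norm)


def call_presence(cov: GeneCoverage, threshold: float = DEFAULT_PRESENCE_THRESHOLD) -> int:
    """PRESENT iff breadth >= threshold (inclusive), compared on exact rationals."""
    if not (0 < threshold <= 1):
        raise PavError(f"presence threshold {threshold} outside (0, 1]")
    thr = Fraction(str(threshold))
    return PRESENT if cov.breadth_exact >= thr else ABSENT


def coverage_table(
    track: DepthTrack,
    annotations: list[CdsAnnotation],
    min_depth: int = 1,
    scale_constant: float = DEFAULT_SCALE_CONSTANT,
    sample_id: str = "",
) -> pd.DataFrame:
    """Per-gene coverage of one accession, vectorized over genes.

    Equivalent to calling :func:`gene_coverage` per gene but batched per
    chromosome for speed; returns a DataFrame with columns gene_id,
    cds_length, covered_bases, breadth, norm_depth.
    """
    if min_depth < 1:
        raise PavError("min_depth must be >= 1")
    rows = {
        "gene_id": [a.gene_id for a in annotations],
        "cds_length": np.empty(len(annotations), dtype=np.int64),
        "covered_bases": np.empty(len(annotations), dtype=np.int64),
        "depth_sum": np.empty(len(annotations), dtype=np.int64),
    }
    by_chrom: dict[str, list[int]] = {}
    unions = []
    for i, ann in enumerate(annotations):
        iv, length = cds_union(ann)
        unions.append(iv)
        rows["cds_length"][i] = length
        by_chrom.setdefault(ann.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        offsets = np.cumsum([0] + [len(unions[i]) for i in idx])
        allq = np.vstack([unions[i] for i in idx])
        if chrom in track.records:
            s, e, d = track.records[chrom]
            lens = e - s
            pass_len = np.where(d >= min_depth, lens, 0)
            cum_pass = np.concatenate(([0], np.cumsum(pass_len)))
            cum_depth = np.concatenate(([0], np.cumsum(lens * d)))
            qs, qe = allq[:, 0], allq[:, 1]
            i0 = np.searchsorted(e, qs, side="right")
            i1 = np.searchsorted(s, qe, side="left")
            covered = cum_pass[i1] - cum_pass[i0]
            depth_sum = cum_depth[i1] - cum_depth[i0]
            has = i1 > i0
            if has.any():
                first, last = i0[has], i1[has] - 1
                left_clip = np.clip(qs[has] - s[first], 0, lens[first])
                right_clip = np.clip(e[last] - qe[has], 0, lens[last])
                cv = covered[has]
                cv -= np.where(d[first] >= min_depth, left_clip, 0)
                cv -= np.where(d[last] >= min_depth, right_clip, 0)
                covered[has] = cv
                ds = depth_sum[has]
                ds -= left_clip * d[first]
                ds -= right_clip * d[last]
                depth_sum[has] = ds
        else:
            covered = np.zeros(len(allq), dtype=np.int64)
            depth_sum = np.zeros(len(allq), dtype=np.int64)
        for k, i in enumerate(idx):
            sl = slice(offsets[k], offsets[k + 1])
            rows["covered_bases"][i] = covered[sl].sum()
            rows["depth_sum"][i] = depth_sum[sl].sum()
    df = pd.DataFrame(rows)
    df["breadth"] = df["covered_bases"] / df["cds_length"]
    if track.total_mapped_reads > 0:
        df["norm_depth"] = (df["depth_sum"] / df["cds_length"]) * (
            scale_constant / track.total_mapped_reads
        )
    else:
        df["norm_depth"] = 0.0
    df.insert(0, "sample_id", sample_id)
    return df


@dataclass
class QcRules:
    """Sample-level QC: when a rule fires, every call of that sample is missing."""

    min_mapped_reads: int = 1
    min_mean_depth: float = 1.0


def build_pav_matrix(
    tracks: dict[str, DepthTrack],
    annotations: list[CdsAnnotation],
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    min_depth: int = 1,
    scale_constant: float = DEFAULT_SCALE_CONSTANT,
    qc_rules: QcRules | None = None,
) -> PAVMatrix:
    """Call presence/absence for every (gene, accession) pair.

    ``tracks`` maps sample_id -> DepthTrack; genes and samples keep input
    order. Samples failing QC get all-missing calls.
    """
    if not (0 < threshold <= 1):
        raise PavError(f"presence threshold {threshold} outside (0, 1]")
    qc = qc_rules or QcRules()
    sample_ids = list(tracks)
    if len(set(sample_ids)) != len(sample_ids):
        raise PavError("duplicate sample ids")
    gene_ids = [a.gene_id for a in annotations]
    thr = Fraction(str(threshold))
    calls = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int8)
    for j, sid in enumerate(sample_ids):
        track = tracks[sid]
        if track.total_mapped_reads < qc.min_mapped_reads or track.mean_depth() < qc.min_mean_depth:
            calls[:, j] = MISSING
            continue
        cov = coverage_table(track, annotations, min_depth, scale_constant, sid)
        # exact rational comparison: covered/length >= p/q  <=>  covered*q >= p*length
        present = (
            cov["covered_bases"].to_numpy() * thr.denominator
            >= thr.numerator * cov["cds_length"].to_numpy()
        )
        calls[:, j] = np.where(present, PRESENT, ABSENT)
    meta = pd.DataFrame(
        {
            "chrom": [a.chrom for a in annotations],
            "start": [a.span[0] for a in annotations],
            "end": [a.span[1] for a in annotations],
            "source": ["novel" if a.chrom.startswith("novel") else "reference" for a in annotations],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return PAVMatrix(gene_ids, sample_ids, calls, meta)
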