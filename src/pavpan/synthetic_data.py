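"""Synthetic cohorts with known gene-content truth.

The generator emulates the statistical structure the downstream analyses
assume for a two-population (wild vs artificial-selection) cohort:

* a core of genes present in every accession (default 77.23% of genes) and
  a variable fraction with a Beta-distributed occupancy spectrum;
* population differentiation of variable-gene presence frequencies under
  the Balding–Nichols model, so the expected F_ST equals a tunable target;
* a handful of "selected" genes whose presence frequencies are pinned to
  explicit (p_wild, p_selection) pairs — the default triple mirrors a
  transposon-derived gene dropping from 59.52% presence in the wild
  population to 26.21% under selection, and two genes nearly fixed by
  selection but ~10% absent in the wild;
* per-accession run-length depth tracks in which present genes have CDS
  breadth >= 0.98 and absent genes carry only background mismapping
  coverage, so the breadth >= 0.95 presence rule can be inverted.

Depth is emitted interval-wise (chunked Poisson), not read-level: read
simulation would add nothing testable to the coverage arithmetic.
Everything is reproducible byte-for-byte from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import CdsAnnotation, DepthTrack, write_depth_bed, write_gff_cds
from .matrix import ABSENT, MISSING, PRESENT, PAVMatrix, PavError, SampleSheet

# presence frequencies of the default "selected" genes: (p_wild, p_selection)
DEFAULT_SELECTED_SHIFTS = [(0.5952, 0.2621), (0.90, 1.0), (0.90, 1.0)]


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    Defaults are the cohort the analyses are sized for: 268 accessions
    (91 wild + 177 selection), 1000 genes of which 77.23% are core,
    mean sequencing depth 20x and background (mismapping) breadth 0.3 on
    absent genes.
    """

    n_genes: int = 1000
    n_wild: int = 91
    n_selection: int = 177
    core_fraction: float = 0.7723
    variable_freq_shape: tuple[float, float] = (0.8, 0.8)
    # calibrated so the empirical top-1% per-gene F_ST threshold of the
    # default cohort lands near 0.40, the value such scans report on real
    # wild-vs-domesticated fish cohorts of this size
    fst_target: float = 0.1
    selected_shifts: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_SELECTED_SHIFTS)
    )
    mean_depth: float = 20.0
    background_breadth: float = 0.3
    missing_rate: float = 0.0
    n_chromosomes: int = 10
    novel_fraction: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.n_wild + self.n_selection

    @property
    def n_core(self) -> int:
        return int(round(self.n_genes * self.core_fraction))

    @property
    def n_variable(self) -> int:
        return self.n_genes - self.n_core

    @property
    def n_selected_genes(self) -> int:
        return len(self.selected_shifts)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_wild < 1 or self.n_selection < 1:
            raise PavError("n_genes, n_wild, n_selection must be positive")
        if not (0 <= self.core_fraction <= 1):
            raise PavError("core_fraction outside [0, 1]")
        if not (0 <= self.fst_target < 1):
            raise PavError("fst_target outside [0, 1)")
        if self.n_selected_genes > self.n_variable:
            raise PavError(
                f"{self.n_selected_genes} selected genes exceed "
                f"{self.n_variable} variable genes"
            )
        if not (0 <= self.background_breadth < 0.95):
            raise PavError("background_breadth must stay below the presence threshold 0.95")
        for p1, p2 in self.selected_shifts:
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise PavError("selected shift frequencies outside [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise PavError("missing_rate outside [0, 1)")
        if self.mean_depth <= 0:
            raise PavError("mean_depth must be positive")

    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        d["variable_freq_shape"] = list(self.variable_freq_shape)
        d["selected_shifts"] = [list(x) for x in self.selected_shifts]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["variable_freq_shape"] = tuple(d["variable_freq_shape"])
        d["selected_shifts"] = [tuple(x) for x in d["selected_shifts"]]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    gene_ids: list[str]
    sample_ids: list[str]
    class_truth: np.ndarray  # "core" | "variable" per gene
    p_wild: np.ndarray
    p_selection: np.ndarray
    selected_flag: np.ndarray  # bool per gene
    presence: np.ndarray  # int8 (genes x samples), 1 present / 0 absent
    missing_mask: np.ndarray  # bool (genes x samples)
    population: np.ndarray  # "wild" | "selection" per sample

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "class_truth": self.class_truth,
                "p_wild": self.p_wild,
                "p_selection": self.p_selection,
                "selected_flag": self.selected_flag,
            }
        )

    def to_pav_matrix(self, annotations: list[CdsAnnotation] | None = None) -> PAVMatrix:
        """Truth presence matrix as a PAVMatrix (missing mask applied)."""
        calls = np.where(self.presence == 1, PRESENT, ABSENT).astype(np.int8)
        calls[self.missing_mask] = MISSING
        meta = None
        if annotations is not None:
            meta = pd.DataFrame(
                {
                    "chrom": [a.chrom for a in annotations],
                    "start": [a.span[0] for a in annotations],
                    "end": [a.span[1] for a in annotations],
                    "source": [
                        "novel" if a.chrom.startswith("novel") else "reference"
                        for a in annotations
                    ],
                },
                index=pd.Index([a.gene_id for a in annotations], name="gene_id"),
            )
        return PAVMatrix(self.gene_ids, self.sample_ids, calls, meta)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_sample_sheet(config: SimConfig) -> SampleSheet:
    """Deterministic ids: wild_0001.. then sel_0001..; regions alternate
    America/Canada within the wild population (both wild provenances exist
    in the cohort being emulated)."""
    ids = [f"wild_{i:04d}" for i in range(1, config.n_wild + 1)] + [
        f"sel_{i:04d}" for i in range(1, config.n_selection + 1)
    ]
    pops = ["wild"] * config.n_wild + ["selection"] * config.n_selection
    regions = [("America" if i % 2 == 0 else "Canada") for i in range(config.n_wild)] + [
        "other"
    ] * config.n_selection
    return SampleSheet(
        pd.DataFrame({"sample_id": ids, "population": pops, "region": regions})
    )


def simulate_pav_truth(config: SimConfig) -> SimTruth:
    """Draw the true presence matrix.

    Variable, non-selected genes follow Balding–Nichols: an ancestral
    frequency p ~ Beta(alpha, beta), then per-population frequencies
    p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F) independently, with F the target
    F_ST (F = 0 degenerates to p_k = p). Presence is an independent
    Bernoulli draw per accession. Core genes are present everywhere.
    """
    config.validate()
    rng = _rng(config.seed)
    G, S = config.n_genes, config.n_samples
    n_core, n_var = config.n_core, config.n_variable
    gene_ids = [f"gene_{i:05d}" for i in range(1, G + 1)]
    sheet = make_sample_sheet(config)
    population = np.array(
        ["wild"] * config.n_wild + ["selection"] * config.n_selection
    )

    class_truth = np.array(["core"] * n_core + ["variable"] * n_var, dtype=object)
    p_wild = np.ones(G)
    p_sel = np.ones(G)
    selected_flag = np.zeros(G, dtype=bool)

    alpha, beta = config.variable_freq_shape
    n_free = n_var - config.n_selected_genes
    if n_free > 0:
        p_anc = rng.beta(alpha, beta, size=n_free)
        F = config.fst_target
        if F > 0:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            pw = rng.beta(a, b)
            ps = rng.beta(a, b)
        else:
            pw = p_anc.copy()
            ps = p_anc.copy()
        p_wild[n_core : n_core + n_free] = pw
        p_sel[n_core : n_core + n_free] = ps
    for k, (pw_k, ps_k) in enumerate(config.selected_shifts):
        i = n_core + n_free + k
        p_wild[i] = pw_k
        p_sel[i] = ps_k
        selected_flag[i] = True

    wild_mask = population == "wild"
    per_cell_p = np.where(wild_mask[None, :], p_wild[:, None], p_sel[:, None])
    presence = (rng.random((G, S)) < per_cell_p).astype(np.int8)
    presence[:n_core, :] = 1

    missing_mask = np.zeros((G, S), dtype=bool)
    if config.missing_rate > 0:
        missing_mask = rng.random((G, S)) < config.missing_rate

    return SimTruth(
        gene_ids,
        sheet.sample_ids,
        class_truth,
        p_wild,
        p_sel,
        selected_flag,
        presence,
        missing_mask,
        population,
    )


def simulate_annotation(config: SimConfig) -> list[CdsAnnotation]:
    """Gene models to go with the truth: 1-3 CDS exons of 60-140 bp each,
    laid out along ``n_chromosomes`` chromosomes with a small fraction on
    unplaced ``novel_*`` contigs (mirroring genes assembled from unmapped
    reads)."""
    rng = _rng(config.seed + 1_000_003)
    anns: list[CdsAnnotation] = []
    n_novel = int(round(config.n_genes * config.novel_fraction))
    cursor: dict[str, int] = {}
    for i in range(config.n_genes):
        gid = f"gene_{i + 1:05d}"
        if i >= config.n_genes - n_novel:
            chrom = f"novel_{i - (config.n_genes - n_novel) + 1}"
        else:
            chrom = f"chr{(i % config.n_chromosomes) + 1}"
        pos = cursor.get(chrom, 0)
        n_exons = int(rng.integers(1, 4))
        intervals = []
        for _ in range(n_exons):
            pos += int(rng.integers(50, 400))  # intergenic / intron gap
            length = int(rng.integers(60, 141))
            intervals.append((pos + 1, pos + length))  # 1-based inclusive
            pos += length
        cursor[chrom] = pos
        strand = "+" if rng.random() < 0.5 else "-"
        anns.append(CdsAnnotation(gid, chrom, strand, intervals))
    return anns


_CHUNK = 50  # bp; depth is piecewise-constant on chunks of this size


def simulate_depth(
    truth: SimTruth, annotations: list[CdsAnnotation], config: SimConfig
) -> dict[str, DepthTrack]:
    """One run-length depth track per accession.

    Present genes: each <= 50 bp chunk of the CDS union draws a depth
    ~ Poisson(mean_depth) conditioned positive, and a random leading cut of
    at most 2% of the union is zeroed — realized breadth is >= 0.98 by
    construction. Absent genes: a random leading sub-interval totalling at
    most ``background_breadth`` of the CDS gets depth 1-2, the rest 0.
    total_mapped_reads is proportional to the sample's summed depth
    (~100 bp reads).
    """
    truth_ids = list(truth.gene_ids)
    ann_ids = [a.gene_id for a in annotations]
    if truth_ids != ann_ids:
        raise PavError("annotation gene set must equal truth gene set (same order)")
    from .pav_calling import cds_union

    # static chunk / interval geometry, shared by all samples
    chroms: list[str] = []
    chrom_idx: dict[str, int] = {}
    ck_start, ck_end, ck_gene, ck_chrom, ck_first = [], [], [], [], []
    iv_start, iv_end, iv_gene, iv_chrom, iv_cum = [], [], [], [], []
    union_len = np.empty(len(annotations), dtype=np.int64)
    for i, ann in enumerate(annotations):
        iv, length = cds_union(ann)
        union_len[i] = length
        ci = chrom_idx.setdefault(ann.chrom, len(chroms))
        if ci == len(chroms):
            chroms.append(ann.chrom)
        cum = 0
        first = True
        for s, e in iv:
            iv_start.append(s)
            iv_end.append(e)
            iv_gene.append(i)
            iv_chrom.append(ci)
            iv_cum.append(cum)
            cum += int(e - s)
            a = int(s)
            while a < e:
                b = min(a + _CHUNK, int(e))
                ck_start.append(a)
                ck_end.append(b)
                ck_gene.append(i)
                ck_chrom.append(ci)
                ck_first.append(first)
                first = False
                a = b
    ck_start = np.array(ck_start, dtype=np.int64)
    ck_end = np.array(ck_end, dtype=np.int64)
    ck_gene = np.array(ck_gene, dtype=np.int64)
    ck_chrom = np.array(ck_chrom, dtype=np.int64)
    ck_first = np.array(ck_first, dtype=bool)
    iv_start = np.array(iv_start, dtype=np.int64)
    iv_end = np.array(iv_end, dtype=np.int64)
    iv_gene = np.array(iv_gene, dtype=np.int64)
    iv_chrom = np.array(iv_chrom, dtype=np.int64)
    iv_cum = np.array(iv_cum, dtype=np.int64)
    max_cut = np.maximum((0.02 * union_len).astype(np.int64), 1)

    rng = _rng(config.seed + 2_000_003)
    tracks: dict[str, DepthTrack] = {}
    for j, sid in enumerate(truth.sample_ids):
        present = truth.presence[:, j] == 1
        # -- present genes: chunked positive-Poisson depth, leading cut --
        cuts = rng.integers(0, max_cut + 1)  # per gene; <= 2% of union length
        m = present[ck_gene]
        starts = ck_start[m].copy()
        shift = np.where(ck_first[m], cuts[ck_gene[m]], 0)
        starts += shift  # cut <= 8 bp < first chunk, so only it is trimmed
        ends = ck_end[m]
        depths = rng.poisson(config.mean_depth, size=len(starts)).astype(np.int64)
        zero = depths == 0
        while zero.any():
            depths[zero] = rng.poisson(config.mean_depth, size=int(zero.sum()))
            zero = depths == 0
        keep = ends > starts
        p_start, p_end, p_depth, p_chrom = starts[keep], ends[keep], depths[keep], ck_chrom[m][keep]
        # -- absent genes: leading background stretch at depth 1-2 --------
        budget = (config.background_breadth * union_len * rng.random(len(union_len))).astype(
            np.int64
        )
        m2 = ~present[iv_gene]
        take = np.clip(budget[iv_gene[m2]] - iv_cum[m2], 0, iv_end[m2] - iv_start[m2])
        keep2 = take > 0
        a_start = iv_start[m2][keep2]
        a_end = a_start + take[keep2]
        a_depth = rng.integers(1, 3, size=len(a_start)).astype(np.int64)
        a_chrom = iv_chrom[m2][keep2]

        all_start = np.concatenate([p_start, a_start])
        all_end = np.concatenate([p_end, a_end])
        all_depth = np.concatenate([p_depth, a_depth])
        all_chrom = np.concatenate([p_chrom, a_chrom])
        records = {}
        for ci in np.unique(all_chrom):
            sel = all_chrom == ci
            s, e, d = all_start[sel], all_end[sel], all_depth[sel]
            order = np.argsort(s, kind="stable")
            records[chroms[ci]] = (s[order], e[order], d[order])
        depth_total = int((all_depth * (all_end - all_start)).sum())
        total_reads = max(int(depth_total / 100), 1)
        tracks[sid] = DepthTrack(records, total_reads)
    return tracks


def write_cohort(config: SimConfig, outdir) -> dict[str, Path]:
    """Simulate and write the full fixture set: GFF3, per-sample depth BEDs,
    sample sheet, truth tables and the config itself. Returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_pav_truth(config)
    anns = simulate_annotation(config)
    tracks = simulate_depth(truth, anns, config)
    sheet = make_sample_sheet(config)

    paths = {
        "gff": outdir / "annotation.gff3",
        "sheet": outdir / "samples.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_matrix": outdir / "truth_matrix.tsv",
        "depth_dir": outdir / "depth",
        "reads": outdir / "mapped_reads.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_gff_cds(anns, paths["gff"])
    sheet.to_tsv(paths["sheet"])
    truth.truth_table().to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.to_pav_matrix(anns).to_tsv(paths["truth_matrix"])
    paths["depth_dir"].mkdir(exist_ok=True)
    reads_rows = []
    for sid, track in tracks.items():
        write_depth_bed(track, paths["depth_dir"] / f"{sid}.per-base.bed")
        reads_rows.append({"sample_id": sid, "total_mapped_reads": track.total_mapped_reads})
    pd.DataFrame(reads_rows).to_csv(paths["reads"], sep="\t", index=False)
    config.to_yaml(paths["config"])
    return paths
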