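"""End-to-end workflow: depth -> PAV matrix -> classification -> structure
-> differentiation -> association, with a machine-readable run manifest.

Every stage writes deterministic TSV/VCF/Newick artifacts into the run
directory; re-running with the same config and seed reproduces them
byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    fisher_assoc,
    filter_markers,
    glm_assoc,
    kinship,
    manhattan_table,
    mlm_assoc,
    qq_summary,
    significance,
)
from .io_formats import read_depth_bed, read_gff_cds, write_hapmap, write_newick, write_pav_vcf
from .matrix import PavError, SampleSheet
from .pan_classification import chromosome_density, classify_matrix, saturation
from .pav_calling import build_pav_matrix
from .popgen import (
    fst_per_gene,
    frequency_divergence,
    nj_tree,
    pav_distance,
    pav_pca,
    top_fraction,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and seeds of one pipeline run."""

    gff: str
    depth_dir: str
    sample_sheet: str
    mapped_reads: str  # TSV: sample_id, total_mapped_reads
    outdir: str
    presence_threshold: float = 0.95
    min_depth: int = 1
    maf_min: float = 0.05
    miss_max: float = 0.15
    top_fst: float = 0.01
    neglog10_cut: float = 5.0
    bonferroni_alpha: float = 0.05
    n_pcs: int = 3
    pca_k: int = 10
    fst_estimator: str = "weir_cockerham"
    assoc_models: tuple[str, ...] = ("glm", "mlm", "fisher")
    n_permutations: int = 100
    window: int = 1_000_000
    seed: int = 1
    build_tree: bool = True

    def validate(self) -> None:
        if not (0 < self.presence_threshold <= 1):
            raise PavError("presence_threshold outside (0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise PavError("maf_min outside [0, 0.5)")
        if not (0 < self.miss_max <= 1):
            raise PavError("miss_max outside (0, 1]")
        if not (0 < self.top_fst < 1):
            raise PavError("top_fst outside (0, 1)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["assoc_models"] = list(self.assoc_models)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "assoc_models" in d:
            d["assoc_models"] = tuple(d["assoc_models"])
        return cls(**d)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pavpan_version": __version__,
        "config": {**asdict(config), "assoc_models": list(config.assoc_models)},
        "stages": {},
    }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageFailure(name, exc) from exc
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 3)
                return False

        return _Ctx()

    with stage("call_pav"):
        annotations = read_gff_cds(config.gff)
        sheet = SampleSheet.from_tsv(config.sample_sheet)
        reads = pd.read_csv(config.mapped_reads, sep="\t", dtype={"sample_id": str})
        reads_of = dict(zip(reads["sample_id"], reads["total_mapped_reads"]))
        depth_dir = Path(config.depth_dir)
        tracks = {}
        for sid in sheet.sample_ids:
            bed = depth_dir / f"{sid}.per-base.bed"
            tracks[sid] = read_depth_bed(bed, int(reads_of[sid]))
        matrix = build_pav_matrix(
            tracks, annotations, threshold=config.presence_threshold, min_depth=config.min_depth
        )
        write_pav_vcf(matrix, out / "pav.vcf")
        write_hapmap(matrix, out / "pav.hapmap.tsv")
        matrix.to_tsv(out / "pav_matrix.tsv")

    with stage("classify"):
        classes, counts = classify_matrix(matrix)
        classes.to_csv(out / "classification.tsv", sep="\t", index=False)
        counts.to_csv(out / "classification_counts.tsv", sep="\t")
        density = chromosome_density(classes, matrix.gene_meta, window=config.window)
        density.to_csv(out / "class_density.tsv", sep="\t", index=False)

    with stage("saturate"):
        curve = saturation(matrix, n_permutations=config.n_permutations, seed=config.seed)
        curve.to_frame().to_csv(out / "saturation.tsv", sep="\t", index=False)

    with stage("structure"):
        pca = pav_pca(matrix, k=config.pca_k)
        pca.to_frame().to_csv(out / "pca_coordinates.tsv", sep="\t", index=False)
        pd.DataFrame({"component": np.arange(1, pca.k + 1), "explained": pca.explained}).to_csv(
            out / "pca_explained.tsv", sep="\t", index=False
        )
        dist = pav_distance(matrix)
        dist.to_phylip(out / "distance.phy")
        if config.build_tree:
            tree = nj_tree(dist)
            write_newick(tree, out / "nj_tree.nwk")

    with stage("fst"):
        fst = fst_per_gene(matrix, sheet, estimator=config.fst_estimator)
        threshold, fst = top_fraction(fst, fraction=config.top_fst)
        fst.to_csv(out / "fst.tsv", sep="\t", index=False)
        divergence = frequency_divergence(matrix, sheet)
        divergence.to_csv(out / "frequency_divergence.tsv", sep="\t", index=False)
        manifest["fst_top_threshold"] = threshold

    with stage("assoc"):
        filtered, qc = filter_markers(matrix, maf_min=config.maf_min, miss_max=config.miss_max)
        qc.to_csv(out / "marker_qc.tsv", sep="\t", index=False)
        pops = sheet.population_of(filtered.sample_ids)
        phenotype = (pops == "selection").astype(float)
        covars = pca.coordinates[:, : config.n_pcs] if config.n_pcs > 0 else None
        K, _ = kinship(filtered)
        model_fns = {
            "glm": lambda: glm_assoc(filtered, phenotype, covars),
            "mlm": lambda: mlm_assoc(filtered, phenotype, covars, K),
            "fisher": lambda: fisher_assoc(filtered, phenotype),
        }
        lambdas = {}
        for model in config.assoc_models:
            rec = significance(
                model_fns[model](),
                n_markers=filtered.n_genes,
                alpha=config.bonferroni_alpha,
                fixed_neglog10=config.neglog10_cut,
            )
            rec.to_csv(out / f"assoc_{model}.tsv", sep="\t", index=False)
            qq = qq_summary(rec)
            qq.to_frame().to_csv(out / f"qq_{model}.tsv", sep="\t", index=False)
            lambdas[model] = qq.lambda_gc
            manhattan_table(rec, filtered.gene_meta).to_csv(
                out / f"manhattan_{model}.tsv", sep="\t", index=False
            )
        manifest["lambda_gc"] = lambdas

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
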