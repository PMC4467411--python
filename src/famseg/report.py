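"""Pipeline orchestration: filters -> scores -> cascade -> contrast -> enrichment.

One configuration drives the whole analysis and every stage writes a plain
TSV, so each number in the run manifest can be recomputed from the stage
file it summarizes. Output is written to a temporary directory and renamed
into place on success; a failing stage therefore leaves no partial output.
"""

from __future__ import annotations

import json
import logging
import shutil
import sys
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .enrichment import band_sets_from_locations, filter_by_overlap, hypergeom_ora
from .filters import (
    FilterResult,
    multi_hit_genes,
    recessive_quad_filter,
    tumor_denovo_het_filter,
    tumor_newly_homozygous_filter,
)
from .model import CHILD_F, CHILD_M, GERMLINE_ROLES, TUMOR_F, TUMOR_M, ConfigurationError
from .scoring import ScoreConfig, cumulative_scores, sibling_contrast, three_step_filter
from .variant_io import attach_annotation, read_annotation, read_gene_locations, read_gmt, read_vcf

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf: Path
    roles: Path
    annotation: Path
    out_dir: Path
    gmt: Path | None = None
    locations: Path | None = None
    pass_only: bool = False
    nonsyn_only: bool = True
    run_recessive: bool = True
    run_tumor_filters: bool = True
    run_enrichment: bool = True
    alpha: float = 0.05
    min_overlap: int = 3
    score: ScoreConfig = field(default_factory=ScoreConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        for name in ("vcf", "roles", "annotation", "gmt", "locations"):
            value = getattr(self, name)
            if value is None:
                continue
            path = Path(value)
            setattr(self, name, path)
            if not path.exists():
                raise ConfigurationError(f"{name} path does not exist: {path}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        score = ScoreConfig(**raw.pop("score", {}))
        return cls(score=score, **raw)


def _filter_frame(result: FilterResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "rsid": v.rsid or ".",
                "ref": v.ref,
                "alt": v.alt,
                "genes": ",".join(sorted(v.genes)),
                "func_class": v.func_class,
                "filter_name": result.name,
            }
            for v in result.variants
        ],
        columns=["chrom", "pos", "rsid", "ref", "alt", "genes", "func_class", "filter_name"],
    )


def _enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "background_size": r.background_size,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "member_genes": ",".join(sorted(r.member_genes)),
            }
            for r in results
        ],
        columns=[
            "set_name", "overlap", "set_size", "query_size",
            "background_size", "p_raw", "p_adj", "member_genes",
        ],
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every enabled stage, write stage TSVs plus a run manifest.

    Returns the manifest (also written as ``run_manifest.json``). Raises
    :class:`StageError` naming the first failing stage; no output
    directory is created in that case.
    """
    t0 = time.time()
    counts: dict[str, int] = {}
    stage = "setup"
    tmp = Path(tempfile.mkdtemp(prefix="famseg_"))
    try:
        stage = "load_inputs"
        cohort = read_vcf(config.vcf, config.roles, pass_only=config.pass_only)
        cohort = attach_annotation(cohort, read_annotation(config.annotation))
        counts["variants_loaded"] = cohort.n_variants
        logger.info("stage=%s variants=%d samples=%d", stage, cohort.n_variants, cohort.n_samples)

        recessive = None
        if config.run_recessive:
            stage = "recessive_filter"
            recessive = recessive_quad_filter(cohort, nonsyn_only=config.nonsyn_only)
            _filter_frame(recessive).to_csv(tmp / "recessive_variants.tsv", sep="\t", index=False)
            hits = multi_hit_genes(recessive, min_hits=2)
            pd.DataFrame(
                sorted(hits.items(), key=lambda kv: (-kv[1], kv[0])),
                columns=["gene", "n_variants"],
            ).to_csv(tmp / "recessive_multi_hit_genes.tsv", sep="\t", index=False)
            counts["recessive_variants"] = recessive.n_variants
            counts["recessive_genes"] = recessive.n_genes
            counts["recessive_multi_hit_genes"] = len(hits)
            logger.info("stage=%s variants=%d genes=%d", stage, recessive.n_variants, recessive.n_genes)

        stage = "gene_scores"
        table = cumulative_scores(cohort, config.score)
        table.to_frame().to_csv(tmp / "gene_scores.tsv", sep="\t")
        counts["scored_genes"] = len(table.genes)

        if all(r in table.roles for r in GERMLINE_ROLES):
            stage = "three_step_filter"
            ranked = three_step_filter(table, config.score)
            pd.DataFrame(
                [
                    {"gene": r.gene, **{f"score_{k}": v for k, v in r.scores.items()},
                     "children_combined": r.children_combined,
                     "ratio": "inf" if r.ratio == float("inf") else round(r.ratio, 4)}
                    for r in ranked
                ]
            ).to_csv(tmp / "ranked_genes.tsv", sep="\t", index=False)
            counts["ranked_genes"] = len(ranked)

            stage = "sibling_contrast"
            for focus, other, fname in (
                (CHILD_F, CHILD_M, "contrast_daughter_minus_son.tsv"),
                (CHILD_M, CHILD_F, "contrast_son_minus_daughter.tsv"),
            ):
                pd.DataFrame(
                    sibling_contrast(table, focus, other), columns=["gene", "score_diff"]
                ).to_csv(tmp / fname, sep="\t", index=False)

        if config.run_tumor_filters and cohort.has_roles((TUMOR_F, TUMOR_M)):
            stage = "tumor_filters"
            hom = tumor_newly_homozygous_filter(cohort)
            het = tumor_denovo_het_filter(cohort)
            _filter_frame(hom).to_csv(tmp / "tumor_newly_homozygous.tsv", sep="\t", index=False)
            _filter_frame(het).to_csv(tmp / "tumor_denovo_het.tsv", sep="\t", index=False)
            counts["tumor_newly_homozygous_variants"] = hom.n_variants
            counts["tumor_denovo_het_variants"] = het.n_variants
            logger.info("stage=%s newly_hom=%d denovo_het=%d", stage, hom.n_variants, het.n_variants)

        if config.run_enrichment and recessive is not None:
            stage = "enrichment"
            query = set(recessive.genes)
            if config.locations is not None:
                locations = read_gene_locations(config.locations)
                chrom_sets, band_sets = band_sets_from_locations(locations)
                for sets, fname, key in (
                    (chrom_sets, "enrichment_chromosomes.tsv", "significant_chromosomes"),
                    (band_sets, "enrichment_bands.tsv", "significant_bands"),
                ):
                    results = hypergeom_ora(query, sets)
                    _enrichment_frame(results).to_csv(tmp / fname, sep="\t", index=False)
                    counts[key] = int(sum(r.p_adj < config.alpha for r in results))
            if config.gmt is not None:
                background = set(read_gene_locations(config.locations)) if config.locations else None
                if background is None:
                    ann = read_annotation(config.annotation)
                    background = {g for genes, _ in ann.values() for g in genes}
                pathways = read_gmt(config.gmt, background)
                results = filter_by_overlap(hypergeom_ora(query, pathways), config.min_overlap)
                _enrichment_frame(results).to_csv(tmp / "enrichment_pathways.tsv", sep="\t", index=False)
                counts["significant_pathways"] = int(sum(r.p_adj < config.alpha for r in results))

        stage = "manifest"
        manifest = {
            "famseg_version": __version__,
            "python_version": sys.version.split()[0],
            "seed": config.seed,
            "alpha": config.alpha,
            "nonsyn_only": config.nonsyn_only,
            "score_config": {
                "min_child_score": config.score.min_child_score,
                "child_parent_ratio": config.score.child_parent_ratio,
                "child_rule": config.score.child_rule,
            },
            "counts": counts,
            "runtime_seconds": round(time.time() - t0, 3),
            "notes": (
                "Fixture-reproducible quantities are the filter and gene counts; "
                "enrichment p-values depend on the supplied background/gene sets."
            ),
        }
        (tmp / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

        config.out_dir.parent.mkdir(parents=True, exist_ok=True)
        if config.out_dir.exists():
            shutil.rmtree(config.out_dir)
        shutil.move(str(tmp), str(config.out_dir))
        return manifest
    except Exception as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
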