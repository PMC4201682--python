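"""Single-entry orchestration of simulate -> normalize -> anova -> classify
-> enrich -> pca, with a manifest and deterministic seeding.

All randomness flows from one config seed: stage seeds are derived with
``numpy.random.SeedSequence([seed, stage_index])`` (stage indices fixed in
``STAGE_INDEX``), so re-running with the same config reproduces every TSV
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import StudyDesign
from .model import AcclimationAnova, SamplePCA
from .preprocess import normalize_pipeline
from .synthetic import (
    DEFAULT_CLASS_PROPORTIONS,
    DEFAULT_NOISE,
    generate_annotation,
    generate_dataset,
    generate_probe_level,
)

logger = logging.getLogger(__name__)

STAGE_INDEX = {"dataset": 0, "probes": 1, "annotation": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the config seed."""
    ss = np.random.SeedSequence([int(seed), STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run (CLI flag > config file > default)."""

    out_dir: str = "gxe_run"
    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    simulate_probes: bool = False
    probe_offset_sd: float = 0.25
    n_pathways: int = 125
    genes_per_pathway: tuple = (10, 60)
    n_enriched: int = 10
    enrichment_boost: float = 8.0
    alpha: float = 0.05
    pooling_threshold: float = 0.2
    pool_applies_to: str = "both"
    fdr_method: str = "bh"
    universe: str = "all"
    pca_k: int = 3
    plot: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if not 0 < self.pooling_threshold < 1:
            raise ValueError(
                f"pooling_threshold must lie in (0,1), got {self.pooling_threshold}"
            )
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.genes_per_pathway, list):
            cfg.genes_per_pathway = tuple(cfg.genes_per_pathway)
        return cfg


def run_all(config: PipelineConfig) -> Path:
    """Execute the full chain; returns the result directory.

    Writes per-stage TSVs plus ``manifest.json`` (version, seed, parameters,
    per-stage gene counts) and ``run.log``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("gxe_acclim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    try:
        # -- simulate ---------------------------------------------------------
        design = StudyDesign.default(config.n_replicates)
        expr, truth = generate_dataset(
            config.n_genes,
            class_proportions=config.class_proportions,
            noise=config.noise,
            design=design,
            seed=stage_seed(config.seed, "dataset"),
        )
        annotation, pathway_truth = generate_annotation(
            truth,
            n_pathways=config.n_pathways,
            genes_per_pathway=tuple(config.genes_per_pathway),
            n_enriched=config.n_enriched,
            enrichment_boost=config.enrichment_boost,
            seed=stage_seed(config.seed, "annotation"),
        )
        design.to_tsv(out / "design.tsv")
        expr.to_tsv(out / "expr.tsv")
        truth.to_tsv(out / "truth.tsv")
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        pathway_truth.to_csv(out / "pathway_truth.tsv", sep="\t", index=False)
        manifest["stages"]["simulate"] = {
            "n_genes": expr.n_genes, "n_samples": design.n_samples,
            "n_pathways": config.n_pathways,
        }
        logger.info("simulate: %d genes x %d samples", expr.n_genes, design.n_samples)

        probes = None
        if config.simulate_probes:
            probes = generate_probe_level(
                expr, probe_offset_sd=config.probe_offset_sd,
                seed=stage_seed(config.seed, "probes"),
            )
            probes.to_tsv(out / "probes.tsv", out / "probe_map.tsv")
            manifest["stages"]["simulate"]["n_probes"] = len(probes.values)

        # -- normalize --------------------------------------------------------
        norm = normalize_pipeline(expr, probes)
        norm.to_tsv(out / "normexpr.tsv")
        manifest["stages"]["normalize"] = {"n_genes": norm.n_genes}

        # -- anova ------------------------------------------------------------
        res = AcclimationAnova(norm, design).fit(
            alpha=config.alpha,
            pooling_threshold=config.pooling_threshold,
            pool_applies_to=config.pool_applies_to,
            fdr_method=config.fdr_method,
        )
        res.save(out / "anova")
        g = res.gene_table
        manifest["stages"]["anova"] = {
            "n_genes": len(g),
            "pooled": int(g["pooled"].sum()),
            "sig_T": int((g["q_T"] < config.alpha).sum()),
            "sig_T_x_geo": int((g["q_T_x_geo"] < config.alpha).sum()),
        }
        logger.info("anova: %s", manifest["stages"]["anova"])

        # -- classify ---------------------------------------------------------
        calls = res.classify_gxe()
        calls.to_csv(out / "calls.tsv", sep="\t", index=False, float_format="%.10g")
        res.crosstab().to_csv(out / "crosstab.tsv", sep="\t")
        manifest["stages"]["classify"] = {
            "n_genes": len(calls), **res.plasticity_summary(),
        }

        # -- enrich -----------------------------------------------------------
        enr = res.pathway_enrichment(annotation, universe=config.universe)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
        kog_counts = res.ipath_lists(annotation, out / "ipath")
        manifest["stages"]["enrich"] = {
            "n_pathways_tested": len(enr),
            "sig_pathways": int((enr["q"] < config.alpha).sum()),
            "kog_list_sizes": kog_counts,
        }

        # -- pca --------------------------------------------------------------
        pres = SamplePCA(norm, design).fit(k=config.pca_k)
        pres.save(out / "pca_scores.tsv", out / "pca_geometry.tsv")
        if config.plot:
            pres.plot(out / "pca.svg")
        manifest["stages"]["pca"] = {
            "variance_fraction": [float(v) for v in pres.geometry.variance_fraction],
            "mean_clone_arrow_cosine": pres.mean_clone_arrow_cosine(),
            "temp_origin_cosine": float(pres.geometry.temp_origin_cosine),
        }

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
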