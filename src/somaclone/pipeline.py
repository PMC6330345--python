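"""End-to-end orchestration: simulate -> classify -> annotate -> contrast ->
cluster -> enrich -> phenotype, from one configuration.

Every stage writes plain-text outputs under one run directory and the run
ends with a JSON manifest listing per-stage summaries, the seeds used, and
a SHA-256 checksum of every output file; re-running the same configuration
reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import annotate_contrast_sites, summarize_high_impact, write_genome_fasta, write_gff3
from .expression import (
    clusters_from_labels,
    count_de_summary,
    de_test,
    find_absence_presence,
    find_constant_de,
    hypergeom_enrichment,
    loose_vs_compact_contrast,
    mean_profiles,
    qt_cluster,
)
from .genotype import (
    ClassificationThresholds,
    classify_sites,
    contrast_sites_to_frame,
    detect_contrast_sites,
    recover_planted_sites,
)
from .phenotype import summarize_clone
from .simulate import (
    ClonePanelSpec,
    ExpressionSimParams,
    VariantSimParams,
    default_phenotype_params,
    gene_ids_for,
    simulate_allele_counts,
    simulate_category_map,
    simulate_expression,
    simulate_phenotypes,
    simulate_reference_and_sites,
)
from .variant_io import filter_by_quality, read_vcf_allele_counts, write_vcf

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master), index]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """One structured configuration for a full run.

    ``variants``, ``expression``, ``classification``, ``contrasts``,
    ``gene_classes``, ``clustering``, ``enrichment`` and ``phenotypes``
    are per-stage option dictionaries; defaults reproduce the study-style
    demo (all-simulated inputs).
    """

    seed: int = 0
    outdir: str | Path = "run"
    vcf: str | None = None  # use an existing VCF instead of simulating
    variants: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)
    gene_classes: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    phenotypes: dict = field(default_factory=dict)

    _KNOWN = {
        "seed", "outdir", "vcf", "variants", "classification", "expression",
        "contrasts", "gene_classes", "clustering", "enrichment", "phenotypes",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.vcf is not None and not Path(self.vcf).exists():
            raise ValueError(f"input VCF not found and no simulation requested: {self.vcf}")
        ClassificationThresholds(**self.classification)  # range checks
        alpha = self.contrasts.get("alpha", 0.05)
        if not 0 < alpha < 1:
            raise ValueError("contrasts.alpha must lie in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = ClonePanelSpec()
    manifest: dict = {
        "version": __version__,
        "master_seed": int(config.seed),
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def save(df, name: str, **kwargs):
        path = outdir / name
        df.to_csv(path, sep="\t", index=kwargs.pop("index", False), float_format="%.6g")
        written.append(path)
        return path

    # --- stage 1: variants (simulate or load) --------------------------------
    vseed = _stage_seed(config.seed, 1)
    vopts = dict(config.variants)
    n_sites = int(vopts.pop("n_sites", 20))
    n_background = int(vopts.pop("n_background_sites", 50))
    vparams = VariantSimParams(seed=vseed, n_background_sites=n_background, **vopts)
    if config.vcf is None:
        genome, models, sites = simulate_reference_and_sites(
            panel, n_sites, n_background_sites=n_background, seed=vseed
        )
        records, vtruth = simulate_allele_counts(panel, sites, vparams, genome=genome)
        write_genome_fasta(genome, outdir / "genome.fa")
        write_gff3(models, outdir / "genes.gff3")
        write_vcf(records, outdir / "variants.vcf")
        vtruth.to_json(outdir / "variant_truth.json")
        written += [outdir / "genome.fa", outdir / "genes.gff3",
                    outdir / "variants.vcf", outdir / "variant_truth.json"]
        vcf_path = outdir / "variants.vcf"
    else:
        genome, models, vtruth = None, [], None
        vcf_path = Path(config.vcf)
    records = read_vcf_allele_counts(vcf_path, panel.sample_map())
    n_read = len(records)
    records = filter_by_quality(records, config.classification.get("min_quality", 40.0))
    manifest["stages"]["variants"] = {
        "seed": vseed, "records_read": n_read, "records_after_quality": len(records),
    }

    # --- stage 2: genotype classification ------------------------------------
    class_opts = {k: v for k, v in config.classification.items() if k != "min_quality"}
    thresholds = ClassificationThresholds(**class_opts)
    site_calls = classify_sites(records, thresholds)
    contrast_sites = detect_contrast_sites(site_calls, thresholds)
    save(contrast_sites_to_frame(contrast_sites), "contrast_sites.tsv")
    summary: dict = {
        "sites": len(contrast_sites),
        "passing_sites": sum(s.passes for s in contrast_sites),
    }
    if vtruth is not None:
        precision, recall = recover_planted_sites(contrast_sites, vtruth.site_truth)
        summary.update(precision=precision, recall=recall)
    manifest["stages"]["classification"] = summary

    # --- stage 3: effect annotation ------------------------------------------
    if genome is not None and models:
        passing = [s for s in contrast_sites if s.passes]
        effects = annotate_contrast_sites(passing, models, genome)
        save(summarize_high_impact(effects, passing), "high_impact_sites.tsv")
        manifest["stages"]["annotation"] = {
            "annotated_sites": len(passing),
            "high_impact_rows": sum(
                1 for effs in effects.values() for e in effs if e.impact == "HIGH"
            ),
        }

    # --- stage 4: expression --------------------------------------------------
    eseed = _stage_seed(config.seed, 2)
    eopts = dict(config.expression)
    eparams = _default_expression_params(panel, eseed, eopts)
    matrices, etruth = simulate_expression(panel, eparams)
    etruth.to_json(outdir / "expression_truth.json")
    written.append(outdir / "expression_truth.json")
    for stage, cm in matrices.items():
        tag = stage.replace("-", "")
        cm.write_tsv(outdir / f"counts_{tag}.tsv", outdir / f"samples_{tag}.tsv")
        written += [outdir / f"counts_{tag}.tsv", outdir / f"samples_{tag}.tsv"]

    fc = config.contrasts.get("fc_threshold", 2.0)
    alpha = config.contrasts.get("alpha", 0.05)
    de_results = []
    clone_pairs = [
        (a, b) for i, a in enumerate(panel.clone_ids) for b in panel.clone_ids[i + 1 :]
    ]
    compacts = panel.clones_in_group("compact")
    for stage, cm in matrices.items():
        for a, b in clone_pairs:
            de_results.append(
                de_test(
                    cm, cm.sample_names(clone=a, stage=stage),
                    cm.sample_names(clone=b, stage=stage),
                    fc_threshold=fc, alpha=alpha, contrast=f"{a}_vs_{b}", stage=stage,
                )
            )
        for loose in panel.clones_in_group("loose"):
            de_results.append(
                loose_vs_compact_contrast(cm, loose, compacts, stage, fc, alpha)
            )
    all_de = pd.concat(de_results, ignore_index=True)
    save(all_de[all_de["significant"]], "de_significant.tsv")
    save(count_de_summary(de_results), "de_summary.tsv")

    gopts = config.gene_classes
    class_frames = []
    stage_list = list(panel.stages)
    for stage, cm in matrices.items():
        for clone in panel.clone_ids:
            others = [c for c in panel.clone_ids if c != clone]
            class_frames.append(
                find_absence_presence(
                    cm, clone, others, stage,
                    max_reads=gopts.get("max_reads", 3),
                    min_fc=gopts.get("min_fc", 8.0),
                    expressed_floor=gopts.get("expressed_floor", 5),
                )
            )
    for loose in panel.clones_in_group("loose"):
        de1 = next(
            d for d in de_results
            if d["contrast"].iloc[0] == f"{loose}_vs_compact" and d["stage"].iloc[0] == stage_list[0]
        )
        de2 = next(
            d for d in de_results
            if d["contrast"].iloc[0] == f"{loose}_vs_compact" and d["stage"].iloc[0] == stage_list[1]
        )
        class_frames.append(find_constant_de(de1, de2))
    class_frames = [f for f in class_frames if len(f)] or class_frames[:1]
    gene_classes = pd.concat(class_frames, ignore_index=True)
    save(gene_classes, "gene_classes.tsv")
    manifest["stages"]["expression"] = {
        "seed": eseed,
        "n_genes": eparams.n_genes,
        "significant_de_rows": int(all_de["significant"].sum()),
        "gene_class_calls": len(gene_classes),
    }

    # --- stage 5: clustering ---------------------------------------------------
    de_genes = sorted(set(all_de.loc[all_de["significant"], "gene_id"]))
    copts = config.clustering
    if len(de_genes) >= 2:
        profiles = mean_profiles(matrices, genes=de_genes)
        labels = qt_cluster(
            profiles,
            max_diameter=copts.get("max_diameter", 0.2),
            min_cluster_size=copts.get("min_cluster_size", 2),
        )
        save(labels.rename_axis("gene_id").reset_index(), "clusters.tsv")
        n_clusters = len(clusters_from_labels(labels))
    else:
        n_clusters = 0
    manifest["stages"]["clustering"] = {"genes_clustered": len(de_genes), "clusters": n_clusters}

    # --- stage 6: enrichment ---------------------------------------------------
    universe = gene_ids_for(eparams)
    categories = simulate_category_map(
        universe, etruth,
        n_categories=config.enrichment.get("n_categories", 15),
        seed=_stage_seed(config.seed, 3),
    )
    save(categories, "categories.tsv")
    gene_list = de_genes if de_genes else []
    enrichment = hypergeom_enrichment(
        gene_list, universe, categories, alpha=config.enrichment.get("alpha", 0.05)
    )
    save(enrichment, "enrichment.tsv")
    manifest["stages"]["enrichment"] = {
        "list_size": len(gene_list),
        "significant_categories": int(enrichment["significant"].sum()) if len(enrichment) else 0,
    }

    # --- stage 7: phenotypes ----------------------------------------------------
    pseed = _stage_seed(config.seed, 4)
    phen = simulate_phenotypes(
        default_phenotype_params(panel),
        n_inflorescences=config.phenotypes.get("n_inflorescences", 10),
        seed=pseed,
    )
    save(phen, "phenotypes.tsv")
    save(summarize_clone(phen), "phenotype_summary.tsv")
    manifest["stages"]["phenotypes"] = {"seed": pseed, "inflorescences": len(phen)}

    # --- manifest ---------------------------------------------------------------
    for path in sorted(set(written)):
        manifest["outputs"][path.name] = _sha256(path)
    manifest_path = outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d outputs under %s", len(manifest["outputs"]), outdir)
    return manifest


def _default_expression_params(panel: ClonePanelSpec, seed: int, opts: dict) -> ExpressionSimParams:
    """Expression parameters for the demo run, with planted gene classes.

    Unless overridden, plants per loose clone: 5 silent genes, 10 genes
    with a constant log2 effect of +/-3, and 20 genes differential at the
    first stage only (emulating the pre-flowering excess of expression
    differences).
    """
    n_genes = int(opts.pop("n_genes", 500))
    if any(k in opts for k in ("planted_absent", "planted_constant_de", "planted_stage_de")):
        return ExpressionSimParams(n_genes=n_genes, seed=seed, **opts)
    ids = [f"g{i:04d}" for i in range(n_genes)]
    loose = panel.clones_in_group("loose")
    cursor = 0

    def take(k):
        nonlocal cursor
        chunk = tuple(ids[cursor : cursor + k])
        cursor += k
        return chunk

    planted_absent = {clone: take(5) for clone in loose}
    planted_constant = tuple(
        (clone, take(10), effect) for clone in loose for effect in (3.0, -3.0)
    )
    planted_stage = tuple(
        (clone, take(20), 2.5, panel.stages[0]) for clone in loose
    )
    return ExpressionSimParams(
        n_genes=n_genes,
        planted_absent=planted_absent,
        planted_constant_de=planted_constant,
        planted_stage_de=planted_stage,
        seed=seed,
        **opts,
    )
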