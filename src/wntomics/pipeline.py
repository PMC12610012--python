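"""End-to-end orchestration: simulate -> screen -> GSEA -> consistency ->
mIF phenotyping -> spatial interaction -> exact statistics, with artifacts
and a machine-readable run report.

A single global seed fans out to per-stage seeds by fixed offsets so each
stage is independently reproducible.  Every artifact is written through
:mod:`wntomics.io`; the JSON report records per-stage counts, the package
version, the seed, and a hash of the configuration, and is structurally
validated against the schema shipped at ``wntomics/run_report.schema.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .gsea import ConsistencyConfig, consistency_filter, filter_gene_sets, \
    make_ranked_list, run_gsea
from .phenotyping import MaskConfig, PhenotypeConfig, assign_compartments, \
    build_tumor_mask, combat_normalize, compute_densities, masks_to_geojson, \
    phenotype_cells, summarize_table
from .screen import ScreenConfig, compute_group_stats, concordance_screen, \
    welch_group_compare
from .spatial import ClusterConfig, build_graph, cluster_enrichment, \
    cluster_images, interaction_profile
from .synthetic import SimulationConfig, default_thresholds, gen_cell_tables, \
    gen_cohort_pair, gen_gene_sets

__all__ = ["RunConfig", "run_pipeline", "validate_report"]

log = logging.getLogger(__name__)

# fixed per-stage seed offsets under the global seed
STAGE_SEED_OFFSETS = {"simulate": 0, "gsea": 11, "spatial": 23}


@dataclass
class RunConfig:
    """Pipeline configuration; stages run on synthetic inputs by default."""

    out_dir: str = "wntomics_run"
    seed: int = 0
    #: external input paths (keys: discovery, discovery_groups,
    #: validation_prot, validation_rna, validation_groups, gene_sets,
    #: cells, genotypes); when None, inputs are simulated instead
    inputs: dict | None = None
    simulation: SimulationConfig | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    consistency: ConsistencyConfig = field(default_factory=ConsistencyConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    #: clusters compared against the rest in the genotype Fisher test;
    #: "auto" = the two clusters with the strongest immune-immune centroids
    immune_clusters: tuple[int, ...] | str = "auto"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "out_dir" in raw:
            kw["out_dir"] = raw["out_dir"]
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        if "inputs" in raw:
            kw["inputs"] = dict(raw["inputs"])
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            for key in ("set_size_range", "cells_per_image_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kw["simulation"] = SimulationConfig(**sim)
        if "screen" in raw:
            kw["screen"] = ScreenConfig(**raw["screen"])
        if "consistency" in raw:
            kw["consistency"] = ConsistencyConfig(**raw["consistency"])
        if "mask" in raw:
            kw["mask"] = MaskConfig(**raw["mask"])
        if "cluster" in raw:
            kw["cluster"] = ClusterConfig(**raw["cluster"])
        if "immune_clusters" in raw:
            v = raw["immune_clusters"]
            kw["immune_clusters"] = v if v == "auto" else tuple(v)
        return cls(**kw)

    def config_hash(self) -> str:
        payload = json.dumps(_as_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_plain(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d.pop("out_dir", None)   # the hash covers the scientific config only
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic inputs; returns (and writes) the report.

    Artifacts land under ``config.out_dir``; the report is written to
    ``report.json`` there.  A stage failure raises after recording the
    failing stage in a partial report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "status": "running",
    }
    stage = "simulate" if config.inputs is None else "load_inputs"
    try:
        if config.inputs is None:
            sim = config.simulation or SimulationConfig()
            sim = sim.with_(seed=config.seed + STAGE_SEED_OFFSETS["simulate"])

            log.info("[simulate] generating cohorts, gene sets, cell tables")
            discovery, val_prot, val_rna, truth = gen_cohort_pair(sim)
            collection = gen_gene_sets(sim, truth)
            cell_table, cell_truth = gen_cell_tables(sim)
            genotype = pd.Series(cell_truth.image_genotype)
            io.write_matrix(discovery, out / "discovery.tsv",
                            out / "discovery_groups.tsv")
            io.write_matrix(val_prot, out / "validation_prot.tsv",
                            out / "validation_groups.tsv")
            io.write_matrix(val_rna, out / "validation_rna.tsv",
                            out / "validation_groups.tsv")
            io.write_gmt(collection, out / "gene_sets.gmt")
            io.write_json({"de_proteins": truth.de_proteins,
                           "enriched_sets": truth.enriched_sets,
                           "image_regime": cell_truth.image_regime,
                           "image_genotype": cell_truth.image_genotype},
                          out / "truth.json")
        else:
            log.info("[load_inputs] reading externally supplied inputs")
            paths = config.inputs
            required = ["discovery", "discovery_groups", "validation_prot",
                        "validation_groups", "validation_rna", "gene_sets",
                        "cells", "genotypes"]
            for key in required:
                if key not in paths:
                    raise ValueError(f"missing input path {key!r}")
                if not Path(paths[key]).exists():
                    raise FileNotFoundError(f"input {key!r} not found: {paths[key]}")
            discovery = io.read_matrix(paths["discovery"], paths["discovery_groups"])
            val_prot = io.read_matrix(paths["validation_prot"],
                                      paths["validation_groups"])
            val_rna = io.read_matrix(paths["validation_rna"],
                                     paths["validation_groups"])
            collection = io.read_gmt(paths["gene_sets"])
            cell_table = io.read_cells(paths["cells"])
            genotype = pd.Series(io.read_json(paths["genotypes"]))
        report["stages"][stage] = {
            "n_proteins": len(discovery.feature_ids),
            "n_validation_features": len(val_prot.feature_ids),
            "n_gene_sets": len(collection),
            "n_images": len(cell_table.image_ids()),
            "n_cells": len(cell_table),
        }

        stage = "screen"
        log.info("[screen] differential statistics and concordance cascade")
        disc_stats = compute_group_stats(discovery, rank_by=config.screen.rank_by)
        val_stats = compute_group_stats(val_prot, rank_by=config.screen.rank_by)
        rna_stats = compute_group_stats(val_rna, rank_by=config.screen.rank_by)
        screen_res = concordance_screen(disc_stats, val_stats, config.screen)
        screen_res.audit.to_csv(out / "screen_audit.tsv", sep="\t")
        io.write_json({"validated": screen_res.validated,
                       "stage_counts": screen_res.stage_counts},
                      out / "screen.json")
        report["stages"]["screen"] = dict(screen_res.stage_counts)

        stage = "gsea"
        log.info("[gsea] preranked enrichment on three datasets")
        gcfg = config.consistency
        gcfg = ConsistencyConfig(pct=gcfg.pct, n_perm=gcfg.n_perm,
                                 weight_p=gcfg.weight_p,
                                 seed=config.seed + STAGE_SEED_OFFSETS["gsea"])
        selected = filter_gene_sets(collection, screen_res.validated) \
            if screen_res.validated else collection
        tables = {}
        for tag, stats in (("disc_prot", disc_stats), ("val_prot", val_stats),
                           ("val_rna", rna_stats)):
            ranked = make_ranked_list(stats)
            tbl = run_gsea(ranked, selected, gcfg, dataset=tag)
            tbl.to_csv(out / f"gsea_{tag}.tsv", sep="\t")
            tables[tag] = tbl
        report["stages"]["gsea"] = {"n_sets_scored": len(selected)}

        stage = "consistency"
        consistent, cons_audit = consistency_filter(tables, pct=gcfg.pct)
        cons_audit.to_csv(out / "consistency_audit.tsv", sep="\t")
        (out / "consistent_pathways.txt").write_text(
            "".join(f"{n}\n" for n in consistent))
        report["stages"]["consistency"] = {"n_consistent": len(consistent)}

        stage = "mif"
        log.info("[mif] summarization, batch normalization, phenotyping, densities")
        pheno_cfg = PhenotypeConfig(thresholds=default_thresholds())
        summarized = summarize_table(cell_table, q=pheno_cfg.quantile_q)
        normalized = combat_normalize(summarized.cells[io.MARKERS],
                                      summarized.cells["image_id"])
        cells_norm = summarized.cells.copy()
        cells_norm[io.MARKERS] = normalized
        norm_table = io.CellTable(cells=cells_norm, pixels=None)
        phen_table = phenotype_cells(norm_table, pheno_cfg)
        masks = build_tumor_mask(phen_table, config.mask)
        masks_to_geojson(masks, out / "tumor_masks.geojson")
        phen_table = assign_compartments(phen_table, masks)
        io.write_cells(phen_table, out / "cells_phenotyped.csv")
        densities = compute_densities(phen_table, masks, config.mask)
        densities.to_csv(out / "densities.tsv", sep="\t", index=False)

        cd8 = densities[(densities["phenotype"] == "CD8_T")
                        & (densities["compartment"] == "total")]
        geno = cd8["image_id"].map(genotype)
        mean_mut, mean_wt, t_cd8, p_cd8 = welch_group_compare(
            cd8["density_per_mm2"].to_numpy(), geno.to_numpy())
        report["stages"]["mif"] = {
            "n_images_with_density": int(cd8["image_id"].nunique()),
            "cd8_density_mut": mean_mut, "cd8_density_wt": mean_wt,
            "cd8_welch_p": p_cd8,
        }

        stage = "spatial"
        log.info("[spatial] Delaunay graphs, profiles, clustering, enrichment")
        graph = build_graph(phen_table)
        profiles = interaction_profile(graph)
        profiles.to_csv(out / "interaction_profiles.tsv", sep="\t")
        ccfg = ClusterConfig(k=config.cluster.k, n_init=config.cluster.n_init,
                             seed=config.seed + STAGE_SEED_OFFSETS["spatial"],
                             standardize=config.cluster.standardize)
        labels, centroids = cluster_images(profiles, ccfg)
        labels.to_csv(out / "cluster_labels.tsv", sep="\t")
        immune_clusters = config.immune_clusters
        if immune_clusters == "auto":
            immune_clusters = _immune_enriched_clusters(profiles, labels)
        enrich = cluster_enrichment(labels, genotype, immune_clusters)
        io.write_json({"collapsed": enrich["collapsed"],
                       "fisher_p": enrich["fisher_p"],
                       "frac_in_group": enrich["frac_in_group"]},
                      out / "cluster_enrichment.json")
        report["stages"]["spatial"] = {
            "cluster_sizes": labels.value_counts().sort_index().to_dict(),
            "immune_clusters": [int(c) for c in immune_clusters],
            "fisher_p": enrich["fisher_p"],
        }

        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "failed"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        io.write_json(report, out / "report.json")
        raise
    validate_report(report)
    io.write_json(report, out / "report.json")
    return report


def _immune_enriched_clusters(profiles: pd.DataFrame, labels: pd.Series,
                              n_top: int = 2) -> list[int]:
    """The clusters with the strongest mean immune-immune interactions.

    Mirrors how the immune-enriched interaction patterns are recognized:
    by homotypic/heterotypic interactions among CD8 T cells, macrophages
    and Tregs, averaged over each cluster's raw score profile.
    """
    immune = ["CD8_T", "macrophage", "Treg"]
    cols = [f"{a}->{b}" for a in immune for b in immune]
    means = profiles[cols].fillna(0.0).groupby(labels).mean().mean(axis=1)
    return sorted(int(c) for c in means.nlargest(n_top).index)


# ---------------------------------------------------------------------------
# minimal structural validation against the shipped schema
# ---------------------------------------------------------------------------

def _load_schema() -> dict:
    ref = resources.files("wntomics").joinpath("run_report.schema.json")
    return json.loads(ref.read_text(encoding="utf-8"))


_TYPES = {"object": dict, "string": str, "integer": (int, np.integer),
          "number": (int, float, np.integer, np.floating)}


def validate_report(report: dict) -> None:
    """Check the report against the shipped JSON schema (required keys/types)."""
    schema = _load_schema()
    _check(report, schema, "report")


def _check(obj, schema, path):
    expected = _TYPES.get(schema.get("type"))
    if expected is not None and not isinstance(obj, expected):
        raise ValueError(f"{path}: expected {schema['type']}, got {type(obj).__name__}")
    for key in schema.get("required", []):
        if key not in obj:
            raise ValueError(f"{path}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in obj:
            _check(obj[key], sub, f"{path}.{key}")
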