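"""End-to-end pipeline: filter -> rarefy -> alpha -> beta -> tests -> niche.

Given an OTU table, sample metadata and (optionally) a taxonomy table,
:func:`run_pipeline` applies the standard preprocessing (global-singleton
removal, chloroplast removal, shallow-sample exclusion, rarefaction),
computes per-sample alpha diversity, pairwise Bray-Curtis and Jaccard
dissimilarities, per-group turnover/nestedness partitions, ANOSIM and
one-way PERMANOVA of site structure within each compartment, a 2-D nMDS
of the Jaccard distances, the Levins niche-breadth classification with
abundant specialists, and compartment-level shared-OTU counts.  Every
stage's result is written as TSV/JSON into the output directory together
with a manifest recording versions, seeds and thresholds, so a run is
reproducible bit for bit from its manifest.
"""
from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import alpha_table, group_summary
from .beta import multisite_partition, pairwise_dissimilarity, partition_by_group
from .filters import drop_shallow_samples, filter_global_singletons, filter_taxa_by_label, rarefy
from .niche import abundant_otus, abundant_specialists, classify_niche, shared_counts_frame, shared_otu_counts
from .stats import anosim, nmds, permanova_oneway
from .table import OtuTable, SampleMetadata, TaxonomyMap, read_metadata, read_otu_table, read_taxonomy

logger = logging.getLogger("otukit")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds driving :func:`run_pipeline`."""

    otu_table: Path
    metadata: Path
    output_dir: Path
    taxonomy: Path | None = None
    rarefaction_depth: int = 7125
    keep_below_depth: bool = True
    min_reads: int = 1000
    chloroplast_label: str = "Chloroplast"
    generalist_threshold: float = 20.0
    specialist_threshold: float = 10.0
    abundance_fraction: float = 0.002
    preference_threshold: float = 0.20
    n_permutations: int = 9999
    nmds_restarts: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("otu_table", "metadata", "output_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.taxonomy is not None:
            self.taxonomy = Path(self.taxonomy)
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 0 < self.abundance_fraction < 1:
            raise ValueError("abundance_fraction must lie in (0, 1)")
        if not self.specialist_threshold < self.generalist_threshold:
            raise ValueError("specialist_threshold must be below generalist_threshold")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_jsonable(self) -> dict:
        out = asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in out.items()}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return None if math.isnan(obj) else float(obj)
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and return a name -> path map of the written artifacts."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    logger.info("stage=read: loading tables")
    table = read_otu_table(config.otu_table)
    metadata = read_metadata(config.metadata)
    metadata.for_table(table)  # fails naming any sample without metadata
    taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else None

    logger.info("stage=filter: %d OTUs x %d samples in", table.n_otus, table.n_samples)
    table = filter_global_singletons(table)
    if taxonomy is not None:
        table = filter_taxa_by_label(table, taxonomy, config.chloroplast_label)
    table = drop_shallow_samples(table, config.min_reads)
    if table.n_samples < 2:
        raise ValueError("fewer than 2 samples survive filtering; nothing to analyze")
    logger.info("stage=rarefy: depth=%d keep_below=%s", config.rarefaction_depth,
                config.keep_below_depth)
    table = rarefy(table, config.rarefaction_depth, seed=config.seed,
                   keep_below_depth=config.keep_below_depth)
    meta_frame = metadata.for_table(table)
    artifacts["analysis_table"] = out / "analysis_table.tsv"
    table.to_tsv(artifacts["analysis_table"])

    logger.info("stage=alpha")
    alpha = alpha_table(table)
    artifacts["alpha"] = out / "alpha.tsv"
    alpha.to_csv(artifacts["alpha"], sep="\t")
    artifacts["alpha_groups"] = out / "alpha_groups.tsv"
    group_summary(alpha, metadata).to_csv(artifacts["alpha_groups"], sep="\t")

    logger.info("stage=beta")
    bray = pairwise_dissimilarity(table, "bray_curtis")
    jaccard = pairwise_dissimilarity(table, "jaccard")
    artifacts["beta_bray_curtis"] = out / "beta_bray_curtis.tsv"
    bray.to_tsv(artifacts["beta_bray_curtis"])
    artifacts["beta_jaccard"] = out / "beta_jaccard.tsv"
    jaccard.to_tsv(artifacts["beta_jaccard"])
    artifacts["beta_partition"] = out / "beta_partition.tsv"
    partition_by_group(table, metadata).to_csv(artifacts["beta_partition"], sep="\t")

    logger.info("stage=tests: ANOSIM/PERMANOVA of site within each compartment")
    test_records = []
    for compartment, samples in meta_frame.groupby("compartment").groups.items():
        samples = list(samples)
        sites = meta_frame.loc[samples, "site"]
        sizes = sites.value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            logger.warning("stage=tests: skipping %s (needs >= 2 sites with >= 2 samples)",
                           compartment)
            continue
        sub = table.select_samples(samples)
        d = pairwise_dissimilarity(sub, "bray_curtis")
        a = anosim(d, sites, n_permutations=config.n_permutations, seed=config.seed)
        p = permanova_oneway(d, sites, n_permutations=config.n_permutations, seed=config.seed)
        test_records.append({
            "compartment": compartment, "grouping": "site",
            "anosim_r": a.r, "anosim_p": a.p_value,
            "permanova_f": p.pseudo_f, "permanova_p": p.p_value,
            "df_between": p.df_between, "df_within": p.df_within,
            "n_permutations": config.n_permutations, "seed": config.seed,
        })
    artifacts["community_tests"] = out / "community_tests.json"
    artifacts["community_tests"].write_text(
        json.dumps(test_records, indent=2, default=_json_default))

    logger.info("stage=nmds: Jaccard ordination")
    embedding = nmds(jaccard, n_restarts=config.nmds_restarts, seed=config.seed)
    artifacts["nmds_coordinates"] = out / "nmds_coordinates.tsv"
    embedding.coordinates.to_csv(artifacts["nmds_coordinates"], sep="\t")
    artifacts["nmds"] = out / "nmds.json"
    artifacts["nmds"].write_text(json.dumps(
        {"stress": embedding.stress, "n_restarts": embedding.n_restarts,
         "seed": embedding.seed}, indent=2))

    logger.info("stage=niche")
    classification = classify_niche(table, config.generalist_threshold,
                                    config.specialist_threshold)
    classification["is_abundant"] = classification.index.isin(
        abundant_otus(table, config.abundance_fraction))
    artifacts["niche_classification"] = out / "niche_classification.tsv"
    classification.to_csv(artifacts["niche_classification"], sep="\t")
    spec = abundant_specialists(table, metadata,
                                preference_threshold=config.preference_threshold,
                                fraction_threshold=config.abundance_fraction,
                                specialist_threshold=config.specialist_threshold,
                                generalist_threshold=config.generalist_threshold)
    spec = spec.copy()
    spec["preferred_habitats"] = spec["preferred_habitats"].map(
        lambda hits: ";".join(f"{g}={v:.4f}" for g, v in hits))
    artifacts["abundant_specialists"] = out / "abundant_specialists.tsv"
    spec.to_csv(artifacts["abundant_specialists"], sep="\t")

    logger.info("stage=shared")
    shared = shared_otu_counts(table, metadata, ("compartment",))
    artifacts["shared_otus"] = out / "shared_otus.tsv"
    shared_counts_frame(shared).to_csv(artifacts["shared_otus"], sep="\t", index=False)

    manifest = {
        "package": "otukit", "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "config": config.to_jsonable(),
        "n_otus_analyzed": table.n_otus, "n_samples_analyzed": table.n_samples,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    artifacts["manifest"] = manifest_path
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return artifacts
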