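"""End-to-end orchestration: config, stage ordering, seeds, report bundle.

The pipeline mirrors the analysis narrative of a mixed-cropping amplicon
study: simulate (or load) paired kingdom tables -> SV-level filtering and
taxonomy fill-down -> taxon profiles -> ordination + PERMANOVA ->
iterative richness -> community distances + Mantel -> rarefaction,
genus agglomeration and cross-kingdom merge -> per-group Spearman
co-occurrence with tiered counts and networks.

Every stochastic stage draws a child seed deterministically from the
master seed and the stage name, so re-running a config is byte-identical
and single stages can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .containers import CountTable, SampleMetadata, SVAttributes, TaxonomyTable
from .feature_table import (
    agglomerate,
    fill_taxonomy,
    filter_features,
    merge_kingdoms,
    rarefy,
    taxon_profiles,
)
from .inference import mantel, nmds, permanova
from .metrics import distance_matrix, iterative_richness
from .network import (
    build_network,
    network_summary_stats,
    spearman_cooccurrence,
    summary_table,
    tiered_interaction_counts,
)
from .simulate import SVExpansion, SyntheticScenario, PlantedBlock, expand_to_sv_level, simulate_experiment

STAGES = (
    "simulate",
    "preprocess",
    "profiles",
    "ordination",
    "richness",
    "distances",
    "cooccurrence",
)


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every problem found."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; unstated analysis choices are explicit
    fields so the run log records them."""

    scenario: SyntheticScenario | None = None
    # Alternatively, paths to real inputs (per kingdom).
    counts_paths: dict[str, str] = field(default_factory=dict)
    taxonomy_paths: dict[str, str] = field(default_factory=dict)
    attrs_paths: dict[str, str] = field(default_factory=dict)
    metadata_path: str | None = None

    # SV filter settings (bacterial length window; fungi unfiltered by length).
    length_window: dict[str, tuple[int, int] | None] = field(
        default_factory=lambda: {"bacteria": (240, 260), "fungi": None}
    )
    drop_control: bool = True
    min_total_reads: int = 100
    control_first: bool = True

    # Diversity / distance settings.
    richness_trials: int = 100
    metrics: tuple[str, ...] = ("bray_curtis", "jsd", "jaccard_binary")
    mantel_metrics: tuple[str, ...] = ("jsd", "jaccard_binary")
    jaccard_binary: bool = True

    # Inference settings.
    n_permutations: int = 999
    nmds_k: int = 2
    nmds_restarts: int = 20

    # Co-occurrence settings.
    alpha: float = 0.05
    moderate_threshold: float = 0.5
    strong_threshold: float = 0.75
    benjamini_hochberg: bool = False

    profile_rank_top: str = "Family"
    profile_top_n: int = 10
    profile_min_combined: float = 0.01

    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        errors: list[str] = []
        if self.scenario is None:
            for kingdom in ("bacteria", "fungi"):
                if kingdom not in self.counts_paths:
                    errors.append(f"no scenario and no counts path for {kingdom}")
                elif not Path(self.counts_paths[kingdom]).exists():
                    errors.append(f"counts path missing: {self.counts_paths[kingdom]}")
            if self.metadata_path is None:
                errors.append("no scenario and no metadata path")
            elif not Path(self.metadata_path).exists():
                errors.append(f"metadata path missing: {self.metadata_path}")
        if not 0 < self.alpha < 1:
            errors.append(f"alpha {self.alpha} outside (0, 1)")
        if not 0 < self.moderate_threshold < self.strong_threshold < 1:
            errors.append(
                f"need 0 < moderate ({self.moderate_threshold}) < "
                f"strong ({self.strong_threshold}) < 1"
            )
        unknown = [m for m in self.metrics if m not in ("bray_curtis", "jsd", "jaccard_binary", "jaccard_quant")]
        if unknown:
            errors.append(f"unknown metrics: {unknown}")
        if self.n_permutations < 1:
            errors.append("n_permutations must be >= 1")
        if self.richness_trials < 1:
            errors.append("richness_trials must be >= 1")
        if self.scenario is not None:
            try:
                self.scenario.validate()
            except ValueError as exc:
                errors.append(str(exc))
        if errors:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))

    def stage_seed(self, stage: str) -> int:
        """Deterministic child seed: master seed mixed with the stage name."""
        return int((self.seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = None
        if "scenario" in raw:
            sc = dict(raw.pop("scenario") or {})
            if "planted_blocks" in sc:
                sc["planted_blocks"] = [
                    PlantedBlock(tuple(b["members"]), float(b["r"]), tuple(b["groups"]))
                    for b in sc["planted_blocks"]
                ]
            if "sv_expansion" in sc:
                sc["sv_expansion"] = SVExpansion(**sc["sv_expansion"])
            if "depth_range" in sc:
                sc["depth_range"] = {k: tuple(v) for k, v in sc["depth_range"].items()}
            scenario = SyntheticScenario(**sc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = [k for k in raw if k not in known]
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        for key in ("metrics", "mantel_metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "length_window" in raw:
            raw["length_window"] = {
                k: (tuple(v) if v is not None else None)
                for k, v in raw["length_window"].items()
            }
        return cls(scenario=scenario, **raw)


@dataclass
class ReportBundle:
    """In-memory results of a full run plus the run log."""

    tables: dict = field(default_factory=dict)          # kingdom -> CountTable (filtered)
    taxonomy: dict = field(default_factory=dict)        # kingdom -> TaxonomyTable
    metadata: SampleMetadata | None = None
    truth: object | None = None
    filter_reports: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)        # (kingdom, rank) -> DataFrame
    ordinations: dict = field(default_factory=dict)     # kingdom -> Ordination
    permanova_results: dict = field(default_factory=dict)
    richness: dict = field(default_factory=dict)        # kingdom -> RichnessEstimate
    distances: dict = field(default_factory=dict)       # (kingdom, metric) -> DistanceMatrix
    mantel_results: dict = field(default_factory=dict)  # metric -> MantelResult
    merged: CountTable | None = None
    kingdom_map: dict = field(default_factory=dict)
    cooccurrence: dict = field(default_factory=dict)    # group -> CooccurrenceResult
    summaries: list = field(default_factory=list)       # NetworkSummary per group
    networks: dict = field(default_factory=dict)        # group -> nx.Graph
    network_stats: dict = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return summary_table(self.summaries)


def _write_outputs(bundle: ReportBundle, outdir: Path, stage: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "simulate":
        for kingdom, table in bundle.tables.items():
            rio.write_count_table(table, outdir / f"counts_{kingdom}_raw.tsv")
        if bundle.metadata is not None:
            rio.write_metadata(bundle.metadata, outdir / "metadata.tsv")
        if bundle.truth is not None and bundle.truth.correlated_pairs:
            pd.DataFrame(
                [
                    {"feature_a": a, "feature_b": b, "sign": s, "groups": ";".join(sorted(g))}
                    for a, b, s, g in bundle.truth.correlated_pairs
                ]
            ).to_csv(outdir / "planted_truth.tsv", sep="\t", index=False)
    elif stage == "preprocess":
        for kingdom, table in bundle.tables.items():
            rio.write_count_table(table, outdir / f"counts_{kingdom}_filtered.tsv")
            rio.write_taxonomy(bundle.taxonomy[kingdom], outdir / f"taxonomy_{kingdom}.tsv")
        for kingdom, report in bundle.filter_reports.items():
            report.to_frame().to_csv(outdir / f"filter_report_{kingdom}.tsv", sep="\t", index=False)
    elif stage == "profiles":
        for (kingdom, rank), profile in bundle.profiles.items():
            profile.to_csv(outdir / f"profile_{kingdom}_{rank.lower()}.tsv", sep="\t")
    elif stage == "ordination":
        for kingdom, ordination in bundle.ordinations.items():
            pd.DataFrame(
                ordination.coordinates,
                index=ordination.sample_ids,
                columns=[f"NMDS{i + 1}" for i in range(ordination.coordinates.shape[1])],
            ).to_csv(outdir / f"nmds_{kingdom}.tsv", sep="\t")
        records = {
            kingdom: dataclasses.asdict(res)
            for kingdom, res in bundle.permanova_results.items()
        }
        (outdir / "permanova.json").write_text(json.dumps(records, indent=2))
    elif stage == "richness":
        for kingdom, estimate in bundle.richness.items():
            estimate.to_frame().to_csv(outdir / f"richness_{kingdom}.tsv", sep="\t")
    elif stage == "distances":
        for (kingdom, metric), dm in bundle.distances.items():
            rio.write_distance_matrix(dm, outdir / f"distance_{kingdom}_{metric}.tsv")
        records = {m: dataclasses.asdict(r) for m, r in bundle.mantel_results.items()}
        (outdir / "mantel.json").write_text(json.dumps(records, indent=2))
    elif stage == "cooccurrence":
        for group, result in bundle.cooccurrence.items():
            result.edge_frame().to_csv(outdir / f"edges_{group}.tsv", sep="\t", index=False)
        for group, net in bundle.networks.items():
            nx.write_graphml(net, outdir / f"network_{group}.graphml")
        bundle.summary_frame().to_csv(outdir / "interaction_summary.tsv", sep="\t", index=False)
        (outdir / "network_stats.json").write_text(json.dumps(bundle.network_stats, indent=2))


def run_pipeline(config: PipelineConfig, upto: str = "cooccurrence") -> ReportBundle:
    """Execute the pipeline through stage ``upto`` (inclusive).

    Stage failures abort with the stage name; outputs of earlier stages
    remain on disk.
    """
    config.validate()
    if upto not in STAGES:
        raise ConfigError(f"unknown stage {upto!r}; expected one of {STAGES}")
    last = STAGES.index(upto)
    outdir = Path(config.outdir) if config.outdir else None
    bundle = ReportBundle()
    log = bundle.run_log
    log["seed"] = config.seed
    log["stages"] = []
    log["decisions"] = {
        "min_total_reads": config.min_total_reads,
        "length_window": {k: list(v) if v else None for k, v in config.length_window.items()},
        "control_removal_first": config.control_first,
        "jaccard_variant": "binary" if config.jaccard_binary else "quantitative",
        "mantel_correlation": "pearson",
        "spearman_p": "t-approximation (df = n - 2)",
        "multiple_testing": "benjamini-hochberg" if config.benjamini_hochberg else "none",
        "n_permutations": config.n_permutations,
    }

    def run_stage(name: str, fn) -> None:
        if STAGES.index(name) > last:
            return
        try:
            fn()
        except Exception as exc:  # propagate with stage context
            raise PipelineStageError(name, exc) from exc
        log["stages"].append({"stage": name, "seed": config.stage_seed(name), "status": "done"})
        if outdir is not None:
            _write_outputs(bundle, outdir, name)

    genus_truth_tax: dict = {}

    def stage_simulate() -> None:
        if config.scenario is not None:
            scenario = dataclasses.replace(config.scenario, seed=config.stage_seed("simulate"))
            bacteria, fungi, taxonomy, metadata, truth = simulate_experiment(scenario)
            genus_truth_tax["scenario"] = scenario
            genus_truth_tax["taxonomy"] = taxonomy
            bundle.tables = {"bacteria": bacteria, "fungi": fungi}
            bundle.metadata = metadata
            bundle.truth = truth
        else:
            bundle.tables = {
                k: rio.read_count_table(p) for k, p in config.counts_paths.items()
            }
            bundle.taxonomy = {
                k: rio.read_taxonomy(p) for k, p in config.taxonomy_paths.items()
            }
            bundle.metadata = rio.read_metadata(config.metadata_path)

    def stage_preprocess() -> None:
        seed = config.stage_seed("preprocess")
        for kingdom in ("bacteria", "fungi"):
            table = bundle.tables[kingdom]
            if config.scenario is not None:
                scenario = genus_truth_tax["scenario"]
                sv_table, attrs, sv_tax = expand_to_sv_level(
                    table, scenario, taxonomy=genus_truth_tax["taxonomy"],
                    seed=(seed + (0 if kingdom == "bacteria" else 1)) % (2 ** 31),
                )
            else:
                sv_table = table
                attrs = (
                    rio.read_sv_attributes(config.attrs_paths[kingdom])
                    if kingdom in config.attrs_paths
                    else None
                )
                sv_tax = bundle.taxonomy[kingdom]
            filtered, report = filter_features(
                sv_table,
                attrs=attrs,
                length_window=config.length_window.get(kingdom),
                drop_control=config.drop_control and attrs is not None,
                min_total_reads=config.min_total_reads,
                control_first=config.control_first,
            )
            tax = fill_taxonomy(
                TaxonomyTable(sv_tax.data.loc[filtered.feature_ids])
            )
            bundle.tables[kingdom] = filtered
            bundle.taxonomy[kingdom] = tax
            bundle.filter_reports[kingdom] = report

    def root_samples(table: CountTable) -> list[str]:
        meta = bundle.metadata.data
        return [s for s in table.sample_ids if meta.loc[s, "sample_type"] == "root"]

    def stage_profiles() -> None:
        for kingdom in ("bacteria", "fungi"):
            table = bundle.tables[kingdom]
            table = table.select_samples(root_samples(table))
            tax = bundle.taxonomy[kingdom]
            bundle.profiles[(kingdom, config.profile_rank_top)] = taxon_profiles(
                table, tax, bundle.metadata, config.profile_rank_top, top_n=config.profile_top_n
            )
            bundle.profiles[(kingdom, "Genus")] = taxon_profiles(
                table, tax, bundle.metadata, "Genus",
                min_combined_relabund=config.profile_min_combined,
            )

    def stage_ordination() -> None:
        seed = config.stage_seed("ordination")
        for kingdom in ("bacteria", "fungi"):
            table = bundle.tables[kingdom]
            table = table.select_samples(root_samples(table))
            dm = distance_matrix(table, "bray_curtis")
            bundle.distances[(kingdom, "bray_curtis")] = dm
            bundle.ordinations[kingdom] = nmds(
                dm, k=config.nmds_k, n_restarts=config.nmds_restarts, seed=seed
            )
            groups = bundle.metadata.data.loc[dm.ids, "group"]
            bundle.permanova_results[kingdom] = permanova(
                dm, groups, n_permutations=config.n_permutations, seed=seed
            )

    def stage_richness() -> None:
        seed = config.stage_seed("richness")
        for kingdom in ("bacteria", "fungi"):
            table = bundle.tables[kingdom]
            bundle.richness[kingdom] = iterative_richness(
                table, n_trials=config.richness_trials, seed=seed
            )

    def stage_distances() -> None:
        for kingdom in ("bacteria", "fungi"):
            table = bundle.tables[kingdom]
            table = table.select_samples(root_samples(table))
            for metric in config.metrics:
                if (kingdom, metric) not in bundle.distances:
                    bundle.distances[(kingdom, metric)] = distance_matrix(table, metric)
        seed = config.stage_seed("distances")
        runnable = [m for m in config.mantel_metrics if m in config.metrics]
        skipped = [m for m in config.mantel_metrics if m not in config.metrics]
        for metric in runnable:
            bundle.mantel_results[metric] = mantel(
                bundle.distances[("bacteria", metric)],
                bundle.distances[("fungi", metric)],
                n_permutations=config.n_permutations,
                seed=seed,
            )
        if skipped or not runnable:
            log.setdefault("skipped", []).append(
                {
                    "stage": "distances",
                    "what": "mantel",
                    "metrics": skipped,
                    "reason": "distance matrices for these metrics were not computed",
                }
            )

    def stage_cooccurrence() -> None:
        seed = config.stage_seed("cooccurrence")
        rarefied = {}
        for kingdom in ("bacteria", "fungi"):
            table = bundle.tables[kingdom]
            table = table.select_samples(root_samples(table))
            depth = int(table.sample_totals().min())
            rarefied_table, rep = rarefy(table, depth, seed=seed)
            log.setdefault("rarefaction", {})[kingdom] = {
                "depth": depth,
                "dropped_samples": rep.dropped_samples,
            }
            if rarefied_table.axis_rank != "genus":
                rarefied_table = agglomerate(rarefied_table, bundle.taxonomy[kingdom], "Genus")
            rarefied[kingdom] = rarefied_table
        merged, kingdom_map = merge_kingdoms(rarefied["bacteria"], rarefied["fungi"])
        bundle.merged, bundle.kingdom_map = merged, kingdom_map
        for group, samples in bundle.metadata.root_groups().items():
            samples = [s for s in samples if s in merged.sample_ids]
            result = spearman_cooccurrence(merged, kingdom_map, samples, group=group)
            bundle.cooccurrence[group] = result
            summary = tiered_interaction_counts(
                result,
                alpha=config.alpha,
                moderate_threshold=config.moderate_threshold,
                strong_threshold=config.strong_threshold,
                adjust_benjamini_hochberg=config.benjamini_hochberg,
            )
            bundle.summaries.append(summary)
            net = build_network(result, alpha=config.alpha, rho_threshold=config.strong_threshold)
            bundle.networks[group] = net
            bundle.network_stats[group] = network_summary_stats(net)

    run_stage("simulate", stage_simulate)
    run_stage("preprocess", stage_preprocess)
    run_stage("profiles", stage_profiles)
    run_stage("ordination", stage_ordination)
    run_stage("richness", stage_richness)
    run_stage("distances", stage_distances)
    run_stage("cooccurrence", stage_cooccurrence)

    if outdir is not None:
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return bundle
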