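"""End-to-end orchestration: one config, all stages, a run manifest.

``run_pipeline`` chains the stages (simulate-or-read inputs →
preprocess → cluster → enrich → idstats → mods), writes every stage
output as TSV/JSON/Newick under the output directory and records a
manifest with parameter values, seed and per-stage row counts.
Re-running with the same config and inputs reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import clustering, design_io, enrichment, id_stats, mod_artifacts, preprocess
from . import synthetic_data

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: Mapping[str, Any], context: str):
    """Build a dataclass from a mapping, rejecting unknown keys.

    YAML has no tuple type; list values are coerced to tuples where the
    field default is a tuple, so reloaded configs compare equal.
    """
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list) and isinstance(known[key].default, tuple):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


@dataclass
class InputPaths:
    design: str | None = None
    protein_groups: str | None = None
    peptides: str | None = None
    mod_summary: str | None = None
    annotations: str | None = None
    id_counts: str | None = None
    bridge_counts: str | None = None


@dataclass
class StepToggles:
    preprocess: bool = True
    cluster: bool = True
    enrich: bool = True
    idstats: bool = True
    mods: bool = True


@dataclass
class PreprocessParams:
    min_razor_unique: int = 2
    min_valid: int = 3
    irt_patterns: tuple[str, ...] = preprocess.DEFAULT_IRT_PATTERNS
    min_reps: int = 2
    tolerance_fold: float = 2.0


@dataclass
class ClusterParams:
    k_min: int = 2
    k_max: int = 15
    restarts: int = 25
    k_override: int | None = None
    level: str = "method"  # or "sample"


@dataclass
class EnrichParams:
    alpha: float = 0.05
    strong_threshold: float = 2.0
    bh_correction: bool = False
    drop_unannotated: bool = False


@dataclass
class IdStatsParams:
    responses: tuple[str, ...] = id_stats.COUNT_COLUMNS
    anova_type: str = "I"
    bridge_group_a: str = "SDC-A"
    bridge_group_b: str = "EasyPep"


@dataclass
class ModParams:
    min_percent: float = 0.05
    fold: float = 2.0


@dataclass
class PipelineConfig:
    out_dir: str = "prepmatrix_out"
    seed: int = 0
    inputs: InputPaths = field(default_factory=InputPaths)
    steps: StepToggles = field(default_factory=StepToggles)
    simulate: dict = field(default_factory=dict)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    idstats: IdStatsParams = field(default_factory=IdStatsParams)
    mods: ModParams = field(default_factory=ModParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "inputs": InputPaths,
    "steps": StepToggles,
    "preprocess": PreprocessParams,
    "cluster": ClusterParams,
    "enrich": EnrichParams,
    "idstats": IdStatsParams,
    "mods": ModParams,
}


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    data = dict(data or {})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _from_mapping(_SECTIONS[key], value or {}, key)
        else:
            kwargs[key] = value
    if "simulate" in kwargs and kwargs["simulate"]:
        sim_known = {f.name for f in fields(synthetic_data.SimulationConfig)}
        bad = set(kwargs["simulate"]) - sim_known
        if bad:
            raise ConfigError(f"unknown key(s) in simulate: {sorted(bad)}")
    return PipelineConfig(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = config_from_dict(data or {})
    for f in fields(InputPaths):
        p = getattr(cfg.inputs, f.name)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"input path does not exist: {f.name} = {p}")
    return cfg


def _sim_config(cfg: PipelineConfig) -> synthetic_data.SimulationConfig:
    over = dict(cfg.simulate)
    over.setdefault("seed", cfg.seed)
    if "features" in over:
        over["features"] = tuple(
            synthetic_data.FeatureSpec(**f) if isinstance(f, Mapping) else f
            for f in over["features"]
        )
    return synthetic_data.SimulationConfig(**over)


def simulate_inputs(config: synthetic_data.SimulationConfig, out_dir: str | Path) -> dict:
    """Emit all synthetic input tables plus the ground truth as files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, design, truth = synthetic_data.simulate_protein_groups(config)
    annotation = synthetic_data.simulate_annotations(config, truth)
    counts, bridge = synthetic_data.simulate_id_counts(config)
    peptides = synthetic_data.simulate_peptides(config)
    mods = synthetic_data.simulate_mod_summary(config)

    design_io.write_design(design, out / "design.tsv")
    design_io.write_protein_groups(table, out / "proteinGroups.txt")
    design_io.write_peptides(peptides, out / "peptides.txt")
    design_io.write_mod_summary(mods, out / "global.modsummary.tsv")
    design_io.write_annotations(annotation, out / "annotations.tsv")
    counts.to_csv(out / "id_counts.tsv", sep="\t", index=False)
    bridge.to_csv(out / "bridge_counts.tsv", sep="\t", index=False)
    truth_dict = {
        "cluster_sizes": truth.cluster_labels.value_counts().sort_index().to_dict(),
        "effect_matrix": truth.effect_matrix.to_dict(),
        "features": [dataclasses.asdict(f) for f in truth.features],
        "id_means": truth.id_means,
        "batch_offsets": list(truth.batch_offsets),
        "bridge_shift": truth.bridge_shift,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(truth_dict, indent=2, sort_keys=True)
    )
    truth.cluster_labels.to_csv(out / "true_clusters.tsv", sep="\t")
    return {
        "design": str(out / "design.tsv"),
        "protein_groups": str(out / "proteinGroups.txt"),
        "peptides": str(out / "peptides.txt"),
        "mod_summary": str(out / "global.modsummary.tsv"),
        "annotations": str(out / "annotations.tsv"),
        "id_counts": str(out / "id_counts.tsv"),
        "bridge_counts": str(out / "bridge_counts.tsv"),
    }


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all enabled stages; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }

    inputs = dataclasses.asdict(cfg.inputs)
    if inputs["design"] is None:
        sim_cfg = _sim_config(cfg)
        inputs = simulate_inputs(sim_cfg, out / "simulated")
        manifest["stages"]["simulate"] = {
            "n_proteins": sim_cfg.n_proteins,
            "seed": sim_cfg.seed,
            "out": str(out / "simulated"),
        }

    design = design_io.read_design(inputs["design"])
    table = design_io.read_protein_groups(inputs["protein_groups"], design)
    peptides = (
        design_io.read_peptides(inputs["peptides"], design)
        if inputs.get("peptides")
        else None
    )

    matrix = None
    if cfg.steps.preprocess:
        matrix = _stage_preprocess(cfg, table, design, out, manifest)
    if cfg.steps.cluster:
        if matrix is None:
            raise ConfigError("cluster stage requires the preprocess stage")
        model = _stage_cluster(cfg, matrix, design, out, manifest)
    else:
        model = None
    if cfg.steps.enrich:
        if model is None:
            raise ConfigError("enrich stage requires the cluster stage")
        if not inputs.get("annotations"):
            raise ConfigError("enrich stage requires an annotations input")
        annotation = design_io.read_annotations(inputs["annotations"])
        _stage_enrich(cfg, model, annotation, out, manifest)
    if cfg.steps.idstats:
        _stage_idstats(cfg, table, peptides, design, inputs, out, manifest)
    if cfg.steps.mods:
        if not inputs.get("mod_summary"):
            raise ConfigError("mods stage requires a mod_summary input")
        summary = design_io.read_mod_summary(inputs["mod_summary"], design)
        _stage_mods(cfg, summary, design, out, manifest)

    for step in fields(StepToggles):
        if not getattr(cfg.steps, step.name):
            manifest["stages"][step.name] = {"skipped": True}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return out


def _stage_preprocess(cfg, table, design, out: Path, manifest) -> preprocess.LogIntensityMatrix:
    p = cfg.preprocess
    filtered = preprocess.filter_protein_groups(
        table, design, min_razor_unique=p.min_razor_unique,
        irt_patterns=p.irt_patterns,
    )
    qc = preprocess.summed_intensity_qc(filtered, design, p.tolerance_fold)
    masked = preprocess.mask_non_msms(filtered)
    matrix = preprocess.log2_transform(masked)
    matrix = preprocess.valid_value_filter(matrix, design, min_valid=p.min_valid)
    matrix = preprocess.impute_constant(matrix)

    cleared = preprocess.clear_for_overlap(table, irt_patterns=p.irt_patterns)
    report = preprocess.overlap_sets(cleared, design, min_reps=p.min_reps)

    design_io.write_protein_groups(filtered, out / "proteinGroups.filtered.txt")
    matrix.values.to_csv(out / "log2_matrix.tsv", sep="\t")
    matrix.valid.astype(int).to_csv(out / "valid_mask.tsv", sep="\t")
    qc.to_csv(out / "summed_intensity_qc.tsv", sep="\t")
    report.collections.to_csv(out / "overlap_collections.tsv", sep="\t", index=False)
    report.upset.to_csv(out / "overlap_upset.tsv", sep="\t", index=False)
    with open(out / "filter_log.jsonl", "w") as fh:
        for rec in matrix.provenance:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    manifest["stages"]["preprocess"] = {
        "n_groups_in": len(table.meta),
        "n_groups_filtered": len(filtered.meta),
        "n_proteins_matrix": len(matrix.values),
        "imputation_constant": matrix.imputation_constant,
    }
    return matrix


def _stage_cluster(cfg, matrix, design, out: Path, manifest) -> clustering.ClusterModel:
    c = cfg.cluster
    if c.level == "method":
        profiles = clustering.average_replicates(matrix, design)
    elif c.level == "sample":
        profiles = matrix.values
    else:
        raise ConfigError(f"cluster.level must be 'method' or 'sample', got {c.level!r}")
    centered = clustering.center_rows(profiles)
    sweep = clustering.sweep_kmeans(
        centered, k_range=range(c.k_min, c.k_max + 1),
        restarts=c.restarts, seed=cfg.seed,
    )
    k_sel, info = sweep.select_k(override=c.k_override)
    model = sweep.models[k_sel]
    heat, sizes = clustering.cluster_summaries(model, centered)
    dendro = clustering.cluster_dendrogram(heat)
    pca = clustering.run_pca(matrix.values.T)

    model.assignments.to_csv(out / "cluster_assignments.tsv", sep="\t")
    model.centers.to_csv(out / "cluster_centers.tsv", sep="\t")
    sweep.ssw_curve.to_csv(out / "ssw_curve.tsv", sep="\t")
    heat.to_csv(out / "cluster_heatmap.tsv", sep="\t")
    sizes.to_csv(out / "cluster_sizes.tsv", sep="\t")
    (out / "cluster_dendrogram.nwk").write_text(dendro.newick + "\n")
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pd.Series(
        pca.explained_variance_ratio,
        index=pca.scores.columns, name="variance_fraction",
    ).to_csv(out / "pca_variance.tsv", sep="\t")
    manifest["stages"]["cluster"] = {
        "k_selected": k_sel,
        "selection": {k: v for k, v in info.items() if k != "second_differences"},
        "ssw": model.ssw,
        "cluster_sizes": sizes.to_dict(),
    }
    return model


def _stage_enrich(cfg, model, annotation, out: Path, manifest) -> None:
    e = cfg.enrich
    guide = enrichment.build_guide_matrix(
        model.assignments, annotation, alpha=e.alpha,
        strong_threshold=e.strong_threshold, bh_correction=e.bh_correction,
        drop_unannotated=e.drop_unannotated,
    )
    guide.long.to_csv(out / "guide_matrix_long.tsv", sep="\t", index=False)
    guide.ef_matrix.to_csv(out / "guide_matrix_ef.tsv", sep="\t")
    manifest["stages"]["enrich"] = {
        "n_cells": len(guide.long),
        "n_significant": int(guide.long["significant"].sum()),
        "n_strong": int(guide.long["strong"].sum()),
    }


def _stage_idstats(cfg, table, peptides, design, inputs, out: Path, manifest) -> None:
    i = cfg.idstats
    if inputs.get("id_counts"):
        counts = pd.read_csv(inputs["id_counts"], sep="\t")
    else:
        counts = id_stats.count_ids(table, peptides, design)
    counts.to_csv(out / "id_counts.tsv", sep="\t", index=False)

    if peptides is not None:
        mc = id_stats.missed_cleavage_profile(peptides, design)
        mc.to_csv(out / "missed_cleavage_profile.tsv", sep="\t", index=False)

    bridged_info = None
    if inputs.get("bridge_counts"):
        bridge = pd.read_csv(inputs["bridge_counts"], sep="\t")
        result = id_stats.bridge_batches(
            counts, bridge, group_a=i.bridge_group_a, group_b=i.bridge_group_b,
        )
        counts = result.counts
        counts.to_csv(out / "id_counts.bridged.tsv", sep="\t", index=False)
        bridged_info = {"change_factor": dict(result.change_factor)}

    fits = {}
    for response in i.responses:
        fit = id_stats.fit_id_model(counts, response=response,
                                    anova_type=i.anova_type)
        stem = out / f"model_{response}"
        pd.DataFrame({"estimate": fit.params, "std_err": fit.bse}).to_csv(
            f"{stem}.coefficients.tsv", sep="\t"
        )
        fit.anova.to_csv(f"{stem}.anova.tsv", sep="\t", index=False)
        fit.level_predictions.to_csv(f"{stem}.predictions.tsv", sep="\t", index=False)
        fits[response] = {
            "df_resid": fit.df_resid,
            "anova_p": {
                t: (None if pd.isna(p) else p)
                for t, p in zip(fit.anova["term"], fit.anova["p"])
            },
        }
    manifest["stages"]["idstats"] = {
        "n_samples": len(counts),
        "bridged": bridged_info,
        "models": fits,
    }


def _stage_mods(cfg, summary, design, out: Path, manifest) -> None:
    profile = mod_artifacts.summarize_mods(summary, design)
    flags = mod_artifacts.flag_method_specific(
        profile, min_percent=cfg.mods.min_percent, fold=cfg.mods.fold
    )
    profile.percent.to_csv(out / "mod_percent_matrix.tsv", sep="\t")
    long = profile.percent.reset_index().melt(
        id_vars="mod_label", var_name="method", value_name="percent"
    )
    long.to_csv(out / "mod_percent_long.tsv", sep="\t", index=False)
    flags.to_csv(out / "mod_flags.tsv", sep="\t")
    manifest["stages"]["mods"] = {
        "n_modifications": len(profile.percent),
        "n_flagged": int(flags["method_specific"].sum()),
    }
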