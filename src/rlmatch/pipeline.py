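"""End-to-end orchestration: quantify -> annotate -> select -> recommend.

A single declarative config (YAML or JSON, validated by a published
pydantic schema) drives the run. Every stage writes its outputs to
``out_dir`` in plain-text formats, and each later stage reads only the
on-disk artifacts of earlier ones, so a run is restartable from any
stage. The JSON run report records every parameter actually used, the
seed, versions, and the funnel counts.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .annotation import run_funnel
from .io import (
    AnnotationSet,
    DataError,
    LigandKBEntry,
    QuantMatrix,
    default_ligand_kb,
    read_annotation_set,
    read_annotations,
    read_ligand_kb,
    read_quant_table,
    write_annotations,
    write_ligand_kb,
    write_quant_table,
    write_report,
)
from .quant import (
    DetectionClass,
    DifferentialRecord,
    differential,
    differential_frame,
    marker_panel_summary,
    normalize_ibaq,
    volcano_table,
)
from .rlm import (
    RLMParams,
    compare_supplement_sets,
    match_ligands,
    recommendation_markdown,
    select_enriched_receptors,
)
from .simulate import SyntheticConfig, generate, study_like_config

logger = logging.getLogger("rlmatch")

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "stage_simulate",
    "stage_quantify",
    "stage_annotate",
    "stage_select",
    "stage_recommend",
]


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration (CLI exit code 2)."""


class InputsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    quant: str
    meta: str
    dialect: Literal["generic_tsv", "proteome_discoverer_export"] = "generic_tsv"
    annotations: str | None = None  # UniProt-style export
    annotation_set: str | None = None  # pre-derived flag table
    annotation_source_version: str = "unversioned"
    ligand_kb: str = "packaged"


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    study_like: bool = True
    generator: dict | None = None  # raw SyntheticConfig fields when study_like=False


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_batches: int = 1
    floor_quantile: float = 0.0
    floor_factor: float = 0.5
    test: Literal["student", "welch", "mannwhitney"] = "student"
    adjust: Literal["none", "bh"] = "none"
    fold_threshold: float = Field(default=10.0, gt=0)
    require_quantifiable_in_B: bool = True
    require_ligand_available: bool = False
    conventional_supplements: list[str] = Field(default_factory=lambda: ["BDNF", "NT3"])


class PipelineConfig(BaseModel):
    """Published schema of the pipeline configuration file."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 0
    inputs: InputsConfig | None = None
    simulate: SimulateConfig | None = None
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    formats: list[Literal["tsv", "json"]] = Field(default_factory=lambda: ["tsv", "json"])

    def rlm_params(self) -> RLMParams:
        return RLMParams(
            fold_threshold=self.params.fold_threshold,
            require_quantifiable_in_B=self.params.require_quantifiable_in_B,
            require_ligand_available=self.params.require_ligand_available,
        )


def load_config(path: str | Path, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML/JSON config; flag overrides win over file keys."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    if overrides:
        raw = _deep_merge(raw, overrides)
    try:
        cfg = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        fields = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid config: {fields}") from exc
    if (cfg.inputs is None) == (cfg.simulate is None):
        raise ConfigError("config must define exactly one of 'inputs' or 'simulate'")
    return cfg


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if v is None:
            continue
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# stages (each reads only on-disk artifacts of earlier stages)
# ---------------------------------------------------------------------------

def _artifact(cfg: PipelineConfig, name: str) -> Path:
    return Path(cfg.out_dir) / name


def stage_simulate(cfg: PipelineConfig) -> None:
    """Emit synthetic quant/meta/annotation/KB/truth artifacts to out_dir."""
    if cfg.simulate is None:
        raise ConfigError("stage 'simulate' requires a 'simulate' config block")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate.study_like:
        gen_cfg = study_like_config(cfg.seed)
        qm, ann, _, truth = generate(gen_cfg)
        kb = default_ligand_kb()
    else:
        if cfg.simulate.generator is None:
            raise ConfigError("simulate.generator required when study_like=false")
        try:
            gen_cfg = SyntheticConfig.model_validate(
                {**cfg.simulate.generator, "seed": cfg.seed}
            )
        except ValidationError as exc:
            raise ConfigError(f"invalid simulate.generator: {exc}") from exc
        qm, ann, kb, truth = generate(gen_cfg)
    write_quant_table(qm, out / "quant.tsv", out / "samples.tsv")
    write_annotations(ann, out / "annotation_set.tsv")
    write_ligand_kb(kb, out / "ligand_kb.tsv")
    truth.to_frame(qm.accessions).to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "generator_config.json").write_text(
        gen_cfg.model_dump_json(indent=2) + "\n"
    )


def _load_inputs(cfg: PipelineConfig) -> tuple[QuantMatrix, AnnotationSet, list[LigandKBEntry], str]:
    """Resolve the quant matrix, annotations and KB from config or simulate stage."""
    if cfg.inputs is not None:
        inp = cfg.inputs
        qm = read_quant_table(inp.quant, inp.meta, dialect=inp.dialect)
        if inp.annotation_set:
            ann = read_annotation_set(
                inp.annotation_set, source_version=inp.annotation_source_version
            )
        elif inp.annotations:
            ann = read_annotations(
                inp.annotations, source_version=inp.annotation_source_version
            )
        else:
            raise ConfigError("inputs must set 'annotations' or 'annotation_set'")
        kb = default_ligand_kb() if inp.ligand_kb == "packaged" else read_ligand_kb(inp.ligand_kb)
        return qm, ann, kb, inp.ligand_kb
    # simulated runs read the artifacts stage_simulate wrote
    out = Path(cfg.out_dir)
    for name in ("quant.tsv", "samples.tsv", "annotation_set.tsv", "ligand_kb.tsv"):
        if not (out / name).exists():
            raise DataError(
                f"missing artifact {name} in {out}; run the simulate stage first"
            )
    qm = read_quant_table(out / "quant.tsv", out / "samples.tsv")
    ann = read_annotation_set(
        out / "annotation_set.tsv", source_version=f"synthetic-seed{cfg.seed}"
    )
    kb = read_ligand_kb(out / "ligand_kb.tsv")
    return qm, ann, kb, "simulated"


def stage_quantify(cfg: PipelineConfig) -> list[DifferentialRecord]:
    """Normalize, flag detection and compute the differential table."""
    qm, _, _, _ = _load_inputs(cfg)
    qm_norm = normalize_ibaq(qm)
    records = differential(
        qm_norm,
        floor_quantile=cfg.params.floor_quantile,
        floor_factor=cfg.params.floor_factor,
        test=cfg.params.test,
        min_batches=cfg.params.min_batches,
        adjust=cfg.params.adjust,
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    differential_frame(records).to_csv(out / "differential.tsv", sep="\t", index=False)
    volcano_table(records).to_csv(out / "volcano.tsv", sep="\t", index=False)
    summary, calls, unresolved = marker_panel_summary(
        qm_norm,
        floor_quantile=cfg.params.floor_quantile,
        floor_factor=cfg.params.floor_factor,
    )
    summary.to_csv(out / "marker_panels.tsv", sep="\t", index=False)
    (out / "marker_panel_calls.json").write_text(
        json.dumps({"calls": calls, "unresolved": unresolved}, indent=2, sort_keys=True)
        + "\n"
    )
    return records


def _read_differential(path: Path, produced_by: str = "quantify") -> list[DifferentialRecord]:
    if not path.exists():
        raise DataError(
            f"missing artifact {path.name}; run the {produced_by} stage first"
        )
    df = pd.read_csv(path, sep="\t")
    return [
        DifferentialRecord(
            accession=str(r.accession),
            gene_symbol=str(r.gene_symbol),
            mean_norm_intensity_A=float(r.mean_norm_intensity_A),
            mean_norm_intensity_B=float(r.mean_norm_intensity_B),
            ratio_B_over_A=float(r.ratio_B_over_A),
            log2_ratio=float(r.log2_ratio),
            p_value=float(r.p_value),
            n_detected_A=int(r.n_detected_A),
            n_detected_B=int(r.n_detected_B),
            detection_class=DetectionClass(r.detection_class),
        )
        for r in df.itertuples()
    ]


def stage_annotate(cfg: PipelineConfig) -> dict:
    """Membrane filter + receptor classification of the differential table."""
    _, ann, _, _ = _load_inputs(cfg)
    records = _read_differential(_artifact(cfg, "differential.tsv"))
    membrane, gf, nt, counts = run_funnel(records, ann)
    out = Path(cfg.out_dir)
    for name, recs in (
        ("membrane.tsv", membrane),
        ("growth_factor_receptors.tsv", gf),
        ("neurotrophic_receptors.tsv", nt),
    ):
        differential_frame(recs).to_csv(out / name, sep="\t", index=False)
    funnel = {
        "funnel_counts": counts.as_dict(),
        "annotation_source_version": ann.source_version,
    }
    (out / "funnel.json").write_text(json.dumps(funnel, indent=2, sort_keys=True) + "\n")
    return funnel


def stage_select(cfg: PipelineConfig) -> list[DifferentialRecord]:
    """Apply the fold/detectability selection rules to neurotrophic receptors."""
    nt = _read_differential(_artifact(cfg, "neurotrophic_receptors.tsv"), "annotate")
    candidates = select_enriched_receptors(nt, cfg.rlm_params())
    differential_frame(candidates).to_csv(
        _artifact(cfg, "candidates.tsv"), sep="\t", index=False
    )
    return candidates


def stage_recommend(cfg: PipelineConfig) -> dict:
    """Join candidates to the ligand KB; write the ranked recommendation."""
    _, _, kb, _ = _load_inputs(cfg)
    candidates = _read_differential(_artifact(cfg, "candidates.tsv"), "select")
    records = _read_differential(_artifact(cfg, "differential.tsv"))
    recs = match_ligands(candidates, kb, cfg.rlm_params())
    out = Path(cfg.out_dir)
    write_report(recs, differential_frame(records), out, formats=cfg.formats)
    (out / "recommendations.md").write_text(recommendation_markdown(recs))
    selected = sorted(
        {r.ligand_name for r in recs if r.selected_for_supplementation}
    )
    diff = compare_supplement_sets(selected, cfg.params.conventional_supplements)
    result = {"selected_ligands": selected, "vs_conventional": diff}
    (out / "supplement_diff.json").write_text(
        json.dumps(result, indent=2, sort_keys=True) + "\n"
    )
    return result


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute every stage and write the JSON run report.

    Returns the report dict. The report contains the merged parameters
    actually used, the seed, package and annotation versions, the
    funnel counts, and the supplement comparison — everything needed to
    audit the run without re-executing it.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        stage_simulate(cfg)
    records = stage_quantify(cfg)
    funnel = stage_annotate(cfg)
    candidates = stage_select(cfg)
    rec_result = stage_recommend(cfg)
    report = {
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": cfg.model_dump(),
        "funnel_counts": {
            **funnel["funnel_counts"],
            "selected_candidates": len(candidates),
        },
        "annotation_source_version": funnel["annotation_source_version"],
        "selected_ligands": rec_result["selected_ligands"],
        "vs_conventional": rec_result["vs_conventional"],
        "n_differential_records": len(records),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", out / "run_report.json")
    return report
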