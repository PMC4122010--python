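"""End-to-end pipeline orchestration: detect → extract → compare → fba /
fva / sample / diet, with a YAML config, a run manifest and a markdown
report.

Stages write their outputs under ``out_dir/<stage>/`` and append to a
manifest (inputs, seed, checksums).  Re-running with an unchanged config
skips completed stages unless forced; a stage failure aborts the run naming
the stage, keeping partial outputs on disk.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic_data as synth
from .constraint_analysis import Medium, apply_medium, flux_variability, solve_fba
from .context_extraction import PresenceProfile, compare_models, gimme_extract, imat_extract
from .diet_response import (
    CARBON_SOURCES,
    DietCondition,
    diet_stress_reactions,
    simulate_conditions,
    stress_genes,
)
from .flux_sampling import flux_correlations, sample_fluxes
from .model_io import read_model, write_model
from .strain_profiling import (
    aggregate_prevalence,
    profile_sample,
    read_blast_tab,
    records_from_frame,
)

ALL_STAGES = ["simulate", "detect", "extract", "compare", "fba", "fva", "sample", "diet"]


@dataclass
class PipelineConfig:
    """All knobs in one place; defaults are the thresholds used throughout
    the package (identity 99 %, depth 10×, gene fraction 0.8, stress band
    0.9–1.1, FVA fraction 1.0, GIMME/iMAT growth floor 0.9)."""

    out_dir: str = "gutflux_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # strain profiling
    min_identity: float = 99.0
    depth_threshold: float = 10.0
    gene_fraction: float = 0.8
    # extraction
    evidence_threshold: float = 0.5
    growth_fraction: float = 0.9
    imat_epsilon: float = 1.0
    extraction_algorithm: str = "gimme"
    # simulation / media
    uptake: float = 9.0
    aerobic: bool = True
    fva_fraction: float = 1.0
    # sampling
    n_samples: int = 1000
    thinning: int = 100
    # synthetic inputs (used when no real paths are given)
    pan_model: str | None = None
    profiles: dict[str, str] = field(default_factory=dict)  # strain -> TSV path
    alignments: list[str] = field(default_factory=list)  # per-sample BLAST tabs
    genome_lengths: dict[str, int] = field(default_factory=dict)
    n_strains: int = 3
    n_accessory: int = 8
    cohort_samples: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")
        if self.depth_threshold <= 0:
            raise ValueError("depth_threshold must be positive")
        if not (0 < self.gene_fraction <= 1):
            raise ValueError("gene_fraction must be in (0, 1]")
        if not (0 < self.growth_fraction <= 1):
            raise ValueError("growth_fraction must be in (0, 1]")
        if not (0 < self.fva_fraction <= 1):
            raise ValueError("fva_fraction must be in (0, 1]")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the configured stages in dependency order and return the run
    manifest (also written to ``out_dir/manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"config_digest": config.digest(), "seed": config.seed,
                      "stages": {}}
    previous: dict = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}
    reusable = (not force) and previous.get("config_digest") == config.digest()

    state: dict = {}
    order = [s for s in ALL_STAGES if s in config.stages]
    for stage in order:
        stage_dir = out / stage
        prior = previous.get("stages", {}).get(stage) if reusable else None
        if prior and all(Path(p).exists() for p in prior.get("outputs", [])):
            manifest["stages"][stage] = {**prior, "skipped": True}
            _restore_state(stage, stage_dir, config, state)
            continue
        stage_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.time()
        try:
            outputs = _STAGE_FNS[stage](config, stage_dir, state)
        except Exception as e:  # abort naming the stage; keep partial outputs
            manifest_path.write_text(json.dumps(manifest, indent=1))
            raise StageFailure(stage, e) from e
        manifest["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "checksums": {str(p): _checksum(Path(p)) for p in outputs},
            "elapsed_s": round(time.time() - t0, 3),
            "skipped": False,
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Stages.  Each takes (config, stage_dir, state) and returns output paths;
# ``state`` carries in-memory objects forward (models, profiles, fluxes).
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, d: Path, state: dict) -> list[Path]:
    pan, strains = synth.make_pan_with_strains(
        n_strains=cfg.n_strains, n_accessory=cfg.n_accessory, seed=cfg.seed
    )
    outputs = []
    pan_path = d / "pan_model.json"
    write_model(pan, pan_path)
    outputs.append(pan_path)
    for st in strains:
        p = d / f"profile_{st.strain_id}.tsv"
        pd.DataFrame(sorted(st.profile.items()),
                     columns=["gene_id", "score"]).to_csv(p, sep="\t", index=False)
        outputs.append(p)
    cohort = synth.PlantedCohort(
        n_samples=cfg.cohort_samples,
        strains={st.strain_id: (1.0 - 0.2 * i, 12.0)
                 for i, st in enumerate(strains)},
        seed=cfg.seed,
    )
    genome_length = 50_000
    for i, table in enumerate(synth.make_alignments(cohort, genome_length)):
        p = d / f"alignments_sample{i}.tsv"
        table.to_csv(p, sep="\t", index=False, header=False)
        outputs.append(p)
    lengths = {st.strain_id: genome_length for st in strains}
    p = d / "genome_lengths.tsv"
    pd.DataFrame(sorted(lengths.items()),
                 columns=["strain", "length"]).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    state.update(pan=pan, strains=strains, genome_lengths=lengths,
                 alignment_paths=[d / f"alignments_sample{i}.tsv"
                                  for i in range(cfg.cohort_samples)])
    return outputs


def _stage_detect(cfg: PipelineConfig, d: Path, state: dict) -> list[Path]:
    paths = cfg.alignments or [str(p) for p in state.get("alignment_paths", [])]
    lengths = cfg.genome_lengths or state.get("genome_lengths", {})
    if not paths or not lengths:
        raise ValueError("detect needs alignments and genome lengths "
                         "(run the simulate stage or configure paths)")
    per_sample = []
    for p in paths:
        records = read_blast_tab(p)
        per_sample.append(
            profile_sample(records, lengths, min_identity=cfg.min_identity,
                           depth_threshold=cfg.depth_threshold)
        )
    rows = [
        (i, c.strain_id, c.depth, c.breadth, c.present)
        for i, calls in enumerate(per_sample) for c in calls
    ]
    calls_path = d / "strain_calls.tsv"
    pd.DataFrame(rows, columns=["sample", "strain", "depth", "breadth",
                                "present"]).to_csv(calls_path, sep="\t", index=False)
    prev = aggregate_prevalence(per_sample)
    prev_path = d / "prevalence.tsv"
    prev.to_csv(prev_path, sep="\t", index=False)
    state["prevalence"] = prev
    return [calls_path, prev_path]


def _load_pan_and_profiles(cfg: PipelineConfig, state: dict):
    if "pan" in state:
        profiles = [
            PresenceProfile(strain_id=st.strain_id, gene_scores=st.profile)
            for st in state["strains"]
        ]
        return state["pan"], profiles
    if not cfg.pan_model or not cfg.profiles:
        raise ValueError("extract needs a pan model and profiles "
                         "(run the simulate stage or configure paths)")
    pan = read_model(cfg.pan_model)
    profiles = []
    for sid, path in cfg.profiles.items():
        df = pd.read_csv(path, sep="\t")
        profiles.append(PresenceProfile(
            strain_id=sid,
            gene_scores=dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float))),
        ))
    return pan, profiles


def _stage_extract(cfg: PipelineConfig, d: Path, state: dict) -> list[Path]:
    pan, profiles = _load_pan_and_profiles(cfg, state)
    extract = gimme_extract if cfg.extraction_algorithm == "gimme" else imat_extract
    outputs = []
    models = []
    for prof in profiles:
        if cfg.extraction_algorithm == "gimme":
            res = gimme_extract(pan, prof, threshold=cfg.evidence_threshold,
                                growth_fraction=cfg.growth_fraction)
        else:
            res = imat_extract(pan, prof, high_threshold=cfg.evidence_threshold,
                               low_threshold=cfg.evidence_threshold,
                               epsilon=cfg.imat_epsilon,
                               growth_fraction=cfg.growth_fraction)
        p = d / f"{prof.strain_id}_model.json"
        write_model(res.model, p)
        outputs.append(p)
        models.append(res.model)
    state["strain_models"] = models
    return outputs


def _stage_compare(cfg: PipelineConfig, d: Path, state: dict) -> list[Path]:
    models = state.get("strain_models")
    if not models:
        raise ValueError("compare needs extracted strain models")
    cmp = compare_models(models)
    rows = [
        (mid, len(cmp.specific_reactions[mid]), len(cmp.specific_genes[mid]),
         ";".join(sorted(cmp.specific_reactions[mid])))
        for mid in cmp.specific_reactions
    ]
    p1 = d / "specific_reactions.tsv"
    pd.DataFrame(rows, columns=["model", "n_specific_reactions",
                                "n_specific_genes", "reactions"]).to_csv(
        p1, sep="\t", index=False)
    p2 = d / "comparison.json"
    p2.write_text(json.dumps({
        "specific_reactions": {k: sorted(v) for k, v in cmp.specific_reactions.items()},
        "specific_genes": {k: sorted(v) for k, v in cmp.specific_genes.items()},
        "nonshared_metabolites": sorted(cmp.nonshared_metabolites),
        "shared_reaction_count": cmp.shared_reaction_count,
    }, indent=1))
    return [p1, p2]


def _medium(cfg: PipelineConfig) -> Medium:
    return Medium(exchanges={CARBON_SOURCES["glucose"]: cfg.uptake},
                  aerobic=cfg.aerobic)


def _models_for_analysis(cfg: PipelineConfig, state: dict):
    models = state.get("strain_models")
    if models:
        return models
    if cfg.pan_model:
        return [read_model(cfg.pan_model)]
    return [synth.make_core_fixture()]


def _stage_fba(cfg: PipelineConfig, d: Path, state: dict) -> list[Path]:
    outputs = []
    growth_rows = []
    for m in _models_for_analysis(cfg, state):
        res = solve_fba(apply_medium(m, _medium(cfg)))
        p = d / f"{m.id}_fluxes.tsv"
        pd.DataFrame(sorted(res.fluxes.items()),
                     columns=["reaction_id", "flux"]).to_csv(p, sep="\t", index=False)
        outputs.append(p)
        growth_rows.append((m.id, res.status, res.objective_value))
        state.setdefault("fba", {})[m.id] = res
    p = d / "growth.tsv"
    pd.DataFrame(growth_rows, columns=["model", "status", "growth_rate"]).to_csv(
        p, sep="\t", index=False)
    outputs.append(p)
    return outputs


def _stage_fva(cfg: PipelineConfig, d: Path, state: dict) -> list[Path]:
    outputs = []
    for m in _models_for_analysis(cfg, state):
        fva = flux_variability(apply_medium(m, _medium(cfg)),
                               objective_fraction=cfg.fva_fraction)
        rows = [(rid, lo, hi, fva.direction[rid])
                for rid, (lo, hi) in fva.ranges.items()]
        p = d / f"{m.id}_fva.tsv"
        pd.DataFrame(rows, columns=["reaction_id", "min", "max",
                                    "direction"]).to_csv(p, sep="\t", index=False)
        outputs.append(p)
    return outputs


def _stage_sample(cfg: PipelineConfig, d: Path, state: dict) -> list[Path]:
    outputs = []
    for m in _models_for_analysis(cfg, state):
        samples = sample_fluxes(apply_medium(m, _medium(cfg)), cfg.n_samples,
                                seed=cfg.seed, thinning=cfg.thinning)
        p = d / f"{m.id}_samples.tsv"
        samples.to_frame().to_csv(p, sep="\t", index=False)
        outputs.append(p)
        wanted = [r for r in ("PGL", "GND", "RPI") if r in samples.reaction_ids]
        if len(wanted) >= 2:
            pairs = [(a, b) for i, a in enumerate(wanted) for b in wanted[i + 1:]]
            corr = flux_correlations(samples, pairs)
            pc = d / f"{m.id}_correlations.tsv"
            pd.DataFrame(
                [(c.reaction_a, c.reaction_b, c.correlation, c.n_samples)
                 for c in corr],
                columns=["reaction_a", "reaction_b", "pearson_r", "n_samples"],
            ).to_csv(pc, sep="\t", index=False)
            outputs.append(pc)
    return outputs


def _stage_diet(cfg: PipelineConfig, d: Path, state: dict) -> list[Path]:
    outputs = []
    conditions = [DietCondition(carbon_exchange=ex, uptake=cfg.uptake,
                                aerobic=cfg.aerobic, name=name)
                  for name, ex in CARBON_SOURCES.items()]
    for m in _models_for_analysis(cfg, state):
        missing = [c.carbon_exchange for c in conditions
                   if c.carbon_exchange not in {r.id for r in m.exchanges}]
        if missing:
            raise KeyError(f"model {m.id}: missing carbon exchanges {missing}")
        table, fluxes = simulate_conditions(m, conditions)
        p = d / f"{m.id}_growth.tsv"
        table.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        if fluxes.get("glucose") and fluxes.get("succinate"):
            report = diet_stress_reactions(fluxes["succinate"], fluxes["glucose"],
                                           "succinate", "glucose")
            genes = stress_genes(report, m)
            p2 = d / f"{m.id}_stress.tsv"
            report.table.to_csv(p2, sep="\t", index=False)
            p3 = d / f"{m.id}_stress_genes.txt"
            p3.write_text("\n".join(sorted(genes)) + "\n")
            outputs.extend([p2, p3])
    return outputs


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "extract": _stage_extract,
    "compare": _stage_compare,
    "fba": _stage_fba,
    "fva": _stage_fva,
    "sample": _stage_sample,
    "diet": _stage_diet,
}


def _restore_state(stage: str, stage_dir: Path, cfg: PipelineConfig, state: dict) -> None:
    """Rebuild the in-memory state a skipped stage would have produced, from
    its on-disk outputs (only what downstream stages need)."""
    if stage == "simulate":
        pan_path = stage_dir / "pan_model.json"
        if pan_path.exists():
            pan, strains = synth.make_pan_with_strains(
                n_strains=cfg.n_strains, n_accessory=cfg.n_accessory, seed=cfg.seed
            )
            lengths = {st.strain_id: 50_000 for st in strains}
            state.update(pan=pan, strains=strains, genome_lengths=lengths,
                         alignment_paths=sorted(stage_dir.glob("alignments_sample*.tsv")))
    elif stage == "extract":
        models = [read_model(p) for p in sorted(stage_dir.glob("*_model.json"))]
        if models:
            state["strain_models"] = models


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def render_report(manifest: dict | str | Path, out_path: str | Path | None = None) -> str:
    """Markdown summary of a pipeline run: per-stage tables for detection,
    model comparison, growth, FVA and sampling correlations.  Sections whose
    stage output is missing are replaced by a notice."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    lines = ["# gutflux run report", "",
             f"Config digest: `{manifest.get('config_digest', '?')}`; "
             f"seed {manifest.get('seed', '?')}", ""]

    def table_section(title: str, stage: str, suffix: str) -> None:
        lines.append(f"## {title}")
        entry = manifest.get("stages", {}).get(stage)
        if not entry:
            lines.append(f"_stage `{stage}` not run — section omitted_\n")
            return
        shown = False
        for p in entry.get("outputs", []):
            if p.endswith(suffix) and Path(p).exists():
                df = pd.read_csv(p, sep="\t")
                lines.append(f"**{Path(p).name}**\n")
                lines.append(df.to_markdown(index=False))
                lines.append("")
                shown = True
        if not shown:
            lines.append("_no matching outputs on disk_\n")

    table_section("Strain detection", "detect", "prevalence.tsv")
    table_section("Model comparison", "compare", "specific_reactions.tsv")
    table_section("Growth (FBA)", "fba", "growth.tsv")
    table_section("Growth by carbon source", "diet", "_growth.tsv")
    table_section("Flux variability", "fva", "_fva.tsv")
    table_section("Sampling correlations", "sample", "_correlations.tsv")
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
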