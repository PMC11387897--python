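"""End-to-end comparative study orchestration.

A study is declared in a YAML/dict config: a list of models (generated
proxies or tet-mesh files), shared material and bite settings, a scaling
reference, and optional sensitivity settings.  ``run_study`` solves every
model at actual size, re-solves under surface-area-equalized loading,
optionally runs the muscle sensitivity analysis, and writes comparison
CSVs, VTK fields and a run manifest.  Crania and mandibles are always
analyzed as separate models, never articulated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .fe_solver import MaterialProperties, solve
from .loading_model import (
    BiteConfig,
    MuscleSpec,
    ScalingPolicy,
    build_load_case,
    default_muscle_groups,
    muscle_force_from_area,
)
from .mesh_io import read_tetmesh, write_results_vtk
from .sensitivity import run_sensitivity
from .stress_stats import comparison_table, summarize
from .synthetic_skull import LabeledModel, ProxyParams, generate_proxy

logger = logging.getLogger("skullfea")

__all__ = ["StudyConfig", "ConfigFinding", "validate_config", "load_config",
           "run_study", "build_models"]


@dataclass
class ConfigFinding:
    severity: str  # "fatal" | "warning"
    message: str


@dataclass
class StudyConfig:
    """Parsed study configuration (see docs for the YAML schema)."""

    models: list[dict[str, Any]]
    material: MaterialProperties = field(default_factory=MaterialProperties)
    bite: BiteConfig = field(default_factory=BiteConfig)
    scaling_reference: str | None = None
    sensitivity: dict[str, Any] | None = None
    output_dir: Path = Path("results/study")
    seed: int = 0
    raw: dict[str, Any] = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> StudyConfig:
    mat = raw.get("material", {})
    bite = raw.get("bite", {})
    scaling = raw.get("scaling", {})
    return StudyConfig(
        models=raw.get("models", []),
        material=MaterialProperties(
            youngs_modulus=float(mat.get("youngs_modulus", 15000.0)),
            poisson_ratio=float(mat.get("poisson_ratio", 0.29)),
        ),
        bite=BiteConfig(
            mode=bite.get("mode", "load"),
            magnitude=float(bite.get("magnitude", 0.0)),
            direction=tuple(bite.get("direction", (0.0, 0.0, -1.0))),
        ),
        scaling_reference=scaling.get("reference"),
        sensitivity=raw.get("sensitivity"),
        output_dir=Path(raw.get("output_dir", "results/study")),
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


def validate_config(config: StudyConfig) -> list[ConfigFinding]:
    """Static checks; fatal findings should abort the run."""
    findings: list[ConfigFinding] = []
    labels = [m.get("label") for m in config.models]
    if not labels:
        findings.append(ConfigFinding("fatal", "no models declared"))
    if len(set(labels)) != len(labels):
        findings.append(ConfigFinding("fatal", f"duplicate model labels: {labels}"))
    for m in config.models:
        area = m.get("adductor_area", m.get("proxy", {}).get("adductor_area", 20.0))
        if area is not None and float(area) <= 0:
            findings.append(ConfigFinding(
                "fatal", f"model {m.get('label')!r}: nonpositive adductor area"))
        if "proxy" not in m and "file" not in m:
            findings.append(ConfigFinding(
                "fatal", f"model {m.get('label')!r}: neither proxy params nor file"))
    if config.scaling_reference is not None and config.scaling_reference not in labels:
        findings.append(ConfigFinding(
            "fatal",
            f"scaling reference {config.scaling_reference!r} is not a declared model"))
    if config.bite.mode == "load" and config.bite.magnitude == 0.0:
        findings.append(ConfigFinding(
            "warning", "bite mode 'load' with zero magnitude: no bite force applied"))
    return findings


def build_models(config: StudyConfig) -> list[LabeledModel]:
    models = []
    for m in config.models:
        if "proxy" in m:
            params = ProxyParams(seed=config.seed, **m["proxy"])
            model = generate_proxy(params)
        else:
            mesh = read_tetmesh(m["file"])
            from .mesh_io import element_volumes
            model = LabeledModel(
                mesh=mesh,
                summary=element_volumes(mesh),
                adductor_area=float(m.get("adductor_area", 20.0)),
                part=m.get("part", "cranium"),
            )
        model.label = m["label"]
        if "part" in m:
            model.part = m["part"]
        models.append(model)
    return models


def _solve_one(model: LabeledModel, config: StudyConfig,
               policy: ScalingPolicy):
    spec = MuscleSpec(adductor_area=model.adductor_area)
    loads = build_load_case(model, spec=spec, bite=config.bite, policy=policy)
    fld = solve(model.mesh, config.material, loads)
    return loads, fld, summarize(fld)


def _reference_policy(models: list[LabeledModel], ref_label: str) -> ScalingPolicy:
    ref = next(m for m in models if m.label == ref_label)
    groups = default_muscle_groups(ref)
    spec = MuscleSpec(adductor_area=ref.adductor_area)
    pooled = muscle_force_from_area(spec)
    total = next(iter(pooled.values()))
    return ScalingPolicy(
        mode="sa_equalized",
        reference_surface_area=ref.summary.surface_area,
        reference_forces={g.name: total / len(groups) for g in groups},
    )


def family_study_config(output_dir: str | Path = "results/family_study",
                        parts: tuple[str, ...] = ("cranium", "mandible"),
                        sensitivity_mode: str = "per_muscle",
                        seed: int = 0) -> StudyConfig:
    """Packaged comparative study over the example proxy family.

    Three morphs per part: gracile-small, gracile-large (every dimension
    and the adductor area scaled isometrically x2, hence x4 area) and
    robust-large (posterior depth x1.6).  Bite nodes are constrained so
    the bite reaction emerges from lever statics; scaling reference is the
    large gracile individual.
    """
    base = dict(length=100.0, posterior_width=40.0, posterior_depth=30.0,
                anterior_taper=0.35, resolution=12)
    models = []
    for part in parts:
        suffix = "" if len(parts) == 1 else f"-{part}"
        models += [
            {"label": f"gracile-small{suffix}", "part": part,
             "proxy": dict(base, preset=part, robusticity=1.0,
                           adductor_area=20.0)},
            {"label": f"gracile-large{suffix}", "part": part,
             "proxy": dict(preset=part, length=200.0, posterior_width=80.0,
                           posterior_depth=60.0, anterior_taper=0.35,
                           resolution=12, robusticity=1.0,
                           adductor_area=80.0)},
            {"label": f"robust-large{suffix}", "part": part,
             "proxy": dict(base, preset=part, robusticity=1.6,
                           adductor_area=20.0)},
        ]
    raw = {
        "models": models,
        "material": {"youngs_modulus": 15000.0, "poisson_ratio": 0.29},
        "bite": {"mode": "constrain"},
        "scaling": {"reference": "gracile-large" if len(parts) == 1
                    else f"gracile-large-{parts[0]}"},
        "sensitivity": {"mode": sensitivity_mode, "perturbation": 0.10},
        "output_dir": str(output_dir),
        "seed": seed,
    }
    return config_from_dict(raw)


def run_study(config: StudyConfig) -> dict[str, Any]:
    """Run the full comparative study; returns a dict of output paths and
    in-memory tables.  A failing model is logged and skipped; the rest of
    the study continues."""
    findings = validate_config(config)
    fatal = [f for f in findings if f.severity == "fatal"]
    if fatal:
        raise ValueError("; ".join(f.message for f in fatal))
    for f in findings:
        logger.warning("config: %s", f.message)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    models = build_models(config)
    chash = config.config_hash()

    results: dict[str, Any] = {"tables": {}, "paths": [], "failures": []}
    modes: dict[str, ScalingPolicy] = {"actual_size": ScalingPolicy()}
    by_part: dict[str, list[str]] = {}
    for m in models:
        by_part.setdefault(m.part, []).append(m.label)

    if config.scaling_reference is not None:
        modes["sa_equalized"] = None  # filled per part below

    sens_rows = []
    for mode_name in modes:
        rows = []
        for m in models:
            try:
                if mode_name == "sa_equalized":
                    # reference is matched within the same part: crania are
                    # scaled to the reference cranium, mandibles to the
                    # reference mandible (fallback: largest of the part)
                    part_models = [x for x in models if x.part == m.part]
                    if config.scaling_reference in by_part.get(m.part, []):
                        ref_label = config.scaling_reference
                    else:
                        ref_label = max(
                            part_models, key=lambda x: x.summary.surface_area
                        ).label
                    policy = _reference_policy(part_models, ref_label)
                else:
                    policy = modes[mode_name]
                loads, fld, stats = _solve_one(m, config, policy)
                rows.append((m.label, m.part, stats))
                vtk = out / f"{m.label}_{m.part}_{mode_name}.vtk"
                write_results_vtk(m.mesh, fld, vtk)
                results["paths"].append(vtk)
                if mode_name == "actual_size" and config.sensitivity:
                    sens = run_sensitivity(
                        m, config.material, loads,
                        mode=config.sensitivity.get("mode", "per_muscle"),
                        perturbation=float(config.sensitivity.get("perturbation", 0.10)),
                    )
                    sens_rows.append(sens.as_row())
            except Exception as exc:
                logger.error("model %s (%s, %s) failed: %s",
                             m.label, m.part, mode_name, exc)
                results["failures"].append((m.label, mode_name, str(exc)))
        if rows:
            table = comparison_table(rows, mode_name)
            table["config_hash"] = chash
            path = out / f"comparison_{mode_name}.csv"
            table.to_csv(path, index=False)
            results["tables"][mode_name] = table
            results["paths"].append(path)

    if sens_rows:
        sens_table = pd.DataFrame(sens_rows)
        sens_table["config_hash"] = chash
        path = out / "sensitivity.csv"
        sens_table.to_csv(path, index=False)
        results["tables"]["sensitivity"] = sens_table
        results["paths"].append(path)

    manifest = {
        "config_hash": chash,
        "skullfea_version": __version__,
        "seed": config.seed,
        "models": [m.label for m in models],
        "modes": list(modes),
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
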