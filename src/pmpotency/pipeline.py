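"""End-to-end orchestration: simulate or ingest, normalize, fit, integrate,
correlate, rank — with a run manifest and machine-readable outputs.

The pipeline is deterministic given (inputs, config, seed).  Every output
table carries a ``# seed:`` header line; a JSON manifest recording the
config snapshot, per-stage record counts and warnings is written on every
run, success or failure.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    IN_VITRO,
    IN_VIVO,
    ROLE_AHR,
    ROLE_TOXICITY,
    ROLE_VIABILITY,
    default_invitro_design,
    default_invivo_design,
)
from .exceptions import ConfigurationError, PMPotencyError, ValidationError
from .foldeffect import POOLED, compute_fold_effect
from .integrate import (
    CYTOKINE_ROLES,
    ScenarioConfig,
    integrate_invitro,
    integrate_invivo,
    rank_particles,
)
from .association import concordance_table
from .io import read_table, write_table
from .potency import LOG_LINEAR, fit_all
from .simulate import (
    MEASUREMENT_COLUMNS,
    generate_particle_panel,
    panel_metadata,
    simulate_measurements,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_COMPUTATION = 3


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of input_measurements / simulate."""

    outdir: str = "pmpotency_out"
    seed: int = 0
    fmt: str = "tsv"
    input_measurements: str | None = None
    simulate: dict[str, Any] | None = None
    scenario: dict[str, Any] = field(default_factory=dict)
    fit_method: str = LOG_LINEAR
    pooling: str = POOLED
    exclusions: list[str] = field(default_factory=list)
    pearson_tail: str = "one"
    spearman_tail: str = "one"
    spearman_method: str = "t_approx"
    verbosity: str = "INFO"

    def __post_init__(self):
        if (self.input_measurements is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of input_measurements / simulate must be set"
            )
        if self.fmt not in ("tsv", "csv"):
            raise ConfigurationError(f"unknown output format {self.fmt!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    started: str
    finished: str | None = None
    status: str = "running"
    failed_stage: str | None = None
    record_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path):
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _build_designs(sim: dict[str, Any]):
    noise = sim.get("noise_sigma", 0.2)
    invitro = default_invitro_design(
        noise_sigma=noise,
        n_experiments=sim.get("n_experiments", 3),
        n_replicates=sim.get("n_replicates", 3),
    )
    invivo = None
    if sim.get("include_invivo", True):
        invivo = default_invivo_design(
            noise_sigma=sim.get("invivo_noise_sigma", noise),
            n_cohorts=sim.get("n_cohorts", 1),
            n_animals_per_dose=sim.get("n_animals_per_dose", 5),
        )
    return invitro, invivo


def _scenario_from(config: PipelineConfig, roles: dict[str, str]) -> ScenarioConfig:
    opts = dict(config.scenario)
    roles = dict(roles, **opts.pop("roles", {}))
    return ScenarioConfig(roles=roles, **opts)


def validate_inputs(
    measurements: pd.DataFrame, scenario: ScenarioConfig | None = None
) -> list[dict[str, str]]:
    """Schema and contract checks; returns a list of issues (never raises).

    Each issue is a dict with ``level`` ("error"/"warning") and ``message``.
    """
    issues: list[dict[str, str]] = []
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        issues.append(
            {"level": "error", "message": f"missing columns: {sorted(missing)}"}
        )
        return issues
    if (measurements["dose_ug"] < 0).any():
        bad = measurements.index[measurements["dose_ug"] < 0].tolist()[:5]
        issues.append(
            {"level": "error", "message": f"negative doses at rows {bad}"}
        )
    nonpos = measurements["value"].notna() & (measurements["value"] <= 0)
    if nonpos.any():
        issues.append(
            {
                "level": "warning",
                "message": f"{int(nonpos.sum())} non-positive values "
                f"(first rows {measurements.index[nonpos].tolist()[:5]})",
            }
        )
    for (unit, endpoint, exp), grp in measurements.groupby(
        ["unit", "endpoint", "experiment"]
    ):
        if not (grp["dose_ug"] == 0).any():
            issues.append(
                {
                    "level": "error",
                    "message": f"experiment {exp!r} has no dose-0 control rows "
                    f"for {unit}/{endpoint}",
                }
            )
    if scenario is not None:
        known_roles = {k.split("/", 1)[1] for k in scenario.roles}
        cytolike = {
            k.split("/", 1)[1]
            for k, r in scenario.roles.items()
            if r in CYTOKINE_ROLES
        }
        for endpoint in measurements["endpoint"].unique():
            if endpoint not in known_roles:
                issues.append(
                    {
                        "level": "warning",
                        "message": f"endpoint {endpoint!r} has no declared role; "
                        "it will be ignored by integration",
                    }
                )
            elif endpoint in cytolike and (
                endpoint not in scenario.hi_signs or endpoint not in scenario.lo_signs
            ):
                issues.append(
                    {
                        "level": "warning",
                        "message": f"cytokine {endpoint!r} lacks a HI/LO sign; "
                        "add it to the scenario sign maps",
                    }
                )
    return issues


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write output tables under ``config.outdir``.

    Raises on stage failure after writing a manifest with the failed stage;
    callers mapping to shell exit codes should use EXIT_VALIDATION for
    ValidationError/ConfigurationError and EXIT_COMPUTATION otherwise.
    """
    outdir = Path(config.outdir)
    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        version=__version__,
        started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest_path = outdir / "manifest.json"
    header = {"seed": config.seed, "pmpotency_version": __version__}
    stage = "setup"

    def emit(name: str, df: pd.DataFrame, index: bool = False):
        path = write_table(df, outdir / f"{name}.{config.fmt}", config.fmt,
                           header=header, index=index)
        manifest.outputs.append(str(path))
        manifest.record_counts[name] = int(len(df))

    try:
        stage = "ingest"
        truth = None
        if config.simulate is not None:
            sim = dict(config.simulate)
            invitro_design, invivo_design = _build_designs(sim)
            roles = dict(invitro_design.roles())
            if invivo_design is not None:
                roles.update(invivo_design.roles())
            panel = generate_particle_panel(
                n_urban=sim.get("n_urban", 6),
                n_mineral=sim.get("n_mineral", 2),
                beta_ranges=sim.get("beta_ranges"),
                seed=config.seed,
                endpoint_roles=roles,
            )
            ds_vitro = simulate_measurements(invitro_design, panel, config.seed)
            frames = [ds_vitro.measurements]
            truths = [ds_vitro.truth]
            if invivo_design is not None:
                ds_vivo = simulate_measurements(
                    invivo_design, panel, config.seed + 1
                )
                frames.append(ds_vivo.measurements)
                truths.append(ds_vivo.truth)
            measurements = pd.concat(frames, ignore_index=True)
            truth = pd.concat(truths, ignore_index=True)
            emit("measurements", measurements)
            emit("truth", truth)
            emit("panel", panel_metadata(panel))
        else:
            measurements = read_table(config.input_measurements)
            roles_cfg = config.scenario.get("roles")
            if roles_cfg:
                roles = dict(roles_cfg)
            else:
                roles = {
                    **default_invitro_design().roles(),
                    **default_invivo_design().roles(),
                }
        scenario = _scenario_from(config, roles)

        stage = "validate"
        issues = validate_inputs(measurements, scenario)
        for issue in issues:
            manifest.warnings.append(f"{issue['level']}: {issue['message']}")
            logger.log(
                logging.ERROR if issue["level"] == "error" else logging.WARNING,
                "%s", issue["message"],
            )
        if any(i["level"] == "error" for i in issues):
            raise ValidationError(
                "; ".join(i["message"] for i in issues if i["level"] == "error")
            )

        stage = "fold_effect"
        fe = compute_fold_effect(measurements, config.pooling)
        emit("fold_effect", fe)

        stage = "fit"
        potencies = fit_all(fe, config.fit_method)
        emit("potency", potencies)

        stage = "integrate"
        rank_frames = []
        invitro_idx = invivo_idx = None
        pot_vitro = potencies[potencies["model"] == IN_VITRO]
        if len(pot_vitro):
            invitro_idx = integrate_invitro(pot_vitro, scenario)
            emit("integrated_invitro", invitro_idx.reset_index())
            rank_frames.append(
                pd.DataFrame(
                    {
                        "particle": invitro_idx.index,
                        "index": "ibeta",
                        "model": IN_VITRO,
                        "rank": rank_particles(invitro_idx["ibeta"]).to_numpy(),
                    }
                )
            )
        pot_vivo = potencies[potencies["model"] == IN_VIVO]
        if len(pot_vivo):
            invivo_idx = integrate_invivo(pot_vivo, scenario)
            emit("integrated_invivo", invivo_idx.reset_index())
            rank_frames.append(
                pd.DataFrame(
                    {
                        "particle": invivo_idx.index,
                        "index": "ibeta_invivo",
                        "model": IN_VIVO,
                        "rank": rank_particles(invivo_idx["ibeta_invivo"]).to_numpy(),
                    }
                )
            )
        if rank_frames:
            emit("ranks", pd.concat(rank_frames, ignore_index=True))

        stage = "correlate"
        if invitro_idx is not None and invivo_idx is not None:
            conc = concordance_table(
                invitro_idx,
                invivo_idx,
                exclusions=config.exclusions,
                pearson_tail=config.pearson_tail,
                spearman_tail=config.spearman_tail,
                spearman_method=config.spearman_method,
            )
            emit("concordance", conc)

        manifest.status = "success"
        return manifest
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        raise
    finally:
        manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        manifest.write(manifest_path)
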