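"""Synthetic measurement generator with known ground-truth potencies.

Raw values follow the multiplicative power-law model the analysis assumes:

    value = baseline * (dose + 1)**beta_true * exp(eps),   eps ~ N(0, sigma^2)

so the log-linear potency estimator downstream is the exact least-squares
model for the simulated data.  Dose-0 control wells are shared across
particles within an experiment (one pooled control set), matching the
grand-mean-of-controls fold-effect normalization.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    IN_VITRO,
    ROLE_AHR,
    ROLE_ANTI,
    ROLE_DUAL,
    ROLE_PRO,
    ROLE_TOXICITY,
    ROLE_VIABILITY,
    StudyDesign,
    default_invitro_design,
    default_invivo_design,
    endpoint_key,
)
from .exceptions import ConfigurationError, DesignMismatchError

CONTROL_LABEL = "control-buffer"

MEASUREMENT_COLUMNS = (
    "model",
    "unit",
    "endpoint",
    "particle",
    "dose_ug",
    "experiment",
    "replicate",
    "value",
)

URBAN_COARSE = "urban_coarse"
URBAN_FINE = "urban_fine"
MINERAL = "mineral"

# Endotoxin content of urban dust stocks spans roughly 3-127 EU/ug; mineral
# particles carry none (below LAL detection).
ENDOTOXIN_SPAN = (3.0, 127.0)
LOW_ENDOTOXIN_URBAN = 3.0

# Plausible true-slope ranges by endpoint role (dimensionless beta).  Keys
# may also be qualified "unit/endpoint" strings, which take precedence —
# used e.g. to make alveolar macrophage counts decrease on exposure.
DEFAULT_BETA_RANGES: dict[str, tuple[float, float]] = {
    ROLE_VIABILITY: (-0.25, 0.0),
    ROLE_PRO: (0.0, 0.35),
    ROLE_ANTI: (-0.15, 0.10),
    ROLE_DUAL: (-0.10, 0.35),
    ROLE_AHR: (-0.5, 2.0),
    ROLE_TOXICITY: (0.0, 0.30),
    "BALB_c/macrophages": (-0.30, 0.0),
}


@dataclass(frozen=True)
class ParticleSpec:
    """One particle with its class, true potencies and endotoxin load.

    ``true_beta`` maps qualified endpoint keys ("unit/endpoint") to the
    dimensionless slope used for simulation.  ``endotoxin`` is EU per ug of
    particle; ``None`` means not detectable.
    """

    name: str
    particle_class: str
    true_beta: dict[str, float]
    endotoxin: float | None = None

    def __post_init__(self):
        if self.particle_class not in (URBAN_COARSE, URBAN_FINE, MINERAL):
            raise ConfigurationError(
                f"unknown particle class {self.particle_class!r}"
            )
        if self.endotoxin is not None and self.endotoxin < 0:
            raise ConfigurationError("endotoxin must be >= 0 when detectable")


@dataclass
class SyntheticDataset:
    """Simulated measurements plus the ground truth that produced them."""

    measurements: pd.DataFrame
    truth: pd.DataFrame  # columns: particle, unit, endpoint, beta_true
    seed: int

    def truth_lookup(self) -> dict[tuple[str, str], float]:
        return {
            (r.particle, endpoint_key(r.unit, r.endpoint)): r.beta_true
            for r in self.truth.itertuples()
        }


def _beta_range(ranges: dict, key: str, role: str) -> tuple[float, float]:
    lo, hi = ranges.get(key, ranges.get(role, (0.0, 0.0)))
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ConfigurationError(f"beta range for {key or role!r} is not finite")
    if lo > hi:
        raise ConfigurationError(
            f"invalid beta range for {key or role!r}: low {lo} > high {hi}"
        )
    return lo, hi


def generate_particle_panel(
    n_urban: int = 6,
    n_mineral: int = 2,
    beta_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    endpoint_roles: dict[str, str] | None = None,
) -> list[ParticleSpec]:
    """Draw a reproducible particle panel with known true potencies.

    Urban particles receive endotoxin within the observed span of urban dust
    stocks; when two or more urban particles are requested, the last one is
    a fine (PM2.5-like) particle and one urban particle is pinned at the low
    value of 3.0 EU/ug, emulating a low-endotoxin archival urban dust.
    Mineral particles have no detectable endotoxin.

    ``endpoint_roles`` maps qualified endpoint keys to roles and defaults to
    the union of the default in vitro and in vivo designs.
    """
    if n_urban < 0 or n_mineral < 0:
        raise ConfigurationError("particle counts must be >= 0")
    ranges = dict(DEFAULT_BETA_RANGES)
    if beta_ranges:
        ranges.update(beta_ranges)
    if endpoint_roles is None:
        endpoint_roles = {
            **default_invitro_design().roles(),
            **default_invivo_design().roles(),
        }
    # Validate all ranges up front so misconfiguration fails fast.
    for key, role in endpoint_roles.items():
        _beta_range(ranges, key, role)

    rng = np.random.default_rng(seed)
    panel: list[ParticleSpec] = []

    def draw_betas() -> dict[str, float]:
        return {
            key: float(rng.uniform(*_beta_range(ranges, key, role)))
            for key, role in endpoint_roles.items()
        }

    for i in range(n_urban):
        is_fine = n_urban >= 2 and i == n_urban - 1
        cls = URBAN_FINE if is_fine else URBAN_COARSE
        if i == n_urban - 2 or n_urban == 1:
            endotoxin = LOW_ENDOTOXIN_URBAN
        else:
            endotoxin = float(rng.uniform(*ENDOTOXIN_SPAN))
        panel.append(
            ParticleSpec(f"URB-{i + 1}", cls, draw_betas(), endotoxin)
        )
    for i in range(n_mineral):
        panel.append(ParticleSpec(f"MIN-{i + 1}", MINERAL, draw_betas(), None))
    return panel


def panel_from_scores(
    scores: dict[str, float],
    endpoint_roles: dict[str, str],
    role_coefficients: dict[str, float] | None = None,
    particle_class: str = URBAN_COARSE,
    endotoxin: float | None = None,
) -> list[ParticleSpec]:
    """Build a panel whose every true beta is proportional to one scalar
    potency score per particle.

    Useful for ground-truth concordance studies: every integrated index is
    then a fixed positive multiple of the score, so in vitro and in vivo
    rankings coincide by construction.  ``role_coefficients`` maps roles (or
    qualified endpoint keys, which take precedence) to the multiplier
    applied to the score.
    """
    coeffs = {
        ROLE_VIABILITY: -0.2,
        ROLE_PRO: 0.5,
        ROLE_ANTI: 0.5,
        ROLE_DUAL: 0.5,
        ROLE_AHR: 1.0,
        ROLE_TOXICITY: 0.3,
        "BALB_c/macrophages": -0.3,
    }
    if role_coefficients:
        coeffs.update(role_coefficients)
    panel = []
    for name, s in scores.items():
        betas = {
            key: coeffs.get(key, coeffs[role]) * s
            for key, role in endpoint_roles.items()
        }
        panel.append(ParticleSpec(name, particle_class, betas, endotoxin))
    return panel


def simulate_measurements(
    design: StudyDesign, panel: list[ParticleSpec], seed: int = 0
) -> SyntheticDataset:
    """Simulate the full measurement table implied by a design and panel.

    Each experiment carries one pooled set of dose-0 control records
    (particle label ``control-buffer``); treated records cover every
    particle x nonzero dose x replicate cell exactly once.
    """
    if not panel:
        raise ConfigurationError("particle panel is empty")
    for p in panel:
        for e in design.endpoints:
            if e.key not in p.true_beta:
                raise DesignMismatchError(
                    f"particle {p.name!r} has no true beta for endpoint {e.key!r}"
                )

    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    doses = [d for d in design.dose_grid if d > 0]
    for exp in range(1, design.n_experiments + 1):
        for e in design.endpoints:
            for rep in range(1, design.n_replicates + 1):
                noise = np.exp(rng.normal(0.0, e.noise_sigma)) if e.noise_sigma else 1.0
                rows.append(
                    (design.model, e.unit, e.name, CONTROL_LABEL, 0.0, exp, rep,
                     e.baseline * noise)
                )
            for p in panel:
                beta = p.true_beta[e.key]
                for dose in doses:
                    mean = e.baseline * (dose + 1.0) ** beta
                    for rep in range(1, design.n_replicates + 1):
                        noise = (
                            np.exp(rng.normal(0.0, e.noise_sigma))
                            if e.noise_sigma
                            else 1.0
                        )
                        rows.append(
                            (design.model, e.unit, e.name, p.name, dose, exp, rep,
                             mean * noise)
                        )
    for p in panel:
        for e in design.endpoints:
            truth_rows.append((p.name, e.unit, e.name, p.true_beta[e.key]))

    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["particle", "unit", "endpoint", "beta_true"]
    )
    return SyntheticDataset(measurements, truth, seed)


def simulate_nondetects(
    dataset: SyntheticDataset, nd_endpoints: list[str]
) -> SyntheticDataset:
    """Mark whole endpoints as below detection (value -> NaN).

    ``nd_endpoints`` entries may be qualified ("unit/endpoint") or bare
    endpoint names, which match the endpoint in every unit.  The record
    count is unchanged; only values are replaced by the missing marker.
    """
    df = dataset.measurements.copy()
    keys = df["unit"].str.cat(df["endpoint"], sep="/")
    for nd in nd_endpoints:
        mask = (keys == nd) if "/" in nd else (df["endpoint"] == nd)
        if not mask.any():
            raise ConfigurationError(f"unknown endpoint id {nd!r}")
        df.loc[mask, "value"] = np.nan
    return SyntheticDataset(df, dataset.truth.copy(), dataset.seed)


def panel_metadata(panel: list[ParticleSpec]) -> pd.DataFrame:
    """Particle metadata table: name, class, endotoxin (NaN if not detectable)."""
    return pd.DataFrame(
        {
            "particle": [p.name for p in panel],
            "particle_class": [p.particle_class for p in panel],
            "endotoxin_eu_per_ug": [
                np.nan if p.endotoxin is None else p.endotoxin for p in panel
            ],
        }
    )
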