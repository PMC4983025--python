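"""Study designs: which endpoints are measured, at which doses, how often.

A :class:`StudyDesign` describes one exposure model — either cultured cells
(`in_vitro`) dosed on multiwell plates, or animals (`in_vivo`) receiving an
intratracheal instillation — as a list of endpoints with baselines and
log-scale noise levels, a dose grid, and a replication structure.  The
defaults emulate a typical particulate-matter screening study: two cell
lines (an alveolar epithelial line and a macrophage line) assayed for four
viability endpoints and a cytokine panel each, a reporter line for
Ah-receptor (AhR) activation, and a mouse model with bronchoalveolar-lavage
(BAL) toxicity markers and cytokines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Endpoint roles drive sign conventions and aggregation downstream.
ROLE_VIABILITY = "viability"
ROLE_PRO = "pro_inflammatory"
ROLE_ANTI = "anti_inflammatory"
ROLE_DUAL = "dual_inflammatory"
ROLE_AHR = "ahr"
ROLE_TOXICITY = "toxicity_marker"

ROLES = frozenset(
    {ROLE_VIABILITY, ROLE_PRO, ROLE_ANTI, ROLE_DUAL, ROLE_AHR, ROLE_TOXICITY}
)

IN_VITRO = "in_vitro"
IN_VIVO = "in_vivo"


def endpoint_key(unit: str, endpoint: str) -> str:
    """Qualified endpoint identifier, unique across units."""
    return f"{unit}/{endpoint}"


@dataclass(frozen=True)
class EndpointSpec:
    """One measured endpoint within one unit (cell line or strain).

    baseline is the expected control-level reading in `baseline_units`;
    noise_sigma is the standard deviation of multiplicative lognormal
    measurement noise on the natural-log scale.
    """

    unit: str
    name: str
    role: str
    baseline: float
    baseline_units: str = "pg/mL"
    noise_sigma: float = 0.2

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown endpoint role {self.role!r}")
        if not self.baseline > 0:
            raise ValueError(f"baseline must be > 0 for {self.key}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0 for {self.key}")

    @property
    def key(self) -> str:
        return endpoint_key(self.unit, self.name)


@dataclass(frozen=True)
class StudyDesign:
    """Replication structure of one exposure model.

    For in vitro designs ``n_experiments`` is the number of independent
    experiments and ``n_replicates`` the number of wells per dose within an
    experiment.  For in vivo designs ``n_experiments`` is the number of
    cohorts and ``n_replicates`` the number of animals per dose.
    """

    model: str
    endpoints: tuple[EndpointSpec, ...]
    dose_grid: tuple[float, ...]
    n_experiments: int = 3
    n_replicates: int = 3

    def __post_init__(self):
        if self.model not in (IN_VITRO, IN_VIVO):
            raise ValueError(f"model must be in_vitro or in_vivo, got {self.model!r}")
        if not self.endpoints:
            raise ValueError("design needs at least one endpoint")
        if len(self.dose_grid) < 2 or self.dose_grid[0] != 0:
            raise ValueError("dose_grid must start at 0 and contain >= 2 doses")
        if any(b >= a for a, b in zip(self.dose_grid[1:], self.dose_grid[:-1])):
            raise ValueError("dose_grid must be strictly increasing")
        if self.n_experiments < 1 or self.n_replicates < 1:
            raise ValueError("n_experiments and n_replicates must be >= 1")
        keys = [e.key for e in self.endpoints]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate endpoint keys in design")

    @property
    def units(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.endpoints:
            seen.setdefault(e.unit, None)
        return tuple(seen)

    @property
    def endpoint_keys(self) -> tuple[str, ...]:
        return tuple(e.key for e in self.endpoints)

    def roles(self) -> dict[str, str]:
        """Mapping of qualified endpoint key to its role."""
        return {e.key: e.role for e in self.endpoints}


# ---------------------------------------------------------------------------
# Default designs.  Cytokine baselines are typical control-supernatant levels
# (pg/mL); viability-assay baselines are arbitrary instrument units, which is
# immaterial downstream because fold-effect normalization cancels them.
# ---------------------------------------------------------------------------

VIABILITY_ASSAYS = ("LDH", "resazurin", "ATP", "BrdU")

A549_CYTOKINES = {
    "GM-CSF": 2.8,
    "IL-1b": 0.13,
    "IL-6": 430.0,
    "IL-8": 200.0,
    "IL-10": 12.5,
    "MCP-1": 701.5,
    "MIP-1b": 0.9,
    "TNF-a": 0.1,
}

J774_CYTOKINES = {
    "GM-CSF": 9.4,
    "IL-1a": 1.2,
    "IL-1b": 5.9,
    "IL-6": 9.2,
    "IL-10": 12.5,
    "RANTES": 239.0,
    "TNF-a": 3.7,
}

BAL_TOXICITY_MARKERS = {
    # marker -> (baseline, units)
    "protein": (150.0, "ug/mL"),
    "LDH": (50.0, "U/L"),
    "8-isoprostane": (30.0, "pg/mL"),
    "neutrophils": (2.0e4, "cells"),
    "macrophages": (3.0e5, "cells"),
    "band_cells": (1.0e3, "cells"),
    "lymphocytes": (5.0e3, "cells"),
}

BAL_CYTOKINES = {
    "IL-1a": 0.1,
    "IL-1b": 1.3,
    "IL-5": 0.5,
    "IL-6": 0.1,
    "IL-10": 0.3,
    "GM-CSF": 1.3,
    "KC": 3.8,
    "MIP-1a": 25.4,
    "RANTES": 0.3,
    "TNF-a": 3.7,
}

AHR_UNIT = "H1L1.1c2"
AHR_ENDPOINT = "AhR-luciferase"
IN_VIVO_UNIT = "BALB_c"

DEFAULT_INVITRO_DOSES = (0.0, 10.0, 20.0, 40.0, 80.0, 160.0)
DEFAULT_INVIVO_DOSES = (0.0, 50.0, 100.0, 250.0)


def _cytokine_role(name: str) -> str:
    if name == "IL-10":
        return ROLE_ANTI
    if name == "IL-6":
        return ROLE_DUAL
    return ROLE_PRO


def default_invitro_design(
    noise_sigma: float = 0.2,
    n_experiments: int = 3,
    n_replicates: int = 3,
    dose_grid: tuple[float, ...] = DEFAULT_INVITRO_DOSES,
) -> StudyDesign:
    """Two cell lines with viability + cytokine panels, plus an AhR reporter."""
    endpoints: list[EndpointSpec] = []
    for unit, cytokines in (("A549", A549_CYTOKINES), ("J774A.1", J774_CYTOKINES)):
        for assay in VIABILITY_ASSAYS:
            endpoints.append(
                EndpointSpec(unit, assay, ROLE_VIABILITY, 100.0, "AU", noise_sigma)
            )
        for name, baseline in cytokines.items():
            endpoints.append(
                EndpointSpec(unit, name, _cytokine_role(name), baseline, "pg/mL", noise_sigma)
            )
    endpoints.append(
        EndpointSpec(AHR_UNIT, AHR_ENDPOINT, ROLE_AHR, 1000.0, "RLU", noise_sigma)
    )
    return StudyDesign(
        IN_VITRO, tuple(endpoints), tuple(dose_grid), n_experiments, n_replicates
    )


def default_invivo_design(
    noise_sigma: float = 0.2,
    n_cohorts: int = 1,
    n_animals_per_dose: int = 5,
    dose_grid: tuple[float, ...] = DEFAULT_INVIVO_DOSES,
) -> StudyDesign:
    """Mouse instillation model: BAL toxicity markers and cytokines."""
    endpoints: list[EndpointSpec] = []
    for name, (baseline, units) in BAL_TOXICITY_MARKERS.items():
        endpoints.append(
            EndpointSpec(IN_VIVO_UNIT, name, ROLE_TOXICITY, baseline, units, noise_sigma)
        )
    for name, baseline in BAL_CYTOKINES.items():
        endpoints.append(
            EndpointSpec(IN_VIVO_UNIT, name, _cytokine_role(name), baseline, "pg/mL", noise_sigma)
        )
    return StudyDesign(
        IN_VIVO, tuple(endpoints), tuple(dose_grid), n_cohorts, n_animals_per_dose
    )
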