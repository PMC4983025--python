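"""Hierarchical integration of endpoint potencies into consensus indices.

Endpoint-level slopes are combined by plain arithmetic means into a small
hierarchy of per-particle indices:

* beta_V per cell line — mean slope across the viability assays; beta_V
  CELLS averages the cell lines.
* beta_R per cell line — mean |slope| across viability assays ("biological
  reactivity": any deviation from baseline counts); beta_R CELLS averages
  the cell lines plus, optionally, the rescaled AhR reporter slope.
* beta_I-V HI / LO per cell line — signed mean of viability-adjusted
  cytokine slopes.  IL-10 always counts anti-inflammatory (sign -1); the
  pleiotropic IL-6 counts pro-inflammatory (+1) in the HI scenario and
  anti-inflammatory (-1) in the LO scenario.  The denominator is the number
  of non-missing cytokines and is identical for both scenarios.
* Ibeta — mean of reactivity and inflammation, per cell line and grand.
* In vivo: beta_T (sign-weighted mean of BAL toxicity markers, alveolar
  macrophage loss counting as increased potency), beta_I HI/LO over raw
  cytokine slopes (no viability adjustment exists in vivo), and
  Ibeta = mean(beta_T, beta_I).

Missing inputs shrink the averaging denominator; they are never
zero-filled, and input counts are reported alongside the indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import (
    ROLE_AHR,
    ROLE_ANTI,
    ROLE_DUAL,
    ROLE_PRO,
    ROLE_TOXICITY,
    ROLE_VIABILITY,
    StudyDesign,
)
from .exceptions import ConfigurationError, InsufficientDataError

HI = "HI"
LO = "LO"

CYTOKINE_ROLES = (ROLE_PRO, ROLE_ANTI, ROLE_DUAL)


def _bare(key: str) -> str:
    return key.split("/", 1)[1] if "/" in key else key


@dataclass
class ScenarioConfig:
    """Endpoint roles and sign/scale schemes for index aggregation.

    ``roles`` is keyed by qualified endpoint key ("unit/endpoint"); the sign
    maps are keyed by bare endpoint name (signs follow the cytokine, not the
    unit).  ``invivo_signs`` covers in vivo toxicity markers.
    """

    roles: dict[str, str]
    hi_signs: dict[str, int] = field(default_factory=dict)
    lo_signs: dict[str, int] = field(default_factory=dict)
    invivo_signs: dict[str, int] = field(default_factory=dict)
    ahr_factor: float = 20.0
    include_ahr_in_reactivity: bool = True
    ahr_abs_in_reactivity: bool = True

    def __post_init__(self):
        if not self.ahr_factor > 0:
            raise ConfigurationError("ahr_factor must be > 0")
        for key, role in self.roles.items():
            name = _bare(key)
            if role in CYTOKINE_ROLES:
                self.hi_signs.setdefault(name, -1 if role == ROLE_ANTI else +1)
                self.lo_signs.setdefault(
                    name, -1 if role in (ROLE_ANTI, ROLE_DUAL) else +1
                )
            elif role == ROLE_TOXICITY:
                # Loss of resident alveolar macrophages marks increased
                # potency, so its slope enters with sign -1.
                self.invivo_signs.setdefault(
                    name, -1 if name == "macrophages" else +1
                )
        for key, role in self.roles.items():
            name = _bare(key)
            if role == ROLE_ANTI and not (
                self.hi_signs.get(name) == -1 and self.lo_signs.get(name) == -1
            ):
                raise ConfigurationError(
                    f"anti-inflammatory endpoint {name!r} must carry sign -1 "
                    "in both scenarios"
                )
            if role == ROLE_DUAL and not (
                self.hi_signs.get(name) == +1 and self.lo_signs.get(name) == -1
            ):
                raise ConfigurationError(
                    f"dual endpoint {name!r} must carry +1 in HI and -1 in LO"
                )

    @classmethod
    def from_designs(cls, *designs: StudyDesign, **kwargs) -> "ScenarioConfig":
        roles: dict[str, str] = {}
        for d in designs:
            roles.update(d.roles())
        return cls(roles=roles, **kwargs)

    def signs(self, scenario: str) -> dict[str, int]:
        scenario = scenario.upper()
        if scenario == HI:
            return self.hi_signs
        if scenario == LO:
            return self.lo_signs
        raise ConfigurationError(f"unknown scenario {scenario!r}")

    def keys_with_role(self, role: str, unit: str | None = None) -> list[str]:
        return [
            k for k, r in self.roles.items()
            if r == role and (unit is None or k.startswith(unit + "/"))
        ]

    def cell_units(self) -> list[str]:
        seen: dict[str, None] = {}
        for k, r in self.roles.items():
            if r == ROLE_VIABILITY:
                seen.setdefault(k.split("/", 1)[0], None)
        return list(seen)


def _finite(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[np.isfinite(arr)]


def combine_viability(per_assay: Iterable[float]) -> float:
    """Mean slope across a unit's viability assays (beta_V)."""
    arr = _finite(per_assay)
    if arr.size == 0:
        raise InsufficientDataError(message="no finite viability potencies")
    return float(arr.mean())


def combine_reactivity(per_assay: Iterable[float]) -> float:
    """Mean absolute slope across viability assays (beta_R): any deviation
    from baseline control levels counts as biological activity."""
    arr = _finite(per_assay)
    if arr.size == 0:
        raise InsufficientDataError(message="no finite reactivity inputs")
    return float(np.abs(arr).mean())


def combine_reactivity_cells(
    beta_r_by_unit: Mapping[str, float],
    beta_ahr: float | None,
    config: ScenarioConfig,
) -> float:
    """Cross-cell-line reactivity: mean of per-unit beta_R values plus,
    when configured, the AhR reporter slope divided by ``ahr_factor``
    (taken absolute when ``ahr_abs_in_reactivity``)."""
    terms = list(_finite(beta_r_by_unit.values()))
    if config.include_ahr_in_reactivity and beta_ahr is not None and np.isfinite(beta_ahr):
        term = beta_ahr / config.ahr_factor
        terms.append(abs(term) if config.ahr_abs_in_reactivity else term)
    if not terms:
        raise InsufficientDataError(message="no finite reactivity inputs")
    return float(np.mean(terms))


def combine_inflammation(
    beta_iv_by_cytokine: Mapping[str, float],
    config: ScenarioConfig | Mapping[str, int],
    scenario: str = HI,
) -> float:
    """Signed mean of per-cytokine potencies for one HI/LO scenario.

    The denominator is the count of non-missing cytokines, identical for HI
    and LO, so HI - LO = 2 * beta_IL6 / n by construction.
    """
    signs = (
        config.signs(scenario) if isinstance(config, ScenarioConfig) else dict(config)
    )
    total, n = 0.0, 0
    for key, beta in beta_iv_by_cytokine.items():
        name = _bare(key)
        if name not in signs:
            raise ConfigurationError(
                f"cytokine {name!r} has no sign in scenario {scenario}"
            )
        if beta is None or not np.isfinite(beta):
            continue
        total += signs[name] * beta
        n += 1
    if n == 0:
        raise InsufficientDataError(message="no finite cytokine potencies")
    return total / n


def integrate_unit(beta_r: float, beta_iv: float) -> float:
    """Integrated potency Ibeta: mean of reactivity and inflammation."""
    return (beta_r + beta_iv) / 2.0


def combine_invivo_toxicity(
    endpoint_betas: Mapping[str, float], signs: Mapping[str, int]
) -> float:
    """Sign-weighted mean of BAL toxicity-marker slopes (beta_T)."""
    total, n = 0.0, 0
    for key, beta in endpoint_betas.items():
        name = _bare(key)
        if name not in signs:
            raise ConfigurationError(f"toxicity marker {name!r} has no sign")
        if beta is None or not np.isfinite(beta):
            continue
        total += signs[name] * beta
        n += 1
    if n == 0:
        raise InsufficientDataError(message="no finite toxicity-marker potencies")
    return total / n


def combine_invivo_inflammation(
    cytokine_betas: Mapping[str, float],
    config: ScenarioConfig | Mapping[str, int],
    scenario: str = HI,
) -> float:
    """In vivo inflammation index on raw cytokine slopes (no viability
    adjustment exists in vivo); otherwise identical to
    :func:`combine_inflammation`."""
    return combine_inflammation(cytokine_betas, config, scenario)


def rank_particles(
    values: Mapping[str, float] | pd.Series, direction: str = "potent_first"
) -> pd.Series:
    """Rank particles, 1 = most potent (largest value); ties take midranks."""
    if direction != "potent_first":
        raise ConfigurationError(f"unknown ranking direction {direction!r}")
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise InsufficientDataError(message="ranking needs at least 2 particles")
    ranks = rankdata(-s.to_numpy(), method="average")
    return pd.Series(ranks, index=s.index, name="rank")


# ---------------------------------------------------------------------------
# Table-level integration
# ---------------------------------------------------------------------------

def _beta_lookup(potencies: pd.DataFrame) -> dict[tuple[str, str, str], float]:
    return {
        (r.particle, r.unit, r.endpoint): r.beta for r in potencies.itertuples()
    }


def _nan_on_insufficient(fn, *args, **kwargs) -> float:
    try:
        return fn(*args, **kwargs)
    except InsufficientDataError:
        return float("nan")


def integrate_invitro(
    potencies: pd.DataFrame, config: ScenarioConfig
) -> pd.DataFrame:
    """Per-particle in vitro index table from an endpoint potency table.

    ``potencies`` is the long table produced by :func:`pmpotency.potency.fit_all`
    (columns particle, unit, endpoint, beta ...).  Returns one row per
    particle with per-unit and combined indices plus input counts.
    """
    betas = _beta_lookup(potencies)
    particles = list(dict.fromkeys(potencies["particle"]))
    units = config.cell_units()
    ahr_keys = config.keys_with_role(ROLE_AHR)

    rows = []
    for particle in particles:
        row: dict[str, float] = {"particle": particle}
        per_unit_r: dict[str, float] = {}
        per_unit_hi: dict[str, float] = {}
        per_unit_lo: dict[str, float] = {}
        per_unit_v: dict[str, float] = {}
        for unit in units:
            viab = {
                k: betas.get((particle, unit, _bare(k)), np.nan)
                for k in config.keys_with_role(ROLE_VIABILITY, unit)
            }
            beta_v = _nan_on_insufficient(combine_viability, viab.values())
            beta_r = _nan_on_insufficient(combine_reactivity, viab.values())
            cyto_keys = [
                k for role in CYTOKINE_ROLES
                for k in config.keys_with_role(role, unit)
            ]
            beta_iv = {
                k: betas.get((particle, unit, _bare(k)), np.nan) - beta_v
                for k in cyto_keys
            }
            hi = _nan_on_insufficient(combine_inflammation, beta_iv, config, HI)
            lo = _nan_on_insufficient(combine_inflammation, beta_iv, config, LO)
            per_unit_v[unit] = beta_v
            per_unit_r[unit] = beta_r
            per_unit_hi[unit] = hi
            per_unit_lo[unit] = lo
            row[f"beta_v_{unit}"] = beta_v
            row[f"beta_r_{unit}"] = beta_r
            row[f"beta_iv_hi_{unit}"] = hi
            row[f"beta_iv_lo_{unit}"] = lo
            row[f"ibeta_hi_{unit}"] = integrate_unit(beta_r, hi)
            row[f"ibeta_lo_{unit}"] = integrate_unit(beta_r, lo)
            row[f"n_viability_{unit}"] = int(len(_finite(viab.values())))
            row[f"n_cytokines_{unit}"] = int(
                np.isfinite(list(beta_iv.values())).sum()
            )

        beta_ahr = np.nan
        if ahr_keys:
            k = ahr_keys[0]
            unit_a, name_a = k.split("/", 1)
            beta_ahr = betas.get((particle, unit_a, name_a), np.nan)
        row["beta_ahr"] = beta_ahr
        row["beta_ahr_scaled"] = beta_ahr / config.ahr_factor

        row["beta_v_cells"] = _nan_on_insufficient(
            combine_viability, per_unit_v.values()
        )
        row["beta_r_cells"] = _nan_on_insufficient(
            combine_reactivity_cells, per_unit_r, beta_ahr, config
        )
        hi_vals = _finite(per_unit_hi.values())
        lo_vals = _finite(per_unit_lo.values())
        row["beta_iv_hi"] = float(hi_vals.mean()) if hi_vals.size else np.nan
        row["beta_iv_lo"] = float(lo_vals.mean()) if lo_vals.size else np.nan
        row["beta_iv_cells"] = (row["beta_iv_hi"] + row["beta_iv_lo"]) / 2.0
        row["ibeta_hi"] = integrate_unit(row["beta_r_cells"], row["beta_iv_hi"])
        row["ibeta_lo"] = integrate_unit(row["beta_r_cells"], row["beta_iv_lo"])
        row["ibeta"] = (row["ibeta_hi"] + row["ibeta_lo"]) / 2.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("particle")


def integrate_invivo(
    potencies: pd.DataFrame, config: ScenarioConfig
) -> pd.DataFrame:
    """Per-particle in vivo index table (beta_T, beta_I HI/LO, Ibeta)."""
    betas = _beta_lookup(potencies)
    particles = list(dict.fromkeys(potencies["particle"]))
    tox_keys = config.keys_with_role(ROLE_TOXICITY)
    cyto_keys = [
        k for role in CYTOKINE_ROLES for k in config.keys_with_role(role)
        if k in {f"{r.unit}/{r.endpoint}" for r in potencies.itertuples()}
    ]

    rows = []
    for particle in particles:
        def grab(keys):
            out = {}
            for k in keys:
                unit, name = k.split("/", 1)
                out[k] = betas.get((particle, unit, name), np.nan)
            return out

        tox = grab(tox_keys)
        cyto = grab(cyto_keys)
        beta_t = _nan_on_insufficient(
            combine_invivo_toxicity, tox, config.invivo_signs
        )
        hi = _nan_on_insufficient(combine_invivo_inflammation, cyto, config, HI)
        lo = _nan_on_insufficient(combine_invivo_inflammation, cyto, config, LO)
        beta_i = (hi + lo) / 2.0
        rows.append(
            {
                "particle": particle,
                "beta_t": beta_t,
                "beta_i_hi": hi,
                "beta_i_lo": lo,
                "beta_i": beta_i,
                "ibeta_invivo": (beta_t + beta_i) / 2.0,
                "n_toxicity": int(np.isfinite(list(tox.values())).sum()),
                "n_cytokines": int(np.isfinite(list(cyto.values())).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("particle")


def wide_potency_matrix(potencies: pd.DataFrame, value: str = "beta") -> pd.DataFrame:
    """Heatmap-ready wide matrix: particles x (unit, endpoint) slopes."""
    return potencies.pivot_table(
        index="particle", columns=["unit", "endpoint"], values=value
    )
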