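"""Ground-truth calibration studies for the whole pipeline.

These routines exercise the full chain (simulate -> fold-effect -> fit ->
integrate -> correlate) against known truths and summarize how well it
recovers them: estimator bias and RMSE under repeated noisy simulation, and
rank concordance on a noise-free study whose in vivo potencies are a
monotone transform of the in vitro ones (so perfect concordance is the
correct answer).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_INVITRO_DOSES,
    IN_VITRO,
    EndpointSpec,
    StudyDesign,
    default_invitro_design,
    default_invivo_design,
)
from .foldeffect import compute_fold_effect
from .integrate import ScenarioConfig, integrate_invitro, integrate_invivo, rank_particles
from .association import concordance_table
from .potency import fit_all
from .simulate import ParticleSpec, generate_particle_panel, panel_from_scores, simulate_measurements


def _compact_design(noise_sigma: float, n_replicates: int) -> StudyDesign:
    """One unit, three endpoints, the default dose grid and 3 experiments —
    the replicate structure that drives estimator precision."""
    endpoints = (
        EndpointSpec("U", "E1", "pro_inflammatory", 100.0, "pg/mL", noise_sigma),
        EndpointSpec("U", "E2", "viability", 100.0, "AU", noise_sigma),
        EndpointSpec("U", "E3", "anti_inflammatory", 50.0, "pg/mL", noise_sigma),
    )
    return StudyDesign(IN_VITRO, endpoints, DEFAULT_INVITRO_DOSES, 3, n_replicates)


def recovery_study(
    n_sims: int = 200,
    n_replicates: int = 3,
    noise_sigma: float = 0.2,
    seed: int = 0,
) -> dict[str, float]:
    """Repeatedly simulate, fit, and compare fitted slopes to the truth.

    Returns mean bias (fitted minus true), RMSE, and the number of fits.
    Each repetition draws a fresh 2-particle panel and noise realization.
    """
    design = _compact_design(noise_sigma, n_replicates)
    errs: list[float] = []
    for i in range(n_sims):
        panel = generate_particle_panel(
            2, 0, seed=seed + i, endpoint_roles=design.roles()
        )
        ds = simulate_measurements(design, panel, seed=seed + 100_000 + i)
        pot = fit_all(compute_fold_effect(ds.measurements))
        merged = pot.merge(ds.truth, on=["particle", "unit", "endpoint"])
        errs.extend((merged["beta"] - merged["beta_true"]).tolist())
    arr = np.asarray(errs)
    return {
        "bias": float(arr.mean()),
        "rmse": float(np.sqrt((arr**2).mean())),
        "n_fits": int(arr.size),
    }


def zero_noise_concordance_study(
    scores: dict[str, float] | None = None,
    invivo_transform: Callable[[float], float] = lambda s: s**1.5,
) -> pd.DataFrame:
    """Noise-free end-to-end study with proportional truths.

    Every in vitro true slope is a fixed multiple of a per-particle potency
    score; in vivo true slopes use a strictly monotone transform of the same
    scores.  Under these conditions the in vitro and in vivo integrated
    indices rank the particles identically, so every Spearman coefficient in
    the returned concordance table should equal 1 exactly.
    """
    if scores is None:
        scores = {"P1": 0.2, "P2": 0.5, "P3": 0.8, "P4": 1.1, "P5": 1.4}
    d_vitro = default_invitro_design(noise_sigma=0.0)
    d_vivo = default_invivo_design(noise_sigma=0.0)
    panel_vitro = panel_from_scores(scores, d_vitro.roles())
    panel_vivo = panel_from_scores(
        {k: invivo_transform(v) for k, v in scores.items()}, d_vivo.roles()
    )
    panel = [
        ParticleSpec(pv.name, pv.particle_class, {**pv.true_beta, **pw.true_beta})
        for pv, pw in zip(panel_vitro, panel_vivo)
    ]
    scenario = ScenarioConfig(roles={**d_vitro.roles(), **d_vivo.roles()})
    fits = {}
    for design in (d_vitro, d_vivo):
        ds = simulate_measurements(design, panel, seed=0)
        fits[design.model] = fit_all(compute_fold_effect(ds.measurements))
    invitro_idx = integrate_invitro(fits["in_vitro"], scenario)
    invivo_idx = integrate_invivo(fits["in_vivo"], scenario)
    table = concordance_table(invitro_idx, invivo_idx)
    table.attrs["rank_invitro"] = rank_particles(invitro_idx["ibeta"]).to_dict()
    table.attrs["rank_invivo"] = rank_particles(invivo_idx["ibeta_invivo"]).to_dict()
    return table
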