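"""Fold-effect normalization over pooled within-experiment controls.

Every raw value is divided by the grand mean of the dose-0 values measured
in the same experiment for the same endpoint and unit, producing the
dimensionless fold-effect (FE) consumed by all potency fits.  Dose-0
records are normalized too, so their FE averages exactly 1 within an
experiment; rescaling all values of an experiment by a positive constant
leaves every FE unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import MissingControlsError, ValidationError

logger = logging.getLogger(__name__)

POOLED = "pooled"
PER_PARTICLE = "per_particle"


def compute_fold_effect(
    measurements: pd.DataFrame, pooling: str = POOLED
) -> pd.DataFrame:
    """Append an ``fe`` column: value over the within-experiment control mean.

    pooling="pooled" (default): controls are all dose-0 records of the same
    (unit, endpoint, experiment), shared across particles — one pooled
    control set per plate.  pooling="per_particle": controls are matched by
    particle as well, for designs with particle-specific vehicle controls.

    Missing values are excluded from control means and propagate as missing
    FE.  An experiment with no dose-0 records raises
    :class:`MissingControlsError`; if all its controls are missing (e.g. a
    non-detect endpoint) the whole group's FE is set missing with a logged
    warning, so downstream fits report an explicit insufficient-data outcome
    rather than a silently absent series.
    """
    if pooling not in (POOLED, PER_PARTICLE):
        raise ValidationError(f"unknown pooling policy {pooling!r}")
    required = {"unit", "endpoint", "experiment", "dose_ug", "value"}
    missing_cols = required - set(measurements.columns)
    if missing_cols:
        raise ValidationError(f"measurement table lacks columns {sorted(missing_cols)}")

    df = measurements.copy()
    group_cols = ["unit", "endpoint", "experiment"]
    if pooling == PER_PARTICLE:
        group_cols.append("particle")

    out_frames: list[pd.DataFrame] = []
    for key, grp in df.groupby(group_cols, sort=False):
        controls = grp.loc[grp["dose_ug"] == 0, "value"]
        if controls.empty:
            kd = dict(zip(group_cols, key))
            raise MissingControlsError(
                kd["experiment"], kd.get("unit"), kd.get("endpoint")
            )
        control_mean = controls.mean(skipna=True)
        if np.isnan(control_mean):
            kd = dict(zip(group_cols, key))
            logger.warning(
                "all dose-0 controls missing for %s; %d records get missing "
                "fold-effect", kd, len(grp),
            )
            grp = grp.copy()
            grp["fe"] = np.nan
            out_frames.append(grp)
            continue
        if control_mean <= 0:
            kd = dict(zip(group_cols, key))
            raise ValidationError(f"non-positive control mean for {kd}")
        grp = grp.copy()
        grp["fe"] = grp["value"] / control_mean
        out_frames.append(grp)

    if not out_frames:
        raise ValidationError("no usable records after control normalization")
    out = pd.concat(out_frames).sort_index()
    return out


def control_fe_means(fe_table: pd.DataFrame) -> pd.DataFrame:
    """Mean FE of dose-0 records per (unit, endpoint, experiment).

    Equals 1 exactly by construction under pooled normalization; exposed as
    a diagnostic for validation reports.
    """
    ctl = fe_table[fe_table["dose_ug"] == 0]
    return (
        ctl.groupby(["unit", "endpoint", "experiment"])["fe"]
        .mean()
        .reset_index(name="control_fe_mean")
    )
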