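"""Group-level aggregation: summary tables and pooled means.

The summary table mirrors the six-cell layout (two implantation groups
× three MRI time points) with one mean ± SD pair per cell: each
subject's axial distribution of a parameter is averaged along the
spine, and cells aggregate those per-subject scalars. Pooled (grand)
means average the six cell means, which for balanced groups equals the
all-animal, all-timepoint average.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flow import FlowField, summarize_flow
from .hydrodynamics import dimensionless_numbers, mean_velocities
from .types import FluidProperties, NerveRootModel, ValidationError

__all__ = [
    "pooled_means",
    "subject_parameter_profile",
    "cohort_summary",
    "PARAMETER_UNITS",
]

PARAMETER_UNITS = {
    "P_c": "mm", "P_d": "mm", "P_sas": "mm",
    "A_c": "mm^2", "A_d": "mm^2", "A_sas": "mm^2",
    "SA_c": "cm^2", "SA_d": "cm^2", "SA_sas": "cm^2",
    "V_c": "mL", "V_d": "mL", "V_sas": "mL",
    "D_h": "mm", "Re": "-", "alpha": "-",
    "U_peak_sys": "cm/s", "U_peak_dia": "cm/s",
    "Q_peak_sys": "mL/s", "Q_peak_dia": "mL/s",
    "Q_a": "mL/s", "SV": "mL", "PWV": "m/s",
}


def pooled_means(summary_long: pd.DataFrame,
                 parameters: Sequence[str] | None = None) -> pd.Series:
    """Grand mean of the six group × time-point cell means per parameter.

    ``summary_long`` is the long-format summary layout (columns
    parameter, group, timepoint, mean, sd).
    """
    required = {"parameter", "mean"}
    if not required <= set(summary_long.columns):
        raise ValidationError("summary table must have 'parameter' and 'mean' columns")
    sub = summary_long
    if parameters is not None:
        sub = sub[sub["parameter"].isin(parameters)]
    return sub.groupby("parameter", sort=False)["mean"].mean()


def subject_parameter_profile(
    profile,
    field: FlowField,
    fluid: FluidProperties = FluidProperties(),
    nerve_roots: NerveRootModel = NerveRootModel(),
) -> pd.DataFrame:
    """Per-z values of the 13 battery parameters for one subject.

    Geometry comes on the subject's axial grid; flow-derived quantities
    exist only within the span of the measured levels and are
    interpolated onto the grid there (NaN outside, dropped downstream).
    Returns a DataFrame with columns z plus the 13 parameter names, and
    a ``PWV`` attribute in ``df.attrs``.
    """
    if not profile.derived:
        raise ValidationError("subject profile must have derived SAS columns")
    z = profile.grid.z
    fs = summarize_flow(field)
    in_span = (z >= field.z[0]) & (z <= field.z[-1])

    def onto_grid(values: np.ndarray) -> np.ndarray:
        out = np.full(z.shape, np.nan)
        out[in_span] = np.interp(z[in_span], fs.z, values)
        return out

    Q_sys, Q_dia = onto_grid(fs.Q_sys), onto_grid(fs.Q_dia)
    U_sys, U_dia = mean_velocities(Q_sys, Q_dia, profile.A_sas)
    hydro = dimensionless_numbers(U_sys, U_dia, profile.D_h, z, fluid, nerve_roots)
    df = pd.DataFrame(
        {
            "z": z,
            "A_d": profile.A_d,
            "A_c": profile.A_c,
            "A_sas": profile.A_sas,
            "P_d": profile.P_d,
            "P_c": profile.P_c,
            "P_sas": profile.P_sas,
            "D_h": profile.D_h,
            "alpha": hydro.alpha,
            "Re": hydro.Re,
            "U_peak_sys": U_sys,
            "U_peak_dia": U_dia,
            "Q_a": onto_grid(fs.Q_a),
            "SV": onto_grid(fs.SV),
        }
    )
    # flow-derived columns are undefined outside the measured span
    flow_cols = ["Re", "U_peak_sys", "U_peak_dia", "Q_a", "SV"]
    df.loc[~in_span, flow_cols] = np.nan
    df.attrs["PWV"] = fs.PWV
    return df


def cohort_summary(
    per_subject: Mapping[tuple[str, str, str], pd.DataFrame],
) -> pd.DataFrame:
    """Six-cell mean ± SD summary from per-subject parameter profiles.

    ``per_subject`` maps (subject_id, group, timepoint) to the
    per-z parameter DataFrame from :func:`subject_parameter_profile`.
    Each subject contributes its along-spine mean (and its PWV); cells
    aggregate subjects.
    """
    rows = []
    for (sid, group, timepoint), df in per_subject.items():
        means = df.drop(columns="z").mean(skipna=True)
        for param, value in means.items():
            rows.append(
                {"subject": sid, "group": group, "timepoint": timepoint,
                 "parameter": param, "value": value}
            )
        if "PWV" in df.attrs:
            rows.append(
                {"subject": sid, "group": group, "timepoint": timepoint,
                 "parameter": "PWV", "value": df.attrs["PWV"]}
            )
    long = pd.DataFrame(rows)
    agg = (
        long.groupby(["parameter", "group", "timepoint"], sort=False)["value"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"std": "sd"})
    )
    agg["unit"] = agg["parameter"].map(PARAMETER_UNITS).fillna("-")
    return agg[["parameter", "unit", "group", "timepoint", "mean", "sd"]]
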