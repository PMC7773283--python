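"""Linear mixed-effects comparison battery.

Each geometric or hydrodynamic parameter is measured at many axial
locations per animal, so per-animal measurements form a curve along the
spine. Differences between implantation groups or MRI time points are
tested with the mixed model

    y = β0 + β1·x1 + β2·x1² + β3·x2 + β4·age + β5·weight
        + z0 + z1·x1 + z2·x1² + ε,

where x1 is the normalized axial location, x2 a 0/1 indicator of the
cell being compared, and (z0, z1, z2) are per-animal random intercept,
slope and curvature with an unstructured 3×3 covariance. β3 is the
effect of interest; its Wald-z p-value is reported.

The full battery runs 7 pairwise comparisons (4 between time points
within group, 3 between groups within time point) for 13 parameters,
giving 91 p-values, Bonferroni-corrected at 0.05/91.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .types import SubjectRecord, ValidationError

__all__ = [
    "PARAMETERS",
    "COMPARISONS",
    "Comparison",
    "LMEFit",
    "ComparisonBattery",
    "assemble_long_table",
    "fit_lme",
    "run_battery",
    "simulate_comparison_table",
]

log = logging.getLogger(__name__)

#: The 13 parameters entering the battery.
PARAMETERS = (
    "A_d", "A_c", "A_sas", "P_d", "P_c", "P_sas",
    "D_h", "alpha", "Re", "U_peak_sys", "U_peak_dia", "Q_a", "SV",
)


@dataclass(frozen=True)
class Comparison:
    """One pairwise contrast: two (group, timepoint) cells.

    ``cell_a`` is the reference (x2 = 0), ``cell_b`` the comparison
    (x2 = 1); each cell is a (group, timepoint) pair.
    """

    name: str
    cell_a: tuple[str, str]
    cell_b: tuple[str, str]


#: The 7 comparisons: 4 time-point pairs within group, 3 group pairs
#: within time point.
COMPARISONS = (
    Comparison("PRE-2C vs POST-1C", ("cervical", "PRE-2"), ("cervical", "POST-1")),
    Comparison("PRE-2L vs POST-1L", ("lumbar", "PRE-2"), ("lumbar", "POST-1")),
    Comparison("PRE-2C vs POST-2C", ("cervical", "PRE-2"), ("cervical", "POST-2")),
    Comparison("PRE-2L vs POST-2L", ("lumbar", "PRE-2"), ("lumbar", "POST-2")),
    Comparison("PRE-2C vs PRE-2L", ("cervical", "PRE-2"), ("lumbar", "PRE-2")),
    Comparison("POST-1C vs POST-1L", ("cervical", "POST-1"), ("lumbar", "POST-1")),
    Comparison("POST-2C vs POST-2L", ("cervical", "POST-2"), ("lumbar", "POST-2")),
)

#: Star codes at Bonferroni-scaled levels (fractions of alpha / n_tests).
_STAR_LEVELS = ((0.001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class LMEFit:
    """Results of one mixed-model fit (statsmodels MixedLM, REML)."""

    parameter: str
    comparison: str
    fe_params: pd.Series  # β0..β5
    fe_bse: pd.Series
    cov_re: pd.DataFrame  # 3×3 random-effect covariance
    sigma2: float  # residual variance
    llf: float
    beta3: float
    se3: float
    pvalue: float  # Wald z on β3
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class ComparisonBattery:
    """13 × 7 grid of mixed-model contrasts with Bonferroni correction."""

    pvalues: pd.DataFrame  # parameters × comparisons
    stars: pd.DataFrame
    alpha: float
    threshold: float  # alpha / (n_params · n_comparisons)
    fits: dict[tuple[str, str], LMEFit]

    @property
    def n_tests(self) -> int:
        return self.pvalues.size


def assemble_long_table(
    values: Mapping[tuple[str, str], pd.DataFrame],
    subjects: Mapping[str, SubjectRecord] | Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Build the long-format table the mixed model consumes.

    Parameters
    ----------
    values
        ``(subject_id, timepoint) -> DataFrame`` with a ``z_norm``
        column (normalized axial location) and one column per parameter.
    subjects
        Metadata records; age and weight are required covariates.

    Returns a DataFrame with columns subject, group, timepoint, x1, age,
    weight, parameter, y. Rows with missing y are dropped (logged).
    """
    if not isinstance(subjects, Mapping):
        subjects = {s.id: s for s in subjects}
    rows = []
    for (sid, timepoint), df in values.items():
        if sid not in subjects:
            raise ValidationError(f"no metadata for subject {sid!r}")
        rec = subjects[sid]
        if not np.isfinite(rec.age) or not np.isfinite(rec.weight):
            raise ValidationError(f"subject {sid!r} lacks age/weight covariates")
        if "z_norm" not in df.columns:
            raise ValidationError("profile tables need a z_norm column")
        params = [c for c in df.columns if c != "z_norm"]
        melted = df.melt(id_vars="z_norm", value_vars=params,
                         var_name="parameter", value_name="y")
        melted["subject"] = sid
        melted["group"] = rec.group
        melted["timepoint"] = timepoint
        melted["age"] = rec.age
        melted["weight"] = rec.weight
        rows.append(melted.rename(columns={"z_norm": "x1"}))
    if not rows:
        raise ValidationError("no profile tables supplied")
    table = pd.concat(rows, ignore_index=True)
    n_missing = int(table["y"].isna().sum())
    if n_missing:
        log.info("dropping %d rows with missing parameter values", n_missing)
        table = table.dropna(subset=["y"]).reset_index(drop=True)
    dup = table.duplicated(subset=["subject", "timepoint", "x1", "parameter"])
    if dup.any():
        first = table[dup].iloc[0]
        raise ValidationError(
            "duplicate measurement for subject "
            f"{first['subject']!r} at timepoint {first['timepoint']!r}, "
            f"x1 = {first['x1']:g}, parameter {first['parameter']!r}"
        )
    return table[["subject", "group", "timepoint", "x1", "age", "weight",
                  "parameter", "y"]]


def _design(sub: pd.DataFrame, comparison: Comparison) -> tuple[pd.DataFrame, np.ndarray]:
    x1 = sub["x1"].to_numpy(dtype=float)
    span = x1.max() - x1.min()
    x1s = (x1 - x1.min()) / span if span > 0 else np.zeros_like(x1)
    in_b = (
        (sub["group"] == comparison.cell_b[0])
        & (sub["timepoint"] == comparison.cell_b[1])
    ).to_numpy()
    x2 = in_b.astype(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "x1": x1s,
            "x1_sq": x1s**2,
            "x2": x2,
            "age": sub["age"].to_numpy(dtype=float),
            "weight": sub["weight"].to_numpy(dtype=float),
        },
        index=sub.index,
    )
    Z = np.column_stack([np.ones_like(x1s), x1s, x1s**2])
    return X, Z


def fit_lme(table: pd.DataFrame, parameter: str, comparison: Comparison) -> LMEFit:
    """Fit the mixed model for one parameter and one pairwise comparison.

    The table is restricted to the comparison's two cells; β3 is the
    coefficient of the cell indicator. Singular random-effect covariance
    triggers a flagged refit with a diagonal covariance; non-convergence
    is flagged on the returned fit.
    """
    cells = [comparison.cell_a, comparison.cell_b]
    mask = (table["parameter"] == parameter).to_numpy()
    mask &= np.array(
        [(g, t) in cells for g, t in zip(table["group"], table["timepoint"])]
    )
    sub = table[mask]
    if sub.empty:
        raise ValidationError(f"no data for parameter {parameter!r} in {comparison.name}")
    for cell in cells:
        n_sub = sub[(sub["group"] == cell[0]) & (sub["timepoint"] == cell[1])][
            "subject"
        ].nunique()
        if n_sub < 2:
            raise ValidationError(
                f"comparison {comparison.name}: cell {cell} has {n_sub} subject(s); "
                "at least 2 are required"
            )
    X, Z = _design(sub, comparison)
    if X["x2"].nunique() < 2:
        raise ValidationError(
            f"comparison indicator is constant for {comparison.name}; "
            "the effect of interest is inestimable"
        )
    # drop covariates without variation (e.g. single-animal metadata reused)
    for col in ("age", "weight"):
        if X[col].nunique() < 2:
            X = X.drop(columns=col)

    y = sub["y"].to_numpy(dtype=float)
    groups = sub["subject"].to_numpy()
    flags: list[str] = []

    model = MixedLM(y, X, groups=groups, exog_re=Z)
    with np.errstate(all="ignore"):
        result = _quiet_fit(model)
    eigvals = np.linalg.eigvalsh(np.asarray(result.cov_re))
    if not result.converged or eigvals.min() < 1e-10 * max(eigvals.max(), 1e-12):
        free = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(Z.shape[1])
        )
        with np.errstate(all="ignore"):
            refit = _quiet_fit(model, free=free)
        if refit.converged or not result.converged:
            flags.append("singular covariance; refit with diagonal covariance")
            result = refit
    if not result.converged:
        flags.append("non-convergence")

    names = list(X.columns)
    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(all="ignore"):
        _warnings.simplefilter("ignore")
        fe = pd.Series(np.asarray(result.fe_params), index=names)
        bse = pd.Series(np.asarray(result.bse_fe), index=names)
        pvals = pd.Series(np.asarray(result.pvalues)[: len(names)], index=names)
    if not np.isfinite(pvals["x2"]):
        flags.append("non-finite Wald statistic for the comparison effect")
    return LMEFit(
        parameter=parameter,
        comparison=comparison.name,
        fe_params=fe,
        fe_bse=bse,
        cov_re=pd.DataFrame(np.asarray(result.cov_re)),
        sigma2=float(result.scale),
        llf=float(result.llf),
        beta3=float(fe["x2"]),
        se3=float(bse["x2"]),
        pvalue=float(pvals["x2"]),
        converged=bool(result.converged),
        flags=flags,
    )


def _quiet_fit(model: MixedLM, **kwargs):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=True, **kwargs)


def bonferroni_stars(p: float, threshold_base: float) -> str:
    """Star code per the battery's Bonferroni-scaled significance levels."""
    for level, stars in _STAR_LEVELS:
        if p < level * threshold_base:
            return stars
    return ""


def run_battery(
    table: pd.DataFrame,
    alpha: float = 0.05,
    parameters: Sequence[str] = PARAMETERS,
    comparisons: Sequence[Comparison] = COMPARISONS,
) -> ComparisonBattery:
    """Run the full 13-parameter × 7-comparison mixed-model battery.

    Emits one Wald p-value for β3 per (parameter, comparison) cell and
    a Bonferroni threshold of alpha / (13·7). Fits that fail to converge
    are recorded as NaN with a logged warning, never silently dropped.
    """
    present = set(table["parameter"].unique())
    absent = [p for p in parameters if p not in present]
    if absent:
        raise ValidationError(f"parameters missing from the table: {absent}")
    n_tests = len(parameters) * len(comparisons)
    threshold = alpha / n_tests
    pvals = pd.DataFrame(
        np.nan, index=list(parameters), columns=[c.name for c in comparisons]
    )
    stars = pd.DataFrame("", index=list(parameters), columns=[c.name for c in comparisons])
    fits: dict[tuple[str, str], LMEFit] = {}
    for param in parameters:
        for comp in comparisons:
            fit = fit_lme(table, param, comp)
            fits[(param, comp.name)] = fit
            if fit.converged and np.isfinite(fit.pvalue):
                pvals.loc[param, comp.name] = fit.pvalue
                stars.loc[param, comp.name] = bonferroni_stars(fit.pvalue, 1.0 / n_tests)
            else:
                log.warning(
                    "battery cell (%s, %s) did not converge; excluded",
                    param,
                    comp.name,
                )
    return ComparisonBattery(
        pvalues=pvals, stars=stars, alpha=alpha, threshold=threshold, fits=fits
    )


def simulate_comparison_table(
    n_subjects_per_cell: int,
    beta3: float,
    n_z: int = 11,
    fixed: Sequence[float] = (10.0, 2.0, -1.5),
    re_sd: Sequence[float] = (1.0, 0.5, 0.5),
    sigma: float = 1.0,
    rng: np.random.Generator | None = None,
    parameter: str = "A_sas",
) -> pd.DataFrame:
    """Simulate one two-cell dataset from the battery's own model.

    Two groups of subjects (cervical PRE-2 vs lumbar PRE-2) with random
    intercept/slope/curvature drawn independently with the given SDs,
    fixed quadratic location trend, group effect ``beta3`` and residual
    SD ``sigma``. Used for type-I-error and effect-recovery studies.
    """
    rng = rng or np.random.default_rng()
    x1 = np.linspace(0.0, 1.0, n_z)
    rows = []
    for cell_idx, (group, x2) in enumerate((("cervical", 0.0), ("lumbar", 1.0))):
        for j in range(n_subjects_per_cell):
            sid = f"S{cell_idx}{j:03d}"
            z = rng.normal(0.0, re_sd, size=3)
            age = rng.uniform(4.0, 5.0)
            weight = rng.uniform(3.0, 6.0)
            mu = (
                fixed[0]
                + fixed[1] * x1
                + fixed[2] * x1**2
                + beta3 * x2
                + z[0]
                + z[1] * x1
                + z[2] * x1**2
            )
            y = mu + rng.normal(0.0, sigma, size=n_z)
            for xi, yi in zip(x1, y):
                rows.append(
                    {
                        "subject": sid,
                        "group": group,
                        "timepoint": "PRE-2",
                        "x1": xi,
                        "age": age,
                        "weight": weight,
                        "parameter": parameter,
                        "y": yi,
                    }
                )
    return pd.DataFrame(rows)
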