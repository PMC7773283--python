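"""Synthetic cohort generator with recorded ground truth.

Emulates the structure of a cynomolgus-monkey catheter-implantation MRI
study: smoothly tapering cord/dura area and perimeter profiles along a
~30 cm spine, cardiac-gated flow waveforms whose amplitude decays
caudally and whose systolic peak propagates down the spine at a finite
pulse wave speed, per-subject heart-period variability, and a
post-implantation cohort whose flow attenuation follows each subject's
own Hagen–Poiseuille flow-reduction prediction.

Every generated dataset carries its ground truth (true geometry scale
factors, pulse wave velocity, attenuation factors) so recovery by the
analysis pipeline can be tested end to end. Generation is a pure
function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .geometry import catheter_footprint, derive_sas_profile
from .resistance import hagen_poiseuille_reduction
from .types import (
    AxialGrid,
    AxialProfile,
    CatheterSpec,
    FlowWaveform,
    SubjectRecord,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "SubjectTruth",
    "SyntheticSubject",
    "SyntheticCohort",
    "generate_geometry",
    "generate_waveforms",
    "apply_catheter_effect",
    "generate_cohort",
]

#: Template shapes: (axial fraction, relative value) control points.
_SHAPE_A_C = ((0.0, 1.40), (0.25, 1.25), (0.5, 1.00), (0.75, 0.75), (1.0, 0.35))
_SHAPE_A_D = ((0.0, 1.25), (0.25, 1.15), (0.5, 1.00), (0.75, 0.85), (1.0, 0.55))
_SHAPE_P_C = ((0.0, 1.20), (0.25, 1.10), (0.5, 1.00), (0.75, 0.85), (1.0, 0.55))
_SHAPE_P_D = ((0.0, 1.15), (0.25, 1.08), (0.5, 1.00), (0.75, 0.90), (1.0, 0.70))
#: Caudal decay of flow amplitude (peaks just below the foramen magnum).
_SHAPE_FLOW = ((0.0, 0.75), (0.08, 1.00), (0.25, 0.90), (0.5, 0.55), (0.75, 0.30), (1.0, 0.08))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the published cohort: four animals per implantation
    group, ~300 mm SAS, group-mean cross-sections near 15.4 / 39.7 mm²
    (cord / dura) and perimeters near 13.9 / 22.1 mm, a 0.35 mL/s
    cervical systolic peak decaying caudally, a 1.15 m/s pulse wave
    velocity, and a 0.53 s mean cardiac period.
    """

    n_per_group: int = 4
    dz: float = 1.0  # mm
    L_mean: float = 300.0  # mm
    L_sd: float = 15.0  # mm
    mean_A_c: float = 15.43  # mm²
    mean_A_d: float = 39.65  # mm²
    mean_P_c: float = 13.88  # mm
    mean_P_d: float = 22.09  # mm
    geom_sd: float = 0.08  # lognormal sigma of per-subject scale factors
    q0: float = 0.35  # mL/s, systolic peak amplitude at its axial maximum
    q0_sd: float = 0.2  # lognormal sigma of per-subject amplitude
    pwv: float = 1.15  # m/s, true pulse wave velocity
    T_mean: float = 0.53  # s
    T_sd: float = 0.05  # s, between-subject heart-period SD
    n_t: int = 32  # time samples per cycle
    second_harmonic: float = 0.3  # relative amplitude of the 2nd harmonic
    level_fracs: tuple[float, ...] = (0.0, 0.08, 0.2, 0.45, 0.7, 0.88)
    noise_sd_Q: float = 0.01  # mL/s, additive measurement noise
    # catheter paths as fractions of each subject's own L_sas
    entry_frac: float = 0.95
    tip_frac_cervical: float = 0.20
    tip_frac_lumbar: float = 0.72
    weight_mean: float = 4.4  # kg
    weight_sd: float = 1.2
    age_mean: float = 4.6  # yr
    age_sd: float = 0.4

    def __post_init__(self) -> None:
        for name in ("dz", "L_mean", "mean_A_c", "mean_A_d", "mean_P_c",
                     "mean_P_d", "q0", "pwv", "T_mean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name} must be positive")
        if self.mean_A_d <= self.mean_A_c:
            raise ValidationError("mean dura area must exceed mean cord area")
        if self.n_t < 8:
            raise ValidationError("at least 8 time samples per cycle are required")


@dataclass
class SubjectTruth:
    """Ground truth recorded for one generated subject."""

    id: str
    L_sas: float
    area_factor: float
    perim_factor: float
    q0: float  # effective amplitude (post-attenuation when implanted)
    T: float
    pwv: float
    attenuation: float = 0.0  # fraction of flow removed by the catheter


@dataclass
class SyntheticSubject:
    record: SubjectRecord
    profile: AxialProfile  # derived (A_sas/P_sas/D_h filled)
    waveforms: list[FlowWaveform]
    truth: SubjectTruth


@dataclass
class SyntheticCohort:
    """One timepoint's worth of generated subjects, plus the config."""

    config: SyntheticConfig
    timepoint: str
    subjects: list[SyntheticSubject]


def _shape(points: Sequence[tuple[float, float]]) -> PchipInterpolator:
    xs, ys = zip(*points)
    return PchipInterpolator(np.array(xs), np.array(ys))


def _lognormal_factor(rng: np.random.Generator, sigma: float) -> float:
    """Unit-mean lognormal multiplier."""
    if sigma == 0:
        return 1.0
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


def _scaled_field(shape, frac, target_mean, factor):
    raw = shape(frac)
    return target_mean * factor * raw / raw.mean()


def generate_geometry(
    config: SyntheticConfig, rng: np.random.Generator, subject_id: str,
    group: str,
) -> tuple[SubjectRecord, AxialProfile, SubjectTruth]:
    """One subject's metadata, axial geometry and ground truth.

    The four geometry fields follow smooth monotone-taper templates
    evaluated at fractional axial position, rescaled so the cohort-mean
    along-spine average hits the configured targets, then multiplied by
    per-subject unit-mean lognormal factors (one shared factor for the
    two areas, one for the two perimeters, preserving A_d > A_c).
    """
    L = max(float(rng.normal(config.L_mean, config.L_sd)), 0.5 * config.L_mean)
    grid = AxialGrid.uniform(L, config.dz)
    frac = grid.z / grid.L_sas
    f_area = _lognormal_factor(rng, config.geom_sd)
    f_perim = _lognormal_factor(rng, config.geom_sd)
    profile = AxialProfile(
        grid=grid,
        A_c=_scaled_field(_shape(_SHAPE_A_C), frac, config.mean_A_c, f_area),
        A_d=_scaled_field(_shape(_SHAPE_A_D), frac, config.mean_A_d, f_area),
        P_c=_scaled_field(_shape(_SHAPE_P_C), frac, config.mean_P_c, f_perim),
        P_d=_scaled_field(_shape(_SHAPE_P_D), frac, config.mean_P_d, f_perim),
    )
    T = max(float(rng.normal(config.T_mean, config.T_sd)), 0.3)
    record = SubjectRecord(
        id=subject_id,
        group=group,
        timepoint="PRE-2",
        weight=max(float(rng.normal(config.weight_mean, config.weight_sd)), 1.0),
        age=max(float(rng.normal(config.age_mean, config.age_sd)), 1.0),
        T=T,
    )
    q0 = config.q0 * _lognormal_factor(rng, config.q0_sd)
    truth = SubjectTruth(
        id=subject_id, L_sas=L, area_factor=f_area, perim_factor=f_perim,
        q0=q0, T=T, pwv=config.pwv,
    )
    return record, derive_sas_profile(profile), truth


def _pulse(tau: np.ndarray, T: float, a2: float) -> np.ndarray:
    """Two-harmonic cardiac pulse, normalized to unit peak."""
    x = 2.0 * math.pi * tau / T
    s = np.sin(x) + a2 * np.sin(2.0 * x)
    dense = np.sin(np.linspace(0, 2 * math.pi, 4096)) + a2 * np.sin(
        2 * np.linspace(0, 2 * math.pi, 4096)
    )
    return s / dense.max()


def generate_waveforms(
    config: SyntheticConfig,
    truth: SubjectTruth,
    rng: np.random.Generator,
) -> list[FlowWaveform]:
    """Per-level cardiac-gated waveforms for one subject.

    ``Q(z, t) = -q0 · g(z/L) · s((t - z/PWV) mod T)`` with the caudally
    decaying amplitude template g and a two-harmonic pulse s whose
    systolic lobe peaks ~100 ms into the cycle; additive Gaussian noise
    on every sample. Caudal flow is negative.
    """
    if truth.pwv <= 0:
        raise ValidationError("true PWV must be positive")
    g = _shape(_SHAPE_FLOW)
    T = truth.T
    t = np.arange(config.n_t) * (T / config.n_t)
    pwv_mm_s = truth.pwv * 1000.0
    waveforms = []
    for frac_z in config.level_fracs:
        z = frac_z * truth.L_sas
        tau = np.mod(t - z / pwv_mm_s, T)
        q = -truth.q0 * float(g(frac_z)) * _pulse(tau, T, config.second_harmonic)
        q = q + rng.normal(0.0, config.noise_sd_Q, size=q.shape)
        waveforms.append(FlowWaveform(level_z=z, t=t, Q=q, T=T))
    return waveforms


def _catheter_for(config: SyntheticConfig, group: str, L_sas: float) -> CatheterSpec:
    tip_frac = config.tip_frac_cervical if group == "cervical" else config.tip_frac_lumbar
    return CatheterSpec(tip_z=tip_frac * L_sas, entry_z=config.entry_frac * L_sas)


def generate_cohort(
    config: SyntheticConfig, seed: int, timepoint: str = "PRE-2"
) -> SyntheticCohort:
    """Generate the catheter-free (PRE-2) cohort for both groups."""
    rng = np.random.default_rng(seed)
    subjects = []
    for group in ("cervical", "lumbar"):
        for j in range(config.n_per_group):
            sid = f"NHP-{group[0].upper()}{j + 1:02d}"
            record, profile, truth = generate_geometry(config, rng, sid, group)
            waveforms = generate_waveforms(config, truth, rng)
            subjects.append(
                SyntheticSubject(record=record, profile=profile,
                                 waveforms=waveforms, truth=truth)
            )
    return SyntheticCohort(config=config, timepoint=timepoint, subjects=subjects)


def apply_catheter_effect(
    cohort: SyntheticCohort,
    seed: int,
    timepoint: str = "POST-1",
    catheters: Mapping[str, CatheterSpec] | None = None,
) -> SyntheticCohort:
    """Implant each subject's group catheter and attenuate its flow.

    Geometry gains the catheter footprint; the flow amplitude is scaled
    by ``1 - reduction`` where the reduction is the Hagen–Poiseuille
    prediction computed from the subject's *own* pre-implant geometry.
    Measurement noise is redrawn. The true attenuation is recorded in
    the returned ground truth.
    """
    rng = np.random.default_rng(seed)
    config = cohort.config
    subjects = []
    for subj in cohort.subjects:
        group = subj.record.group
        cath = (catheters or {}).get(group) or _catheter_for(
            config, group, subj.truth.L_sas
        )
        bare = replace(subj.profile, A_sas=None, P_sas=None, D_h=None)
        try:
            result = hagen_poiseuille_reduction(bare, cath)
            footprint = catheter_footprint(cath, bare.grid)
            post_profile = derive_sas_profile(bare, footprint)
        except ValidationError as exc:
            raise ValidationError(
                f"catheter incompatible with subject {subj.record.id}: {exc}"
            ) from exc
        truth = replace(
            subj.truth,
            q0=subj.truth.q0 * (1.0 - result.reduction),
            attenuation=result.reduction,
        )
        record = replace(subj.record, timepoint=timepoint)
        waveforms = generate_waveforms(config, truth, rng)
        subjects.append(
            SyntheticSubject(record=record, profile=post_profile,
                             waveforms=waveforms, truth=truth)
        )
    return SyntheticCohort(config=config, timepoint=timepoint, subjects=subjects)
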