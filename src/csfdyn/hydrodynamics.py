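"""Mean velocities and dimensionless characterization of the CSF flow.

All quantities are computed in a consistent mm / s / mm²·s⁻¹ unit system
so the dimensionless numbers carry no hidden conversion factors:

* ``Ū_sys = Q_sys / A_sas`` and ``Ū_dia = Q_dia / A_sas`` — spatial mean
  through-plane velocities (reported in cm/s);
* ``Re = |Ū_sys| D_h / ν`` — Reynolds number on the hydraulic diameter
  (laminar below ~2300);
* ``δ = sqrt(2ν/ω)`` — Stokes oscillatory boundary-layer thickness, and
  ``Re_δ = |Ū_sys| δ / ν`` (conditional turbulence above ~550);
* ``α = (D_h/2) sqrt(ω/ν)`` — Womersley number, unsteady inertia vs.
  viscosity (parabolic profiles below ~2, plug-like above ~10);
* ``Re_NR = |Ū_sys| D_NR / ν`` and ``K = |Ū_sys| T / D_NR`` — external
  flow around nerve roots of diameter ``D_NR``; their ratio
  ``β = Re_NR / K = D_NR² / (ν T)`` controls the Honji-instability
  threshold ``K_cr = 5.778 β^(-1/4) (1 + 0.205 β^(-1/4))``.

Magnitudes |Ū_sys| are used throughout — the thresholds address flow
speed, not direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import FluidProperties, NerveRootModel, ValidationError

__all__ = [
    "HydroSummary",
    "InstabilityReport",
    "mean_velocities",
    "dimensionless_numbers",
    "critical_keulegan_carpenter",
    "instability_assessment",
    "RE_LAMINAR_THRESHOLD",
    "RE_DELTA_THRESHOLD",
]

#: Laminar pipe-flow threshold on Re.
RE_LAMINAR_THRESHOLD = 2300.0
#: Conditional-turbulence threshold on the Stokes-layer Reynolds number.
RE_DELTA_THRESHOLD = 550.0


@dataclass
class HydroSummary:
    """Per-z hydrodynamic quantities plus the scalar instability inputs."""

    z: np.ndarray
    U_sys: np.ndarray  # cm/s, signed
    U_dia: np.ndarray  # cm/s, signed
    Re: np.ndarray
    alpha: np.ndarray
    Re_delta: np.ndarray
    Re_NR: np.ndarray
    K: np.ndarray
    delta: float  # Stokes layer thickness, mm
    beta: float
    K_cr: float


@dataclass(frozen=True)
class InstabilityReport:
    """Flow-regime flags derived from the dimensionless numbers."""

    max_Re: float
    max_Re_delta: float
    max_K: float
    K_cr: float
    laminar: bool  # max Re below the 2300 pipe-flow threshold
    below_conditional_turbulence: bool  # max Re_delta below 550
    honji_stable: bool  # max K below K_cr

    @property
    def messages(self) -> list[str]:
        out = []
        out.append(
            f"max Re = {self.max_Re:.2f}: "
            + ("laminar" if self.laminar else "above the laminar threshold (2300)")
        )
        out.append(
            f"max Re_delta = {self.max_Re_delta:.2f}: "
            + (
                "no conditional turbulence (threshold 550)"
                if self.below_conditional_turbulence
                else "above the conditional-turbulence threshold (550)"
            )
        )
        out.append(
            f"max K = {self.max_K:.2f} vs K_cr = {self.K_cr:.2f}: "
            + ("no Honji-type instability expected" if self.honji_stable
               else "Honji-type instability possible")
        )
        return out


def mean_velocities(
    Q_sys: np.ndarray, Q_dia: np.ndarray, A_sas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial mean through-plane velocities, cm/s.

    Q in mL/s over A in mm² gives 1000·Q/A mm/s; one factor of 10 less
    is cm/s, so ``U[cm/s] = 100 · Q[mL/s] / A[mm²]``.
    """
    A_sas = np.asarray(A_sas, dtype=float)
    if np.any(A_sas <= 0):
        bad = int(np.argmax(A_sas <= 0))
        raise ValidationError(f"A_sas must be positive everywhere (index {bad})")
    return 100.0 * np.asarray(Q_sys) / A_sas, 100.0 * np.asarray(Q_dia) / A_sas


def critical_keulegan_carpenter(beta: float) -> float:
    """Hall's critical Keulegan–Carpenter number for Honji instability."""
    if beta <= 0:
        raise ValidationError("beta must be positive")
    b = beta ** -0.25
    return 5.778 * b * (1.0 + 0.205 * b)


def dimensionless_numbers(
    U_sys: np.ndarray,
    U_dia: np.ndarray,
    D_h: np.ndarray,
    z: np.ndarray,
    fluid: FluidProperties = FluidProperties(),
    nerve_roots: NerveRootModel = NerveRootModel(),
) -> HydroSummary:
    """All per-z dimensionless numbers from velocities and geometry.

    ``U_sys``/``U_dia`` are in cm/s (as produced by
    :func:`mean_velocities`); internally they are converted to mm/s to
    match ν in mm²/s.
    """
    z = np.asarray(z, dtype=float)
    D_h = np.asarray(D_h, dtype=float)
    u_mm = np.abs(np.asarray(U_sys, dtype=float)) * 10.0  # cm/s -> mm/s
    nu, omega, T = fluid.nu, fluid.omega, fluid.T_ref
    d_nr = nerve_roots.diameter_at(z)

    delta = math.sqrt(2.0 * nu / omega)
    beta = float(np.mean(d_nr) ** 2 / (nu * T))
    return HydroSummary(
        z=z,
        U_sys=np.asarray(U_sys, dtype=float),
        U_dia=np.asarray(U_dia, dtype=float),
        Re=u_mm * D_h / nu,
        alpha=(D_h / 2.0) * math.sqrt(omega / nu),
        Re_delta=u_mm * delta / nu,
        Re_NR=u_mm * d_nr / nu,
        K=u_mm * T / d_nr,
        delta=delta,
        beta=beta,
        K_cr=critical_keulegan_carpenter(beta),
    )


def instability_assessment(summary: HydroSummary) -> InstabilityReport:
    """Assess laminarity and oscillatory-instability margins."""
    max_Re = float(np.max(summary.Re))
    max_Re_delta = float(np.max(summary.Re_delta))
    max_K = float(np.max(summary.K))
    return InstabilityReport(
        max_Re=max_Re,
        max_Re_delta=max_Re_delta,
        max_K=max_K,
        K_cr=summary.K_cr,
        laminar=max_Re < RE_LAMINAR_THRESHOLD,
        below_conditional_turbulence=max_Re_delta < RE_DELTA_THRESHOLD,
        honji_stable=max_K < summary.K_cr,
    )
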