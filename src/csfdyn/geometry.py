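"""SAS axial geometry: catheter adjustment, hydraulic diameter, summaries.

The subarachnoid space (SAS) at each axial position is the annular area
between dura and cord, ``A_sas = A_d - A_c``, wetted by both surfaces,
``P_sas = P_c + P_d``. An implanted catheter occludes its own
cross-section and adds its outer perimeter to the wetted boundary; the
hydraulic diameter ``D_h = 4 A_sas / P_sas`` then shrinks accordingly.

Volumes and surface areas are axial integrals of the area and perimeter
profiles (trapezoidal rule on the uniform grid), reported in mL and cm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .types import (
    AxialGrid,
    AxialProfile,
    CatheterSpec,
    GeometrySummary,
    ValidationError,
)

__all__ = [
    "CatheterFootprint",
    "catheter_footprint",
    "derive_sas_profile",
    "summarize_geometry",
    "normalize_axial",
]


@dataclass(frozen=True)
class CatheterFootprint:
    """Occluded area and added wetted perimeter of a catheter, per z.

    ``A_cath = (π/4)·OD²`` and ``P_cath = π·OD`` wherever the catheter is
    present, zero elsewhere.
    """

    grid: AxialGrid
    A_cath: np.ndarray  # mm²
    P_cath: np.ndarray  # mm

    @classmethod
    def empty(cls, grid: AxialGrid) -> "CatheterFootprint":
        zeros = np.zeros(grid.n)
        return cls(grid, zeros, zeros.copy())

    @property
    def is_empty(self) -> bool:
        return not np.any(self.A_cath > 0)


def catheter_footprint(cath: CatheterSpec, grid: AxialGrid) -> CatheterFootprint:
    """Map a catheter onto the axial grid.

    Segments are walked from the tip caudally toward the entry site;
    catheter length beyond the entry point lies outside the SAS and
    contributes nothing.
    """
    if not (0.0 <= cath.tip_z <= grid.L_sas) or not (0.0 <= cath.entry_z <= grid.L_sas):
        raise ValidationError(
            f"catheter path [{cath.tip_z:g}, {cath.entry_z:g}] mm must lie within "
            f"the SAS [0, {grid.L_sas:g}] mm"
        )
    od = cath.od_at(grid.z)
    return CatheterFootprint(grid, math.pi / 4.0 * od**2, math.pi * od)


def derive_sas_profile(
    profile: AxialProfile, footprint: CatheterFootprint | None = None
) -> AxialProfile:
    """Fill ``A_sas``, ``P_sas`` and ``D_h`` on a geometry profile.

    With a catheter footprint, the occluded area is subtracted and the
    catheter perimeter added before forming ``D_h = 4 A_sas / P_sas``.
    The adjustment is conservative: subtracting the same footprint again
    restores the original SAS profile exactly.
    """
    if footprint is None:
        footprint = CatheterFootprint.empty(profile.grid)
    elif footprint.grid.n != profile.grid.n or not np.allclose(
        footprint.grid.z, profile.grid.z
    ):
        raise ValidationError("catheter footprint grid does not match the profile grid")

    A_sas = profile.A_d - profile.A_c - footprint.A_cath
    P_sas = profile.P_c + profile.P_d + footprint.P_cath
    if np.any(A_sas <= 0):
        z_bad = profile.grid.z[np.argmax(A_sas <= 0)]
        raise ValidationError(
            f"catheter occludes the SAS entirely at z = {z_bad:g} mm (A_sas <= 0)"
        )
    if np.any(P_sas <= 0):
        z_bad = profile.grid.z[np.argmax(P_sas <= 0)]
        raise ValidationError(f"wetted perimeter vanishes at z = {z_bad:g} mm")
    return replace(profile, A_sas=A_sas, P_sas=P_sas, D_h=4.0 * A_sas / P_sas)


def summarize_geometry(profile: AxialProfile) -> GeometrySummary:
    """Integrate a derived profile into scalar volume/surface summaries.

    ``V_x = ∫ A_x dz`` (mm³ → mL) and ``SA_x = ∫ P_x dz`` (mm² → cm²),
    both by the trapezoidal rule; the identities ``SA_sas = SA_c + SA_d``
    and ``V_sas = V_d - V_c`` hold exactly by construction.
    """
    if profile.grid.n < 2:
        raise ValidationError("geometry summary needs at least two grid points")
    z = profile.grid.z

    def vol(a: np.ndarray) -> float:  # mm³ → mL
        return float(np.trapezoid(a, z)) / 1000.0

    def area(p: np.ndarray) -> float:  # mm² → cm²
        return float(np.trapezoid(p, z)) / 100.0

    V_c, V_d = vol(profile.A_c), vol(profile.A_d)
    SA_c, SA_d = area(profile.P_c), area(profile.P_d)
    return GeometrySummary(
        SA_c=SA_c,
        SA_d=SA_d,
        SA_sas=SA_c + SA_d,
        V_c=V_c,
        V_d=V_d,
        V_sas=V_d - V_c,
        L_sas=profile.grid.L_sas,
    )


def normalize_axial(
    profiles: Sequence[AxialProfile], L_mean: float, dz: float | None = None
) -> list[AxialProfile]:
    """Rescale each profile's axial length to ``L_mean`` on a common grid.

    Each subject's z axis is stretched by ``L_mean / L_sas`` and the
    fields linearly resampled onto a shared uniform grid, so parameter
    values at matching *fractional* positions are unchanged. This lets
    axial distributions be averaged and compared across subjects with
    different spine lengths.
    """
    if not profiles:
        raise ValidationError("normalize_axial needs at least one profile")
    if L_mean <= 0:
        raise ValidationError("L_mean must be positive")
    if dz is None:
        dz = profiles[0].grid.dz
    common = AxialGrid.uniform(L_mean, dz)
    out = []
    for p in profiles:
        scale = L_mean / p.grid.L_sas
        z_stretched = p.grid.z * scale
        fields = {
            name: np.interp(common.z, z_stretched, getattr(p, name))
            for name in ("A_c", "A_d", "P_c", "P_d")
        }
        derived = {}
        for name in ("A_sas", "P_sas", "D_h"):
            val = getattr(p, name)
            if val is not None:
                derived[name] = np.interp(common.z, z_stretched, val)
        out.append(AxialProfile(grid=common, **fields, **derived))
    return out
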