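"""Shared domain types and conventions.

Coordinate convention: ``z`` runs along the spine in millimetres, with
``z = 0`` at the foramen magnum and increasing caudally; the axial domain
ends at the thecal-sac termination, ``L_sas``.

Sign convention: caudally directed CSF flow is **negative**, so the
systolic peak of a cardiac-gated waveform is the most negative flow value
and the diastolic peak the most positive.

Units are fixed per field: lengths and perimeters in mm, areas in mm²,
volumes in mL, flow rates in mL/s, times in s, kinematic viscosity in
mm²/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AxialGrid",
    "AxialProfile",
    "GeometrySummary",
    "CatheterSpec",
    "CatheterSegment",
    "FlowWaveform",
    "SubjectRecord",
    "FluidProperties",
    "NerveRootModel",
    "ValidationError",
    "FormatError",
    "GROUPS",
    "TIMEPOINTS",
]

GROUPS = ("cervical", "lumbar")
TIMEPOINTS = ("PRE-2", "POST-1", "POST-2")

#: Relative tolerance for grid-uniformity checks.
_GRID_RTOL = 1e-9


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class FormatError(ValueError):
    """An input file does not match the expected tabular layout."""


@dataclass(frozen=True)
class AxialGrid:
    """Uniform axial grid from the foramen magnum to the thecal sac.

    Parameters
    ----------
    z
        Strictly increasing, uniformly spaced positions in mm with
        ``z[0] == 0``.
    """

    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 1 or z.size < 2:
            raise ValidationError("axial grid needs at least two positions")
        if abs(z[0]) > _GRID_RTOL:
            raise ValidationError("axial grid must start at z = 0 (foramen magnum)")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise ValidationError("axial grid positions must be strictly increasing")
        if np.ptp(dz) > _GRID_RTOL * max(abs(z[-1]), 1.0):
            raise ValidationError("axial grid spacing must be uniform")
        object.__setattr__(self, "z", z)

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def L_sas(self) -> float:
        """Total SAS length in mm (z of the thecal-sac termination)."""
        return float(self.z[-1])

    @property
    def n(self) -> int:
        return self.z.size

    @classmethod
    def uniform(cls, L_sas: float, dz: float = 1.0) -> "AxialGrid":
        n = int(round(L_sas / dz))
        return cls(np.linspace(0.0, n * dz, n + 1))


@dataclass
class AxialProfile:
    """Per-z cross-sectional geometry of cord, dura and SAS.

    ``A_sas``, ``P_sas`` and ``D_h`` are filled by
    :func:`csfdyn.geometry.derive_sas_profile`.
    """

    grid: AxialGrid
    A_c: np.ndarray  # cord cross-sectional area, mm²
    A_d: np.ndarray  # dura cross-sectional area, mm²
    P_c: np.ndarray  # cord perimeter, mm
    P_d: np.ndarray  # dura perimeter, mm
    A_sas: np.ndarray | None = None  # mm²
    P_sas: np.ndarray | None = None  # mm
    D_h: np.ndarray | None = None  # mm

    def __post_init__(self) -> None:
        n = self.grid.n
        for name in ("A_c", "A_d", "P_c", "P_d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one value per grid point")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if np.any(self.A_c < 0) or np.any(self.P_c < 0) or np.any(self.P_d < 0):
            raise ValidationError("areas and perimeters must be non-negative")
        if np.any(self.A_d <= self.A_c):
            bad = self.grid.z[np.argmax(self.A_d <= self.A_c)]
            raise ValidationError(
                f"dura area must exceed cord area everywhere (violated at z = {bad:g} mm)"
            )

    @property
    def derived(self) -> bool:
        return self.A_sas is not None


@dataclass(frozen=True)
class GeometrySummary:
    """Scalar surface-area (cm²) and volume (mL) summaries of one subject."""

    SA_c: float
    SA_d: float
    SA_sas: float
    V_c: float
    V_d: float
    V_sas: float
    L_sas: float

    def __post_init__(self) -> None:
        if not math.isclose(self.SA_sas, self.SA_c + self.SA_d, rel_tol=1e-12, abs_tol=1e-12):
            raise ValidationError("SA_sas must equal SA_c + SA_d")
        if not math.isclose(self.V_sas, self.V_d - self.V_c, rel_tol=1e-12, abs_tol=1e-12):
            raise ValidationError("V_sas must equal V_d - V_c")
        for name in ("SA_c", "SA_d", "SA_sas", "V_c", "V_d", "V_sas", "L_sas"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CatheterSegment:
    """One piecewise-constant stretch of catheter, ordered from the tip."""

    length: float  # mm
    od: float  # outer diameter, mm
    id: float  # inner diameter, mm

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError("catheter segment length must be positive")
        if not self.od > self.id > 0:
            raise ValidationError("catheter requires OD > ID > 0")


#: Default catheter: 10 cm distal segment (OD 0.99, ID 0.38), then 24 cm
#: (OD 1.98, ID 1.19), then ~1.5 cm (OD 1.93, ID 1.07) at the entry end.
DEFAULT_CATHETER_SEGMENTS = (
    CatheterSegment(100.0, 0.99, 0.38),
    CatheterSegment(240.0, 1.98, 1.19),
    CatheterSegment(15.0, 1.93, 1.07),
)


@dataclass(frozen=True)
class CatheterSpec:
    """Piecewise catheter geometry laid from the tip toward the entry site.

    ``tip_z`` is the rostral-most point the catheter reaches; ``entry_z``
    (> ``tip_z``) is where it crosses the dura. Segments are ordered from
    the tip; any catheter length beyond ``entry_z`` lies outside the SAS.
    """

    tip_z: float
    entry_z: float
    segments: tuple[CatheterSegment, ...] = DEFAULT_CATHETER_SEGMENTS

    def __post_init__(self) -> None:
        if self.entry_z < self.tip_z:
            raise ValidationError("entry_z must not be rostral of tip_z")
        segs = tuple(
            s if isinstance(s, CatheterSegment) else CatheterSegment(*s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        in_sas = self.entry_z - self.tip_z
        if sum(s.length for s in segs) < in_sas - 1e-9:
            raise ValidationError(
                "catheter segments are shorter than the tip-to-entry path "
                f"({in_sas:g} mm); the catheter cannot span its own path"
            )

    def od_at(self, z: np.ndarray) -> np.ndarray:
        """Outer diameter (mm) at each z; 0 outside [tip_z, entry_z]."""
        z = np.asarray(z, dtype=float)
        od = np.zeros_like(z)
        if self.entry_z == self.tip_z:
            return od
        edges = self.tip_z + np.cumsum([0.0] + [s.length for s in self.segments])
        for lo, hi, seg in zip(edges[:-1], edges[1:], self.segments):
            mask = (z >= lo) & (z < hi) & (z <= self.entry_z)
            od[mask] = seg.od
        # the entry point itself belongs to whichever segment covers it
        at_entry = np.isclose(z, self.entry_z) & (od == 0)
        if np.any(at_entry):
            idx = np.searchsorted(edges, self.entry_z, side="right") - 1
            idx = min(idx, len(self.segments) - 1)
            od[at_entry] = self.segments[idx].od
        return od


@dataclass
class FlowWaveform:
    """Cardiac-gated CSF flow at one axial level over one cycle.

    ``t`` spans ``[0, T)`` (the wrap point ``t = T`` is implicit and
    ``Q(T) = Q(0)`` by periodicity). Caudal flow is negative.
    """

    level_z: float  # mm
    t: np.ndarray  # s
    Q: np.ndarray  # mL/s
    T: float  # cardiac period, s

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        if t.shape != Q.shape or t.ndim != 1:
            raise ValidationError("t and Q must be matching 1-D arrays")
        if t.size < 2:
            raise ValidationError("a waveform needs at least two time samples")
        if self.T <= 0:
            raise ValidationError("cardiac period must be positive")
        if abs(t[0]) > 1e-12 or t[-1] >= self.T + 1e-12:
            raise ValidationError("t must span [0, T)")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time samples must be strictly increasing")
        if not np.all(np.isfinite(Q)):
            raise ValidationError("Q contains non-finite values")
        self.t, self.Q = t, Q


@dataclass(frozen=True)
class SubjectRecord:
    """Case metadata for one animal at one MRI time point."""

    id: str
    group: str  # 'cervical' | 'lumbar'
    timepoint: str  # 'PRE-2' | 'POST-1' | 'POST-2'
    weight: float  # kg
    age: float  # years
    T: float = 0.53  # heart period, s

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.weight <= 0 or self.age <= 0 or self.T <= 0:
            raise ValidationError("weight, age and heart period must be positive")


@dataclass(frozen=True)
class FluidProperties:
    """CSF fluid properties at body temperature.

    ``nu`` is the kinematic viscosity in mm²/s (0.693 for CSF at 37 °C,
    numerically equal to the dynamic viscosity in mPa·s at density
    1 g/mL). ``omega = 2π/T_ref`` is the angular frequency of the
    reference cardiac cycle.
    """

    nu: float = 0.693  # mm²/s
    T_ref: float = 0.53  # s

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.T_ref <= 0:
            raise ValidationError("nu and T_ref must be positive")

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * math.pi / self.T_ref


@dataclass(frozen=True)
class NerveRootModel:
    """Nerve roots as circular cylinders of diameter ``D_NR`` (mm).

    Anatomical nerve-root diameters run roughly 0.2–0.3 mm along the
    spine; the default is a single constant, and an axial profile may be
    supplied as a callable of z.
    """

    D_NR: float = 0.25  # mm

    def __post_init__(self) -> None:
        if self.D_NR <= 0:
            raise ValidationError("D_NR must be positive")

    def diameter_at(self, z: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(z, dtype=float).shape, self.D_NR)
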