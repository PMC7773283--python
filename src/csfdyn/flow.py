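"""Cardiac-gated CSF flow processing.

Pipeline: per-level waveforms are first rescaled to a common cardiac
period (time axis only — flow values are untouched so stroke volume is
preserved), then fused into a smooth flow surface Q(z, t) by a
tensor-product cubic smoothing spline, from which systolic/diastolic
peaks, flow amplitude, stroke volume and the pulse wave velocity (PWV)
are extracted.

PWV is the propagation speed of the systolic flow peak down the spine:
the arrival time of the peak is located at each axial position and
regressed on z; the inverse slope, converted to m/s, is the PWV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline

from .types import FlowWaveform, ValidationError

__all__ = [
    "FlowField",
    "FlowSummary",
    "normalize_cycle",
    "fit_spatiotemporal",
    "extract_peaks",
    "stroke_volume",
    "pulse_wave_velocity",
    "pwv_from_arrivals",
    "summarize_flow",
]

log = logging.getLogger(__name__)


@dataclass
class FlowField:
    """Smoothed flow surface Q(z, t) on a dense rectangular grid.

    ``z`` spans the measured levels (mm); ``t`` spans one normalized
    cardiac cycle within [0, T) (s); ``Q[i, j]`` is the flow at
    ``(z[i], t[j])`` in mL/s, caudal negative.
    """

    z: np.ndarray
    t: np.ndarray
    Q: np.ndarray
    T: float
    levels: np.ndarray | None = None  # measured slice locations, if known
    _spline: object = None  # (knots_z, kz, knots_t, kt, coeffs) of the fit

    def __post_init__(self) -> None:
        if self.Q.shape != (self.z.size, self.t.size):
            raise ValidationError("Q must have shape (len(z), len(t))")
        if not np.all(np.isfinite(self.Q)):
            raise ValidationError("flow surface contains non-finite values")

    def evaluate(self, z: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Evaluate the fitted spline surface on the grid z × t."""
        if self._spline is None:
            raise ValidationError("this field carries no spline representation")
        tz, kz, tt, kt, C = self._spline
        Bz = BSpline.design_matrix(np.atleast_1d(z), tz, kz).toarray()
        Bt = BSpline.design_matrix(np.atleast_1d(t), tt, kt).toarray()
        return Bz @ C @ Bt.T


@dataclass
class FlowSummary:
    """Per-z flow descriptors plus the scalar pulse wave velocity."""

    z: np.ndarray
    Q_sys: np.ndarray  # mL/s, <= 0
    Q_dia: np.ndarray  # mL/s, >= 0
    Q_a: np.ndarray  # mL/s, peak-to-peak amplitude
    SV: np.ndarray  # mL
    arrival_z: np.ndarray  # z positions the arrival times refer to, mm
    arrival_t: np.ndarray  # s
    PWV: float  # m/s; +inf when the peak arrives everywhere at once


def normalize_cycle(w: FlowWaveform, T_ref: float) -> FlowWaveform:
    """Affinely rescale a waveform's time axis to span ``[0, T_ref)``.

    Flow values are unchanged, so extrema are preserved exactly and the
    stroke volume scales with the period as it physically must.
    """
    if T_ref <= 0:
        raise ValidationError("T_ref must be positive")
    return FlowWaveform(level_z=w.level_z, t=w.t * (T_ref / w.T), Q=w.Q.copy(), T=T_ref)


def _interp_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Knot vector whose B-spline basis has one function per data site."""
    return make_interp_spline(x, np.zeros(x.size), k=k).t


def _second_diff_penalty(n: int) -> np.ndarray:
    if n < 3:
        return np.zeros((n, n))
    D = np.diff(np.eye(n), n=2, axis=0)
    return D.T @ D


def _gcv_lambda(BtB, Pen, Bty, y_flat, X_design):
    """Pick the roughness penalty weight by generalized cross-validation."""
    n = y_flat.size
    best = (np.inf, 0.0, None)
    for lam in np.logspace(-6, 4, 26):
        A = BtB + lam * Pen
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        c = Ainv @ Bty
        resid = y_flat - X_design @ c
        edf = float(np.trace(Ainv @ BtB))
        denom = max(n - edf, 1e-8)
        gcv = n * float(resid @ resid) / denom**2
        if gcv < best[0]:
            best = (gcv, lam, c)
    if best[2] is None:
        raise ValidationError("smoothing-spline fit failed for every penalty weight")
    return best[1], best[2]


def fit_spatiotemporal(
    waveforms: Sequence[FlowWaveform],
    smoothing: str | float | None = "gcv",
    z_step: float = 1.0,
    n_t: int | None = None,
) -> FlowField:
    """Fit the spatio-temporal flow surface through per-level waveforms.

    A tensor-product cubic B-spline (linear in z when only two levels
    exist) with a second-difference roughness penalty is fitted to the
    level × time samples; the penalty weight is chosen by generalized
    cross-validation (``smoothing="gcv"``), set explicitly
    (``smoothing=<float>``), or dropped (``smoothing=None``), in which
    case the surface interpolates the samples.

    All waveforms must share a common normalized cycle (same period and
    time samples); see :func:`normalize_cycle`.
    """
    if len(waveforms) < 2:
        raise ValidationError("spatio-temporal fit needs at least two axial levels")
    ws = sorted(waveforms, key=lambda w: w.level_z)
    z_levels = np.array([w.level_z for w in ws])
    if np.any(np.diff(z_levels) <= 0):
        raise ValidationError("duplicate axial levels in waveform set")
    T = ws[0].T
    t_data = ws[0].t
    for w in ws[1:]:
        if abs(w.T - T) > 1e-9 or w.t.shape != t_data.shape or np.any(
            np.abs(w.t - t_data) > 1e-9
        ):
            raise ValidationError(
                "waveforms have inconsistent time grids; normalize cycles first"
            )
    Y = np.vstack([w.Q for w in ws])  # (n_z, n_t)

    kz = min(3, z_levels.size - 1)
    kt = min(3, t_data.size - 1)
    tz = _interp_knots(z_levels, kz)
    tt = _interp_knots(t_data, kt)
    Bz = BSpline.design_matrix(z_levels, tz, kz).toarray()
    Bt = BSpline.design_matrix(t_data, tt, kt).toarray()

    if smoothing is None or smoothing == "none" or smoothing == 0:
        # square interpolation system per dimension
        C = np.linalg.solve(Bz, np.linalg.solve(Bt, Y.T).T)
    else:
        # column-major vec: (Bt ⊗ Bz) vec(C) = vec(Bz C Btᵀ)
        X = np.kron(Bt, Bz)
        y_flat = Y.flatten(order="F")
        BtB = X.T @ X
        Pen = np.kron(np.eye(Bt.shape[1]), _second_diff_penalty(Bz.shape[1])) + np.kron(
            _second_diff_penalty(Bt.shape[1]), np.eye(Bz.shape[1])
        )
        if smoothing == "gcv":
            lam, c = _gcv_lambda(BtB, Pen, X.T @ y_flat, y_flat, X)
            log.debug("GCV selected smoothing weight %.3g", lam)
        else:
            lam = float(smoothing)
            c = np.linalg.solve(BtB + lam * Pen, X.T @ y_flat)
        C = c.reshape((Bz.shape[1], Bt.shape[1]), order="F")

    n_z = max(int(round((z_levels[-1] - z_levels[0]) / z_step)), 1)
    z_dense = np.linspace(z_levels[0], z_levels[-1], n_z + 1)
    if n_t is None:
        n_t = max(4 * t_data.size, 64)
    t_dense = np.linspace(t_data[0], t_data[-1], n_t)
    Bz_d = BSpline.design_matrix(z_dense, tz, kz).toarray()
    Bt_d = BSpline.design_matrix(t_dense, tt, kt).toarray()
    Q = Bz_d @ C @ Bt_d.T
    return FlowField(z=z_dense, t=t_dense, Q=Q, T=T, levels=z_levels,
                     _spline=(tz, kz, tt, kt, C))


def extract_peaks(field: FlowField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Systolic and diastolic peak flow and amplitude at each z.

    Under the caudal-negative convention the systolic peak is the global
    minimum over the cycle, the diastolic peak the global maximum, and
    the flow amplitude their difference ``Q_a = Q_dia - Q_sys >= 0``.
    """
    Q_sys = field.Q.min(axis=1)
    Q_dia = field.Q.max(axis=1)
    return Q_sys, Q_dia, Q_dia - Q_sys


def stroke_volume(field: FlowField) -> np.ndarray:
    """Stroke volume SV(z) = ∫|Q(z, t)| dt over one full cycle (mL).

    The cycle is closed periodically (Q at t = T equals Q at t = 0)
    before trapezoidal integration.
    """
    t = np.append(field.t, field.t[0] + field.T)
    Q = np.hstack([field.Q, field.Q[:, :1]])
    return np.trapezoid(np.abs(Q), t, axis=1)


def pwv_from_arrivals(z_mm: np.ndarray, arrival_s: np.ndarray) -> float:
    """PWV (m/s) from peak-arrival times via OLS of arrival time on z.

    The fitted slope is dt/dz (s/mm); its inverse, converted to m/s, is
    the wave speed. A flat arrival profile (zero slope) yields +inf —
    the peak arrives everywhere simultaneously.
    """
    z_mm = np.asarray(z_mm, dtype=float)
    arrival_s = np.asarray(arrival_s, dtype=float)
    if z_mm.size < 2 or np.ptp(z_mm) == 0:
        raise ValidationError("PWV needs at least two distinct axial positions")
    slope = np.polyfit(z_mm, arrival_s, 1)[0]  # s/mm
    span = np.ptp(arrival_s)
    if abs(slope) < 1e-15 or span == 0:
        return float("inf")
    return 1.0 / slope / 1000.0  # mm/s -> m/s


def _refined_arrivals(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Systolic-peak times per row, with parabolic sub-sample refinement."""
    j = np.argmin(Q, axis=1)
    arrival = t[j].astype(float)
    idx = np.flatnonzero((j > 0) & (j < t.size - 1))
    if idx.size:
        jm = j[idx]
        y0, y1, y2 = Q[idx, jm - 1], Q[idx, jm], Q[idx, jm + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / denom, 0.0)
        dt = t[1] - t[0]
        arrival[idx] = t[jm] + np.clip(shift, -0.5, 0.5) * dt
    return arrival


def pulse_wave_velocity(field: FlowField) -> tuple[float, np.ndarray]:
    """Pulse wave velocity and the systolic-peak arrival-time profile.

    The arrival time is the cycle time of the systolic (most negative)
    flow peak; PWV is the inverse OLS slope of arrival time on z,
    positive for caudally propagating peaks. When the field records the
    measured slice locations, the regression runs on the peaks at those
    levels (where the spline is anchored by data); otherwise every dense
    z column is used.
    """
    if field.z.size < 3:
        raise ValidationError("PWV estimation needs at least three axial positions")
    if field.levels is not None and field._spline is not None and field.levels.size >= 3:
        Q = field.evaluate(field.levels, field.t)
        z_pts = field.levels
    else:
        Q, z_pts = field.Q, field.z
    arrival = _refined_arrivals(Q, field.t)
    return pwv_from_arrivals(z_pts, arrival), arrival


def summarize_flow(field: FlowField) -> FlowSummary:
    """All per-z flow descriptors plus PWV in one pass."""
    Q_sys, Q_dia, Q_a = extract_peaks(field)
    sv = stroke_volume(field)
    pwv, arrival = pulse_wave_velocity(field)
    arrival_z = (
        field.levels
        if field.levels is not None and arrival.size == field.levels.size
        else field.z
    )
    return FlowSummary(
        z=field.z, Q_sys=Q_sys, Q_dia=Q_dia, Q_a=Q_a, SV=sv,
        arrival_z=arrival_z, arrival_t=arrival, PWV=pwv,
    )
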