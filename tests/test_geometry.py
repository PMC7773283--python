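"""Catheter footprint, SAS derivation, summaries, axial normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfdyn.geometry import (
    catheter_footprint,
    derive_sas_profile,
    normalize_axial,
    summarize_geometry,
)
from csfdyn.types import AxialGrid, AxialProfile, CatheterSpec, ValidationError


def make_profile(grid, A_c, A_d, P_c, P_d):
    n = grid.n
    return AxialProfile(
        grid=grid,
        A_c=np.full(n, A_c) if np.isscalar(A_c) else A_c,
        A_d=np.full(n, A_d) if np.isscalar(A_d) else A_d,
        P_c=np.full(n, P_c) if np.isscalar(P_c) else P_c,
        P_d=np.full(n, P_d) if np.isscalar(P_d) else P_d,
    )


class TestCatheterFootprint:
    def test_cervical_like_two_segments(self):
        grid = AxialGrid.uniform(310.0, 1.0)
        cath = CatheterSpec(tip_z=60.0, entry_z=310.0)
        fp = catheter_footprint(cath, grid)
        z = grid.z
        distal = (z >= 60) & (z < 160)  # 10 cm piece, OD 0.99
        middle = (z >= 160) & (z <= 310)  # 24 cm piece, OD 1.98
        assert np.allclose(fp.A_cath[distal], math.pi / 4 * 0.99**2)
        assert np.allclose(fp.A_cath[distal], 0.7698, atol=5e-5)
        assert np.allclose(fp.A_cath[middle], math.pi / 4 * 1.98**2)
        assert np.allclose(fp.A_cath[middle], 3.0791, atol=5e-5)
        assert np.allclose(fp.P_cath[distal], math.pi * 0.99)
        assert np.all(fp.A_cath[z < 60] == 0.0)

    def test_lumbar_like_single_segment(self):
        grid = AxialGrid.uniform(310.0, 1.0)
        cath = CatheterSpec(tip_z=250.0, entry_z=310.0)
        fp = catheter_footprint(cath, grid)
        inside = (grid.z >= 250) & (grid.z <= 310)
        assert np.allclose(fp.A_cath[inside], math.pi / 4 * 0.99**2)
        assert np.all(fp.A_cath[~inside] == 0.0)

    def test_zero_length_path(self):
        grid = AxialGrid.uniform(300.0, 1.0)
        fp = catheter_footprint(CatheterSpec(tip_z=100.0, entry_z=100.0), grid)
        assert fp.is_empty

    def test_path_outside_sas_rejected(self):
        grid = AxialGrid.uniform(200.0, 1.0)
        with pytest.raises(ValidationError, match="within"):
            catheter_footprint(CatheterSpec(tip_z=60.0, entry_z=310.0), grid)


class TestDeriveSasProfile:
    def test_reference_cell_values(self):
        grid = AxialGrid.uniform(10.0, 1.0)
        prof = derive_sas_profile(make_profile(grid, 14.40, 38.21, 13.39, 21.53))
        assert np.allclose(prof.A_sas, 23.81)
        assert np.allclose(prof.P_sas, 13.39 + 21.53)

    def test_unit_circle_hydraulic_diameter(self):
        # a circular conduit of unit radius: D_h equals its diameter
        grid = AxialGrid.uniform(5.0, 1.0)
        prof = make_profile(grid, 0.0, math.pi, 0.0, 2 * math.pi)
        # A_d > A_c requires cord area 0 < dura; perimeters cord 0
        derived = derive_sas_profile(prof)
        assert np.allclose(derived.D_h, 2.0)

    def test_catheter_adjustment_hand_values(self):
        grid = AxialGrid.uniform(10.0, 1.0)
        prof = make_profile(grid, 14.70, 38.36, 16.00, 22.36)  # A_sas 23.66, P_sas 38.36
        fp = catheter_footprint(
            CatheterSpec(tip_z=0.0, entry_z=10.0, segments=((400.0, 1.98, 1.19),)), grid
        )
        derived = derive_sas_profile(prof, fp)
        assert np.allclose(derived.A_sas, 20.5809, atol=5e-5)
        assert np.allclose(derived.P_sas, 44.5801, atol=5e-5)
        assert np.allclose(derived.D_h, 1.8467, atol=5e-5)

    def test_oversized_catheter_names_z(self):
        grid = AxialGrid.uniform(10.0, 1.0)
        prof = make_profile(grid, 14.0, 16.0, 13.0, 21.0)  # A_sas = 2 mm²
        fp = catheter_footprint(
            CatheterSpec(tip_z=0.0, entry_z=10.0, segments=((400.0, 1.98, 1.19),)), grid
        )
        with pytest.raises(ValidationError, match="z = 0"):
            derive_sas_profile(prof, fp)

    def test_adjustment_is_reversible(self, uniform_profile):
        """Removing the footprint restores A_sas/P_sas exactly."""
        grid = uniform_profile.grid
        fp = catheter_footprint(CatheterSpec(tip_z=60.0, entry_z=285.0), grid)
        bare = derive_sas_profile(uniform_profile)
        with_cath = derive_sas_profile(uniform_profile, fp)
        np.testing.assert_array_equal(with_cath.A_sas + fp.A_cath, bare.A_sas)
        np.testing.assert_array_equal(with_cath.P_sas - fp.P_cath, bare.P_sas)

    @given(od=st.floats(0.2, 2.0), od_larger=st.floats(1.001, 1.5))
    @settings(max_examples=25, deadline=None)
    def test_dh_decreases_with_od(self, od, od_larger):
        grid = AxialGrid.uniform(10.0, 1.0)
        prof = make_profile(grid, 14.70, 38.36, 16.00, 22.36)

        def dh(outer):
            fp = catheter_footprint(
                CatheterSpec(tip_z=0.0, entry_z=10.0,
                             segments=((400.0, outer, outer / 2),)),
                grid,
            )
            return derive_sas_profile(prof, fp).D_h

        assert np.all(dh(od * od_larger) < dh(od))


class TestSummarizeGeometry:
    def test_constant_profile_analytic_volume(self, uniform_profile):
        derived = derive_sas_profile(uniform_profile)
        summ = summarize_geometry(derived)
        # 23.66 mm² × 300 mm = 7098 mm³ = 7.098 mL
        assert summ.V_sas == pytest.approx(7.098, rel=1e-10)
        assert summ.SA_sas == pytest.approx(summ.SA_c + summ.SA_d, rel=1e-12)

    def test_linear_profile_analytic_integral(self):
        grid = AxialGrid.uniform(100.0, 1.0)
        z = grid.z
        prof = make_profile(grid, 1.0 + 0.01 * z, 11.0 + 0.03 * z, 2.0, 5.0)
        summ = summarize_geometry(prof)
        # trapezoid is exact for linear integrands
        v_c_exact = (1.0 * 100 + 0.01 * 100**2 / 2) / 1000
        v_d_exact = (11.0 * 100 + 0.03 * 100**2 / 2) / 1000
        assert summ.V_c == pytest.approx(v_c_exact, rel=1e-10)
        assert summ.V_sas == pytest.approx(v_d_exact - v_c_exact, rel=1e-10)

    def test_equal_integrands_zero_sas_volume(self):
        grid = AxialGrid.uniform(50.0, 1.0)
        prof = make_profile(grid, 10.0, 10.0 + 1e-9, 3.0, 4.0)
        summ = summarize_geometry(prof)
        assert summ.V_sas == pytest.approx(0.0, abs=1e-10)


class TestNormalizeAxial:
    def test_identity_when_lengths_match(self, uniform_profile):
        (out,) = normalize_axial([uniform_profile], uniform_profile.grid.L_sas)
        np.testing.assert_allclose(out.A_c, uniform_profile.A_c, rtol=1e-12)

    def test_linear_field_stretches_exactly(self):
        grid = AxialGrid.uniform(600.0, 1.0)
        prof = make_profile(grid, 1.0 + 0.01 * grid.z, 20.0 + 0.02 * grid.z, 2.0, 5.0)
        (out,) = normalize_axial([prof], 300.0)
        # value at normalized z equals the linear function at stretched coords
        expected = 1.0 + 0.01 * (out.grid.z * 600.0 / 300.0)
        np.testing.assert_allclose(out.A_c, expected, rtol=1e-10)

    def test_common_length_postcondition(self):
        p1 = make_profile(AxialGrid.uniform(280.0, 1.0), 10.0, 30.0, 10.0, 20.0)
        p2 = make_profile(AxialGrid.uniform(320.0, 1.0), 12.0, 33.0, 11.0, 21.0)
        out = normalize_axial([p1, p2], 300.0)
        assert all(p.grid.L_sas == pytest.approx(300.0) for p in out)
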