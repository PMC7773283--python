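"""Domain-type invariants and tabular I/O."""

import numpy as np
import pandas as pd
import pytest

from csfdyn.io import (
    TableDialect,
    read_axial_profile,
    read_flow_waveforms,
    read_summary_table,
    write_flow_waveforms,
    write_summary_table,
)
from csfdyn.types import (
    AxialGrid,
    CatheterSpec,
    FlowWaveform,
    FluidProperties,
    FormatError,
    SubjectRecord,
    ValidationError,
)


class TestAxialGrid:
    def test_uniform_construction(self):
        g = AxialGrid.uniform(300.0, 1.0)
        assert g.dz == 1.0
        assert g.L_sas == 300.0
        assert g.n == 301

    @pytest.mark.parametrize(
        "z",
        [
            [0.0, 2.0, 1.0],  # non-monotone
            [1.0, 2.0, 3.0],  # does not start at the foramen magnum
            [0.0, 1.0, 3.0],  # non-uniform spacing
            [0.0],  # single point
        ],
    )
    def test_invalid_grids_rejected(self, z):
        with pytest.raises(ValidationError):
            AxialGrid(np.array(z))


class TestCatheterSpec:
    def test_default_segments_walk_from_tip(self):
        cath = CatheterSpec(tip_z=60.0, entry_z=299.0)
        z = np.array([59.0, 60.0, 159.9, 160.0, 299.0, 299.5])
        od = cath.od_at(z)
        assert od[0] == 0.0  # rostral of the tip
        assert od[1] == pytest.approx(0.99)
        assert od[2] == pytest.approx(0.99)  # still in the 10 cm distal piece
        assert od[3] == pytest.approx(1.98)
        assert od[4] == pytest.approx(1.98)  # entry point included
        assert od[5] == 0.0  # outside the SAS

    def test_too_short_catheter_rejected(self):
        with pytest.raises(ValidationError, match="span"):
            CatheterSpec(tip_z=0.0, entry_z=300.0, segments=((100.0, 0.99, 0.38),))

    def test_zero_length_path_has_no_footprint(self):
        cath = CatheterSpec(tip_z=100.0, entry_z=100.0)
        assert np.all(cath.od_at(np.linspace(0, 300, 31)) == 0.0)


class TestRecords:
    def test_subject_vocabulary_enforced(self):
        with pytest.raises(ValidationError):
            SubjectRecord(id="X", group="thoracic", timepoint="PRE-2", weight=4, age=4)
        with pytest.raises(ValidationError):
            SubjectRecord(id="X", group="cervical", timepoint="PRE-3", weight=4, age=4)

    def test_fluid_omega_consistent(self):
        fl = FluidProperties()
        assert fl.omega == pytest.approx(2 * np.pi / 0.53, rel=1e-15)


class TestAxialProfileIO:
    def test_constant_profile_csv(self, tmp_path):
        p = tmp_path / "geom.csv"
        p.write_text(
            "z,A_c,A_d,P_c,P_d\n"
            + "\n".join(f"{z},14.40,38.21,13.39,21.53" for z in range(4))
        )
        prof = read_axial_profile(p)
        assert prof.grid.dz == 1.0
        assert prof.grid.L_sas == 3.0
        assert np.allclose(prof.A_c, 14.40)
        assert np.allclose(prof.A_d, 38.21)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_axial_profile(p)

    def test_non_monotone_z_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("z,A_c,A_d,P_c,P_d\n0,1,2,1,1\n2,1,2,1,1\n1,1,2,1,1\n")
        with pytest.raises(ValidationError):
            read_axial_profile(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "short.csv"
        p.write_text("z,A_c,A_d,P_c\n0,1,2,1\n1,1,2,1\n")
        with pytest.raises(FormatError, match="P_d"):
            read_axial_profile(p)

    def test_nonuniform_grid_resampled(self, tmp_path):
        p = tmp_path / "nonuni.csv"
        rows = [(0.0, 10), (1.0, 11), (2.0, 12), (3.0, 13), (4.5, 14.5)]  # linear in z
        p.write_text(
            "z,A_c,A_d,P_c,P_d\n"
            + "\n".join(f"{z},{a},{a + 20},5,8" for z, a in rows)
        )
        prof = read_axial_profile(p)
        assert prof.grid.dz == pytest.approx(1.0)
        assert np.allclose(prof.A_c, 10 + prof.grid.z)  # linear resample exact

    def test_dialect_header_mapping(self, tmp_path):
        p = tmp_path / "mapped.csv"
        p.write_text("pos,cord_area,dura_area,cord_perim,dura_perim\n0,1,3,1,2\n1,1,3,1,2\n")
        dialect = TableDialect(
            columns={"z": "pos", "A_c": "cord_area", "A_d": "dura_area",
                     "P_c": "cord_perim", "P_d": "dura_perim"}
        )
        prof = read_axial_profile(p, dialect)
        assert np.allclose(prof.A_d, 3.0)


class TestFlowWaveformIO:
    def _write(self, path, levels, n_t=20, T=0.5):
        rows = ["level_z,t,Q,T"]
        for z in levels:
            for i in range(n_t):
                rows.append(f"{z},{i * T / n_t},{-0.2 * np.sin(2 * np.pi * i / n_t):.6f},{T}")
        path.write_text("\n".join(rows))

    def test_six_levels_sorted(self, tmp_path):
        p = tmp_path / "flow.csv"
        self._write(p, [250, 0, 60, 130, 20, 190])
        ws = read_flow_waveforms(p)
        assert [w.level_z for w in ws] == [0, 20, 60, 130, 190, 250]
        assert all(w.T == 0.5 for w in ws)
        assert all(w.t.size == 20 for w in ws)

    def test_single_level_rejected(self, tmp_path):
        p = tmp_path / "one.csv"
        self._write(p, [0])
        with pytest.raises(ValidationError, match="two axial levels"):
            read_flow_waveforms(p)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("level_z,t,Q\n0,0.0,0.1\n0,0.1,oops\n10,0.0,0.1\n10,0.1,0.2\n")
        with pytest.raises(FormatError, match="row 1"):
            read_flow_waveforms(p)

    def test_period_inferred_without_T_column(self, tmp_path):
        p = tmp_path / "noT.csv"
        rows = ["level_z,t,Q"]
        for z in (0, 100):
            for i in range(10):
                rows.append(f"{z},{i * 0.05},0.0")
        p.write_text("\n".join(rows))
        ws = read_flow_waveforms(p)
        assert ws[0].T == pytest.approx(0.5)  # t-range plus one step

    def test_flip_sign_dialect(self, tmp_path):
        p = tmp_path / "flip.csv"
        p.write_text("level_z,t,Q\n0,0.0,1.0\n0,0.1,2.0\n10,0.0,1.0\n10,0.1,2.0\n")
        ws = read_flow_waveforms(p, TableDialect(flip_sign=True))
        assert np.all(ws[0].Q < 0)

    def test_round_trip(self, tmp_path):
        w1 = FlowWaveform(0.0, np.linspace(0, 0.45, 10), np.sin(np.arange(10.0)), 0.5)
        w2 = FlowWaveform(50.0, np.linspace(0, 0.45, 10), np.cos(np.arange(10.0)), 0.5)
        p = tmp_path / "rt.csv"
        write_flow_waveforms([w1, w2], p)
        back = read_flow_waveforms(p)
        np.testing.assert_allclose(back[0].Q, w1.Q, rtol=1e-12)
        np.testing.assert_allclose(back[1].t, w2.t, rtol=1e-12)


class TestSummaryTable:
    def _records(self):
        rows = []
        for tp in ("PRE-2", "POST-1", "POST-2"):
            for grp in ("cervical", "lumbar"):
                rows.append({"parameter": "V_sas", "unit": "mL", "group": grp,
                             "timepoint": tp, "mean": 7.0 + 0.1 * len(rows),
                             "sd": 0.5})
        return pd.DataFrame(rows)

    def test_round_trip_exact(self, tmp_path):
        rec = self._records()
        p = tmp_path / "summary.csv"
        write_summary_table(rec, p)
        back = read_summary_table(p)
        merged = rec.merge(back, on=["parameter", "group", "timepoint"],
                           suffixes=("", "_rt"))
        assert len(merged) == len(rec)
        np.testing.assert_allclose(merged["mean"], merged["mean_rt"], rtol=1e-12)
        np.testing.assert_allclose(merged["sd"], merged["sd_rt"], rtol=1e-12)

    def test_grand_mean_matches_pooled(self, tmp_path):
        rec = self._records()
        p = tmp_path / "summary.csv"
        write_summary_table(rec, p)
        wide = pd.read_csv(p)
        cell_means = wide.filter(like=" mean").iloc[0]
        assert cell_means.mean() == pytest.approx(rec["mean"].mean(), rel=1e-12)

    def test_mixed_units_rejected(self, tmp_path):
        rec = self._records()
        rec.loc[0, "unit"] = "cm^3"
        with pytest.raises(ValidationError, match="mixed units"):
            write_summary_table(rec, tmp_path / "bad.csv")

    def test_single_record_single_row(self, tmp_path):
        rec = self._records().iloc[:1]
        p = tmp_path / "one.csv"
        write_summary_table(rec, p)
        assert len(pd.read_csv(p)) == 1
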