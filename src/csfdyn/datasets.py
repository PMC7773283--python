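"""Bundled reference data.

``reference_group_summary`` returns the published group mean ± SD
summary table from an eight-animal cynomolgus-monkey study of
intrathecal catheter implantation: two implantation groups (cervical,
lumbar) × three MRI time points (PRE-2 before implantation, POST-1 and
POST-2 after), for 22 geometric and hydrodynamic parameters averaged
along the spine. It serves as the magnitude reference the synthetic
generator targets and as input to the report aggregator.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["reference_group_summary"]

# parameter, unit, then (mean, sd) per cell in the order
# PRE-2C, PRE-2L, POST-1C, POST-1L, POST-2C, POST-2L
_TABLE = """\
parameter,unit,m1,s1,m2,s2,m3,s3,m4,s4,m5,s5,m6,s6
P_c,mm,13.39,2.06,14.06,1.64,13.31,2.10,14.09,1.44,13.79,2.13,14.65,1.20
P_d,mm,21.53,1.96,22.30,1.66,21.81,1.91,22.30,1.47,22.05,1.97,22.55,1.38
P_sas,mm,35.72,4.38,37.46,3.91,39.29,4.15,38.06,3.08,40.60,4.82,39.02,2.88
A_c,mm^2,14.40,2.72,15.47,3.07,14.89,3.25,16.12,2.57,15.46,3.46,16.24,2.25
A_d,mm^2,38.21,6.22,40.10,5.89,38.89,6.00,40.05,5.11,39.91,6.05,40.72,4.88
A_sas,mm^2,23.81,4.66,24.63,4.31,22.51,4.50,23.76,3.76,22.96,4.17,24.30,3.62
SA_c,cm^2,40.24,3.38,42.40,2.71,38.68,1.67,41.32,2.80,39.85,3.43,42.97,1.76
SA_d,cm^2,64.85,3.83,67.37,3.54,63.59,4.72,65.55,3.03,63.87,4.90,66.32,2.47
SA_sas,cm^2,105.09,7.17,109.78,6.07,102.27,6.12,106.87,5.74,103.72,8.22,109.29,4.22
V_c,mL,4.33,0.39,4.70,0.59,4.35,0.41,4.76,0.44,4.48,0.39,4.80,0.32
V_d,mL,11.51,1.18,12.13,1.21,11.35,1.10,11.80,0.95,11.59,1.03,12.00,0.87
V_sas,mL,7.17,0.82,7.43,0.79,6.57,0.77,6.99,0.57,6.68,0.67,7.15,0.58
D_h,mm,2.67,0.34,2.66,0.37,2.35,0.43,2.54,0.34,2.31,0.29,2.52,0.29
Re,-,32.32,14.12,28.51,13.12,15.13,11.74,21.77,11.61,10.79,6.58,21.45,13.03
alpha,-,5.45,0.86,5.43,0.65,4.61,1.04,5.05,0.66,4.42,0.56,5.09,0.59
U_peak_sys,cm/s,-0.92,0.42,-0.84,0.36,-0.49,0.40,-0.63,0.32,-0.34,0.21,-0.64,0.39
U_peak_dia,cm/s,0.66,0.30,0.56,0.23,0.40,0.29,0.46,0.23,0.32,0.19,0.49,0.26
Q_peak_sys,mL/s,-0.21,0.09,-0.19,0.08,-0.11,0.08,-0.15,0.08,-0.08,0.04,-0.15,0.09
Q_peak_dia,mL/s,0.15,0.06,0.13,0.05,0.08,0.05,0.11,0.05,0.07,0.04,0.11,0.06
Q_a,mL/s,0.36,0.22,0.32,0.25,0.19,0.11,0.25,0.20,0.15,0.08,0.26,0.21
SV,mL,0.06,0.02,0.05,0.03,0.03,0.02,0.05,0.03,0.03,0.01,0.04,0.03
PWV,m/s,1.15,1.21,1.11,0.21,1.25,0.59,1.16,0.52,1.16,0.06,1.09,0.21
"""

_CELLS = (
    ("PRE-2", "cervical"),
    ("PRE-2", "lumbar"),
    ("POST-1", "cervical"),
    ("POST-1", "lumbar"),
    ("POST-2", "cervical"),
    ("POST-2", "lumbar"),
)


def reference_group_summary() -> pd.DataFrame:
    """Published group summaries, long format.

    Columns: parameter, unit, group, timepoint, mean, sd — the layout
    :func:`csfdyn.io.write_summary_table` consumes.
    """
    wide = pd.read_csv(StringIO(_TABLE))
    records = []
    for _, row in wide.iterrows():
        for i, (tp, grp) in enumerate(_CELLS, start=1):
            records.append(
                {
                    "parameter": row["parameter"],
                    "unit": row["unit"],
                    "group": grp,
                    "timepoint": tp,
                    "mean": row[f"m{i}"],
                    "sd": row[f"s{i}"],
                }
            )
    return pd.DataFrame(records)
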