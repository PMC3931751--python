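"""Bundled reference measurements from the assay's published validation study.

Two small tables ship with the package:

- :func:`reference_cohort` — per-sample normalized expression (molecules per
  1e6 ACTB) of MYC, E2F1 and CDKN1A with replicate SD/CV and the published
  LCDT index for 10 benign (SB) and 10 malignant (SM) surgical FFPE lung
  samples.  Used as the worked diagnostics example and as the calibration
  anchor for the cohort simulator's class medians.
- :func:`interday_wells` / :func:`interday_expected` — one FFPE sample (SM8)
  measured for ACTB and MYC in seven PCR reactions over five days, the
  worked example for external-standard (ESM) drift correction.  The published
  values are rounded (Cq to one decimal, quantities to two significant
  figures), so recomputation from the Cq columns reproduces the quantity
  columns at two significant figures for the day-1 row and within printed
  rounding elsewhere.

The per-day calibrator rows in :func:`interday_wells` are synthetic summary
wells: only the mean ESM Cq difference per day and gene was published, so it
is encoded as a single well with ``nt_cq`` equal to that difference and
``is_cq = 0`` (the arithmetic is identical to averaging the underlying pair
of calibrator wells).
"""
from __future__ import annotations

import io

import pandas as pd

# sample_id, class, MYC (ave, sd, cv), E2F1 (...), CDKN1A (...), published index
_COHORT_CSV = """\
sample_id,class_label,MYC,MYC_sd,MYC_cv,E2F1,E2F1_sd,E2F1_cv,CDKN1A,CDKN1A_sd,CDKN1A_cv,LCDT
SB1,benign,1.5e4,1.2e4,0.83,6.7e2,3.9e2,0.58,3.6e4,1.5e4,0.41,2.8e2
SB2,benign,2.1e4,8.6e3,0.42,1.3e3,9.6e2,0.77,5.8e4,9.5e3,0.16,4.5e2
SB3,benign,4.1e3,4.9e2,0.12,2.8e3,1.0e3,0.35,3.1e4,2.2e3,0.07,3.8e2
SB4,benign,7.4e3,1.0e3,0.14,1.5e3,4.5e2,0.30,3.0e4,2.6e3,0.09,3.6e2
SB5,benign,1.8e3,3.1e2,0.17,1.4e3,1.7e2,0.12,1.1e4,5.7e2,0.05,2.4e2
SB6,benign,3.2e3,5.7e2,0.18,1.3e3,2.7e2,0.20,4.1e4,1.0e4,0.25,1.1e2
SB7,benign,8.1e3,2.4e3,0.30,7.5e3,3.7e3,0.49,4.0e4,1.3e4,0.32,1.5e3
SB8,benign,9.5e3,3.1e3,0.33,1.3e3,8.5e2,0.65,5.4e4,3.2e3,0.06,2.3e2
SB9,benign,6.6e3,1.2e3,0.18,7.1e2,4.8e2,0.69,2.4e4,7.4e3,0.31,2.0e2
SB10,benign,2.7e4,6.8e3,0.26,9.5e2,6.3e2,0.66,7.6e4,2.6e4,0.35,3.3e2
SM1,malignant,1.5e4,3.8e3,0.25,6.1e3,2.7e3,0.45,5.1e4,2.3e4,0.45,1.8e3
SM2,malignant,7.4e3,1.6e3,0.22,8.2e3,2.3e3,0.28,2.2e4,5.5e3,0.25,2.8e3
SM3,malignant,1.2e4,4.0e3,0.33,1.2e3,5.0e2,0.43,1.6e4,4.4e3,0.28,8.9e2
SM4,malignant,1.4e4,2.7e3,0.20,1.2e3,5.2e2,0.43,4.4e4,7.7e3,0.17,3.8e2
SM5,malignant,1.2e4,3.1e3,0.26,1.8e3,3.5e2,0.20,1.8e4,5.1e3,0.29,1.2e3
SM6,malignant,7.7e3,1.8e3,0.23,4.2e3,1.9e3,0.45,1.9e4,3.7e3,0.20,1.7e3
SM7,malignant,9.3e3,2.9e3,0.31,2.0e4,6.4e3,0.31,5.0e4,1.7e4,0.33,3.8e3
SM8,malignant,9.8e3,3.4e3,0.35,2.8e3,1.3e3,0.47,3.6e4,1.4e4,0.39,7.6e2
SM9,malignant,1.3e4,1.6e3,0.12,3.2e3,1.3e2,0.04,2.6e4,8.5e3,0.33,1.7e3
SM10,malignant,1.0e4,1.9e3,0.19,2.4e3,9.9e2,0.41,2.9e4,1.1e4,0.40,8.7e2
"""

# SM8 inter-day experiment: per measurement the ISM used and both genes' Cq.
# Columns: day, measurement id, ism, ACTB NT/IS Cq, MYC NT/IS Cq.
_INTERDAY_CSV = """\
day,meas,ism_id,actb_nt,actb_is,myc_nt,myc_is
1,m1,ISM-D,11.7,13.0,16.7,18.5
2,m2,ISM-D,11.8,11.3,19.7,16.4
2,m3,ISM-E,11.7,11.0,18.7,19.0
3,m4,ISM-D,11.6,10.8,19.8,16.9
3,m5,ISM-E,12.2,11.2,19.8,20.4
4,m6,ISM-D,18.0,16.6,26.2,24.3
5,m7,ISM-D,12.1,13.6,20.2,19.7
"""

# Published mean ESM [NT Cq - IS Cq] per day and gene.
_ESM_OFFSETS = {
    ("1", "ACTB"): -2.0, ("1", "MYC"): -3.0,
    ("2", "ACTB"): 0.0, ("2", "MYC"): 2.3,
    ("3", "ACTB"): -0.6, ("3", "MYC"): 1.7,
    ("4", "ACTB"): 0.5, ("4", "MYC"): 0.9,
    ("5", "ACTB"): -2.1, ("5", "MYC"): -0.5,
}

# Published quantities per measurement: molecules/assay per gene and the
# normalized value, without and with ESM correction (2 significant figures).
_INTERDAY_EXPECTED_CSV = """\
meas,actb_molecules,myc_molecules,myc_per_million,actb_molecules_esm,myc_molecules_esm,myc_per_million_esm
m1,1.5e6,2.1e4,1.4e4,3.8e5,2.5e3,6.6e3
m2,4.3e5,6.0e2,1.4e3,4.5e5,2.9e3,6.5e3
m3,3.7e5,7.1e2,1.9e3,3.8e5,3.4e3,8.8e3
m4,3.4e5,8.1e2,2.4e3,2.3e5,2.7e3,1.2e4
m5,3.0e5,9.0e2,3.0e3,2.0e5,2.9e3,1.5e4
m6,2.3e5,1.6e3,7.0e3,3.3e5,2.9e3,8.8e3
m7,1.7e6,4.3e3,2.5e3,3.9e5,3.0e3,7.7e3
"""


def reference_cohort() -> pd.DataFrame:
    """The 20-sample FFPE validation cohort (normalized expression + LCDT)."""
    return pd.read_csv(io.StringIO(_COHORT_CSV))


def interday_wells() -> pd.DataFrame:
    """The SM8 inter-day experiment as a wells table (one plate per day).

    Sample wells carry the measured ACTB and MYC Cq pairs; per-day synthetic
    calibrator wells encode the published mean ESM Cq difference (see module
    docstring).  Each of the seven PCR measurements is its own analytic unit
    (sample_id ``SM8-m1`` ... ``SM8-m7``) so that every MYC value is
    normalized against its own reaction's ACTB.  Quantifying with
    ``esm_correction=False`` reproduces the uncorrected block; with per-plate
    correction, the corrected block.
    """
    meas = pd.read_csv(io.StringIO(_INTERDAY_CSV), dtype={"day": str})
    rows = []
    for _, m in meas.iterrows():
        plate = f"day{m['day']}"
        for gene, nt, is_ in (("ACTB", m["actb_nt"], m["actb_is"]), ("MYC", m["myc_nt"], m["myc_is"])):
            rows.append(
                dict(plate_id=plate, well_id=f"{m['meas']}-{gene}", sample_id=f"SM8-{m['meas']}",
                     role="sample", ism_id=m["ism_id"], gene=gene, nt_cq=nt, is_cq=is_)
            )
    for (day, gene), offset in _ESM_OFFSETS.items():
        rows.append(
            dict(plate_id=f"day{day}", well_id=f"esm-{gene}", sample_id="ESM",
                 role="esm", ism_id="ESM", gene=gene, nt_cq=offset, is_cq=0.0)
        )
    return pd.DataFrame(rows)


def interday_expected() -> pd.DataFrame:
    """Published per-measurement quantities of the SM8 inter-day experiment."""
    return pd.read_csv(io.StringIO(_INTERDAY_EXPECTED_CSV))
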