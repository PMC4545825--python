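"""Synthetic SEAR-D chart construction.

The published WHO/ISH SEAR-D figures are colour charts, not machine
readable tables, and no transcription is bundled here.  This module
synthesizes a stand-in pair of tables with the structural properties
that matter for analysis of the charts: five ordinal bands, monotone
increase of risk along age, systolic blood pressure and total
cholesterol within every (gender, smoker, diabetes) panel, and an LI
variant that behaves like the HI variant evaluated at a reference
cholesterol.  Absolute cell values are NOT those of the published
charts.

The generator quantizes a latent logistic 10-year-risk surface at a
representative point of each cell.  Because the surface is strictly
monotone in each factor and representative points are ordered with the
bands, the resulting tables are monotone by construction.
"""

from __future__ import annotations

from scipy.special import expit

from .charts import (AGE_BANDS, SBP_BANDS, TC_BANDS, GENDERS,
                     ChartTable, RiskBand)

# Representative (mid-cell) values used to evaluate the latent surface.
AGE_REP = {40: 45.0, 50: 55.0, 60: 65.0, 70: 75.0}
SBP_REP = {120: 130.0, 140: 150.0, 160: 170.0, 180: 190.0}
TC_REP = {4: 4.5, 5: 5.5, 6: 6.5, 7: 7.5, 8: 8.5}

#: cholesterol (mmol/l) at which the LI table evaluates the surface
TC_REFERENCE_MMOLL = 5.5

# Latent surface coefficients (logit scale).  Chosen once so that the
# corner cells span the full band range (young/low-SBP female
# non-smoker non-diabetic well under 10%; old smoking diabetic male at
# high SBP/TC above 40%) and band boundaries fall in the age/SBP region
# where an APHRI-like population actually sits.
INTERCEPT = -3.0          # at age 55, SBP 140, TC 5.5, female, non-smoker, non-diabetic
BETA_AGE = 0.09           # per year (one band per decade row near the boundaries)
BETA_SBP = 0.05           # per mmHg (the four SBP rows cross about three bands,
                          # matching the steep pressure axis of the charts)
BETA_TC = 0.42            # per mmol/l
BETA_MALE = 0.35
BETA_SMOKER = 0.55
BETA_DIABETES = 0.65

_BAND_CUTS = (10.0, 20.0, 30.0, 40.0)


def latent_risk_pct(gender: str, smoker: bool, diabetes: bool,
                    age: float, sbp: float, tc_mmoll: float) -> float:
    """Latent 10-year CVD risk (%) of the synthetic surface."""
    eta = (INTERCEPT
           + BETA_AGE * (age - 55.0)
           + BETA_SBP * (sbp - 140.0)
           + BETA_TC * (tc_mmoll - TC_REFERENCE_MMOLL)
           + BETA_MALE * (gender == "male")
           + BETA_SMOKER * smoker
           + BETA_DIABETES * diabetes)
    return 100.0 * expit(eta)


def band_from_pct(pct: float) -> RiskBand:
    level = sum(pct >= c for c in _BAND_CUTS)
    return RiskBand(level)


def synthesize_seard_tables() -> tuple[ChartTable, ChartTable]:
    """Build the synthetic (LI, HI) SEAR-D stand-in tables."""
    li_cells, hi_cells = {}, {}
    for g in GENDERS:
        for sm in (False, True):
            for db in (False, True):
                for ab in AGE_BANDS:
                    for sb in SBP_BANDS:
                        li_pct = latent_risk_pct(g, sm, db, AGE_REP[ab],
                                                 SBP_REP[sb], TC_REFERENCE_MMOLL)
                        li_cells[(g, sm, db, ab, sb)] = band_from_pct(li_pct)
                        for tb in TC_BANDS:
                            hi_pct = latent_risk_pct(g, sm, db, AGE_REP[ab],
                                                     SBP_REP[sb], TC_REP[tb])
                            hi_cells[(g, sm, db, ab, sb, tb)] = band_from_pct(hi_pct)
    li = ChartTable(variant="li", region="SEAR-D", cells=li_cells)
    hi = ChartTable(variant="hi", region="SEAR-D", cells=hi_cells)
    return li, hi
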