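"""Published summary numbers for the STAR-MH validation cohort.

The raw item-response data of the validation study were never deposited; what
is public are the printed summary tables.  Those numbers are inputs to the
sample-accounting and cut-score arithmetic (they are the only way to recompute
the published participation rate, endorsement percentages, likelihood ratios
and the Youden cut-score choice) and they anchor the synthetic-cohort
generator.  Everything in this module is transcribed from the published
validation-sample tables.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Recruitment and retention
# ---------------------------------------------------------------------------

#: Persons recruited / declined at each pilot site (community resource centre
#: and community health service).
RECRUITED_PER_SITE = {"ASRC": 87, "MHC": 105}
DECLINED_PER_SITE = {"ASRC": 85, "MHC": 10}

#: Screened cohort size and the records dropped for missing scale answers.
N_SCREENED = 192
N_MISSING_OMITTED = 7
N_ANALYZED = 185

#: Structured-interview caseness (MDD and/or PTSD) among the analysed cohort.
N_CASES = 61

# ---------------------------------------------------------------------------
# Item endorsement ("yes" counts among N_ANALYZED; two items have missing
# cells, percentages are nevertheless on the full denominator)
# ---------------------------------------------------------------------------

ENDORSEMENT_COUNTS = {
    "restless": (55, 130),
    "interest": (55, 130),
    "crazy": (48, 137),
    "sleep": (62, 122),      # 1 missing; dropped from the final 7-item scale
    "fearful": (62, 123),
    "trapped": (59, 126),
    "pain": (61, 124),
    "worthless": (54, 131),
}

# ---------------------------------------------------------------------------
# Rasch difficulties of the final 7-item scale (logits, sum-zero convention;
# the printed column sums to 0.01)
# ---------------------------------------------------------------------------

SCALE_ITEMS = ["restless", "interest", "crazy", "fearful", "trapped", "pain", "worthless"]
SCREEN_IN_ITEMS = ["help_seeking", "suicidality"]

ITEM_DIFFICULTIES = {
    "restless": 0.06,
    "interest": 0.06,
    "crazy": 0.40,
    "fearful": -0.27,
    "trapped": -0.13,
    "pain": -0.22,
    "worthless": 0.11,
}

# ---------------------------------------------------------------------------
# Per-cutoff sensitivity / specificity of the 7-item score (percent), as
# printed in the published diagnostic-accuracy table.
# ---------------------------------------------------------------------------

PUBLISHED_SN_SP_PCT = {
    1: (96.7, 63.1),
    2: (93.4, 74.6),
    3: (83.6, 84.6),
    4: (73.8, 91.5),
    5: (55.7, 95.4),
    6: (32.8, 98.5),
    7: (16.4, 98.5),
}

#: Published headline accuracy of the 7-item score against caseness.
PUBLISHED_AUC = 0.912
PUBLISHED_AUC_CI = (0.868, 0.956)
PUBLISHED_OPTIMISM_CORRECTED_AUC = 0.911
PUBLISHED_PSI = 0.75
PUBLISHED_MEAN_INTERITEM_R = 0.46

#: Covariate marginal frequencies of the analysed cohort (used as generator
#: defaults): P(first-listed category).
COVARIATE_FREQUENCIES = {
    "sex": ("male", 0.697),
    "age_group": ("34+", 0.464),
    "interpreter": ("yes", 0.611),
    "agency": ("ASRC", 0.453),
    "origin": ("southern_asia", 0.530),
    "marital": ("partnered", 0.600),
    "travel_mode": ("irregular_maritime", 0.530),
    "detention": ("yes", 0.535),
}
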