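"""Published summary statistics of the motivating routine-care cohort.

A large two-arm psychological-therapy cohort (counselling for depression,
n=1868, vs cognitive-behavioural therapy, n=10888) reported group-level
summaries — means and SDs of questionnaire totals, age and waiting time,
and categorical breakdowns — from which the descriptive effect sizes can
be recomputed without access to the patient-level records. The values here
are those printed summaries, used as *inputs* to
:func:`symptomnet.inference.group_difference_stats`.
"""

from __future__ import annotations

ARM_SIZES = {"cfd": 1868, "cbt": 10888}

MATCHED_PER_ARM = 1673

# (CfD mean, CfD SD, CBT mean, CBT SD)
CONTINUOUS_SUMMARIES = {
    "phq9_total_s1": (16.1, 5.81, 16.7, 5.75),
    "gad7_total_s1": (13.2, 5.21, 14.1, 4.91),
    "phq9_total_s2": (14.4, 6.37, 15.3, 6.07),
    "gad7_total_s2": (12.2, 5.57, 13.2, 5.26),
    "phq9_total_final": (9.23, 6.94, 9.54, 6.80),
    "gad7_total_final": (8.33, 6.12, 8.26, 5.87),
    "n_sessions": (10.4, 3.9, 10.9, 4.6),
    "days_s1_to_s2": (59.9, 49.7, 66.4, 48.9),
    "age": (38.5, 13.10, 42.5, 13.5),
}

# counts per arm: (CfD, CBT)
GENDER_TABLE = {"male": (468, 3515), "female": (1396, 7336)}

ETHNICITY_TABLE = {
    "Asian": (171, 1677),
    "Black": (232, 1301),
    "Chinese": (10, 63),
    "Mixed": (111, 710),
    "Other": (86, 398),
    "White": (1210, 6393),
}


def arm_summary(name: str) -> dict:
    """Summary statistics for one continuous variable, keyed for
    :func:`symptomnet.inference.cohens_d_from_summaries` (arm 1 = CBT)."""
    m0, s0, m1, s1 = CONTINUOUS_SUMMARIES[name]
    return {
        "mean1": m1,
        "sd1": s1,
        "n1": ARM_SIZES["cbt"],
        "mean0": m0,
        "sd0": s0,
        "n0": ARM_SIZES["cfd"],
    }
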