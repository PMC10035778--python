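"""Item-level constants for the PHQ-9 / GAD-7 symptom set.

The network nodes are the 16 items of the two questionnaires, ordered
depression (d1-d9) then anxiety (a1-a7), each scored 0-3.
"""

from __future__ import annotations

DEPRESSION_ITEMS = [
    "anhedonia",
    "depressed_mood",
    "sleep",
    "fatigue",
    "appetite",
    "failure",
    "concentration",
    "psychomotor",
    "suicidal_ideation",
]

ANXIETY_ITEMS = [
    "nervousness",
    "uncontrollable_worry",
    "excessive_worry",
    "trouble_relaxing",
    "restlessness",
    "easily_annoyed",
    "apprehensive_expectation",
]

NODE_LABELS = DEPRESSION_ITEMS + ANXIETY_ITEMS

ITEM_CODES = [f"d{i}" for i in range(1, 10)] + [f"a{i}" for i in range(1, 8)]

N_ITEMS = 16

SESSIONS = ("s1", "s2", "final")


def item_columns(session: str) -> list[str]:
    """CSV column names for one measurement occasion, e.g. ``d1_s1 .. a7_s1``."""
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}; expected one of {SESSIONS}")
    return [f"{code}_{session}" for code in ITEM_CODES]


COVARIATE_COLUMNS = [
    "age",
    "gender",
    "employed",
    "medication",
    "ethnicity",
    "impairment",
]

ETHNICITY_CATEGORIES = ["White", "Mixed", "Asian", "Black", "Chinese", "Other"]
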