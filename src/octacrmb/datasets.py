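"""Bundled example data.

The demographics summary below describes a published 73-subject
case-control cohort (43 vein-occlusion eyes, 30 healthy controls) at the
precision of the published table; it drives the worked examples and the
demographics-statistics reproduction in the acceptance script.
"""

from __future__ import annotations

import pandas as pd

_RVO_DEMOGRAPHICS = [
    # row, kind, then binary counts (a/b group1 yes/no, c/d group2) or summaries
    {"row": "sex_men", "kind": "binary", "a": 19, "b": 24, "c": 17, "d": 13},
    {"row": "eye_right", "kind": "binary", "a": 22, "b": 21, "c": 15, "d": 15},
    {"row": "age_years", "kind": "continuous",
     "mean1": 55.42, "sd1": 12.95, "n1": 43, "mean2": 44.74, "sd2": 15.37, "n2": 30},
    {"row": "diabetes", "kind": "binary", "a": 2, "b": 41, "c": 0, "d": 30},
    {"row": "hypertension", "kind": "binary", "a": 15, "b": 28, "c": 0, "d": 30},
    {"row": "hyperlipidaemia", "kind": "binary", "a": 6, "b": 37, "c": 0, "d": 30},
    {"row": "atherosclerosis", "kind": "binary", "a": 11, "b": 32, "c": 1, "d": 29},
    {"row": "bcva_initial", "kind": "continuous",
     "mean1": 0.43, "sd1": 0.29, "n1": 43, "mean2": 0.93, "sd2": 0.10, "n2": 30},
]


def rvo_demographics_summary() -> pd.DataFrame:
    """Group-level demographic summaries of the example RVO cohort.

    One row per tested characteristic; binary rows carry yes/no counts for
    each group, continuous rows carry mean, SD and n. Feed to
    :func:`octacrmb.stats.demographics_from_summary`.
    """
    return pd.DataFrame(_RVO_DEMOGRAPHICS)
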