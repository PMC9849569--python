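"""Questionnaire scoring and internal-consistency reliability.

PHQ-9 totals range 0-27 and GAD-7 totals 0-21; a total of 10 or above on
either scale flags clinically relevant symptom levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import ITEM_COLUMNS, ItemPanel

PHQ_COLUMNS = ITEM_COLUMNS[:9]
GAD_COLUMNS = ITEM_COLUMNS[9:]
CUTOFF = 10


def total_scores(panel: ItemPanel) -> pd.DataFrame:
    """Scale totals and cutoff flags per participant-wave.

    A participant-wave with any missing item on a scale gets no total for
    that scale (NaN total, missing flag).
    """
    df = panel.data
    out = df[["participant_id", "wave"]].copy()
    for name, cols in (("phq", PHQ_COLUMNS), ("gad", GAD_COLUMNS)):
        block = df[list(cols)]
        complete = block.notna().all(axis=1)
        total = block.sum(axis=1).where(complete)
        out[f"{name}_total"] = total
        out[f"{name}_above_cutoff"] = (total >= CUTOFF).where(complete)
    return out


def cronbach_alpha(X: np.ndarray) -> float:
    """Cronbach's alpha, alpha = k/(k-1) * (1 - sum(var_items)/var_total).

    Sample (n-1) variances throughout. Requires >= 2 items, >= 2 respondents
    and a nonzero total-score variance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two items")
    if X.shape[0] < 2:
        raise ValueError("need at least two respondents")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return (k / (k - 1)) * (1.0 - item_var.sum() / total_var)
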