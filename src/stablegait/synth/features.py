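"""Direct synthetic feature tables with planted group effects.

Bypasses the signal stage: produces a subjects x 96 table of standard
normal columns (optionally block-correlated) in which a chosen subset of
columns is shifted in the impaired group by a given effect size.  Used
to exercise the stable-sparse-classification stage under fully known
conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..features import DUAL_TASKS, STGF_NAMES, TASKS
from .cohort import SubjectRecord

N_FEATURES = 96


def feature_column_names() -> list[str]:
    cols = [f"{t}::{n}" for t in TASKS for n in STGF_NAMES]
    cols += [f"dtc::{d}::{n}" for d in DUAL_TASKS for n in STGF_NAMES]
    return cols


def generate_feature_table(cohort: list[SubjectRecord],
                           planted_features=(),
                           effect_size: float = 0.0,
                           seed: int | None = 0,
                           block_correlation: float = 0.0,
                           block_size: int = 16) -> pd.DataFrame:
    """Standard-normal feature table with the impaired group shifted.

    ``planted_features`` are column indices in [0, 96); those columns are
    shifted by ``effect_size`` (Cohen's d, since columns have unit SD) in
    the MCI-E rows.  ``block_correlation`` > 0 adds equicorrelation
    within consecutive blocks of ``block_size`` columns, mimicking the
    within-task correlation of real gait measures.
    """
    planted = np.asarray(sorted(planted_features), dtype=int)
    if planted.size and (planted.min() < 0 or planted.max() >= N_FEATURES):
        raise IndexError(f"planted feature indices must lie in "
                         f"[0, {N_FEATURES})")
    if effect_size < 0:
        raise ValueError("effect size must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    Z = rng.standard_normal((n, N_FEATURES))
    if block_correlation > 0:
        if not block_correlation < 1:
            raise ValueError("block correlation must be in [0, 1)")
        shared = np.repeat(rng.standard_normal((n, N_FEATURES // block_size)),
                           block_size, axis=1)
        Z = (np.sqrt(block_correlation) * shared
             + np.sqrt(1 - block_correlation) * Z)
    groups = np.array([s.group for s in cohort])
    Z[np.ix_(groups == "MCI-E", planted)] += effect_size
    table = pd.DataFrame(Z, columns=feature_column_names(),
                         index=pd.Index([s.id for s in cohort], name="id"))
    table.insert(0, "label", groups)
    return table
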