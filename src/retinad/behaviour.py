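"""Novel-object-recognition discrimination index.

The D² index corrects for each animal's total exploratory activity:

    D² = (novel - familiar) / (novel + familiar)

ranging from -1 (familiar only) through 0 (no preference) to +1 (novel
only).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .types import NorTrial

log = logging.getLogger(__name__)


def d2_index(trial: NorTrial | tuple[float, float]) -> float:
    """Discrimination index of one trial; undefined when both times are 0."""
    novel, familiar = (
        (trial.novel, trial.familiar) if isinstance(trial, NorTrial) else trial
    )
    if novel < 0 or familiar < 0:
        raise InvalidParameterError("exploration times must be >= 0")
    total = novel + familiar
    if total == 0:
        raise InvalidParameterError("undefined D2 index: zero total exploration")
    return (novel - familiar) / total


def d2_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a ``d2`` column to a trial table (``novel_s``, ``familiar_s``).

    Zero-total trials are excluded (with a logged count) rather than
    propagated as NaN, so group summaries are over valid indices only.
    """
    required = {"novel_s", "familiar_s"}
    if not required.issubset(trials.columns):
        raise InvalidParameterError(f"trial table needs columns {sorted(required)}")
    total = trials.novel_s + trials.familiar_s
    valid = total > 0
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.info("dropping %d zero-total NOR trials", n_dropped)
    out = trials[valid].copy()
    out["d2"] = (out.novel_s - out.familiar_s) / (out.novel_s + out.familiar_s)
    return out


def group_d2_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of D² per genotype × age."""
    table = d2_table(trials)
    return (
        table.groupby(["genotype", "age_months"])
        .d2.agg(mean="mean", sd=lambda v: np.std(v, ddof=1), n="count")
        .reset_index()
    )
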