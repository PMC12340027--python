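"""Per-trial extreme-value metrics and per-subject aggregates.

Listeners may rate the salience of a change not from the full mean shift
but from a handful of outlying stimuli. Four heuristic metrics quantify
that per trial: the jump across the midpoint, the two extreme
cross-half contrasts, and the total range. The condition summaries
(per-subject mean rating and direction accuracy per design cell) are the
input to all group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructuralError
from .paradigm import StimulusSequence, TrialSet

logger = logging.getLogger(__name__)

CONDITION_KEYS = ["precision_level", "mean_change_level", "direction"]
#: metrics reported by default; total_range is computed but not reported
REPORTED_METRICS = ("midpoint_change", "min2_minus_max1", "max2_minus_min1")
ALL_METRICS = REPORTED_METRICS + ("total_range",)


@dataclass(frozen=True)
class ExtremeMetrics:
    midpoint_change: float  # first stimulus of 2nd half minus last of 1st
    min2_minus_max1: float
    max2_minus_min1: float
    total_range: float


def extreme_metrics(sequence: StimulusSequence | np.ndarray) -> ExtremeMetrics:
    """Compute the four extreme-value metrics of one even-length trial.

    The midpoint metric is defined positionally — first stimulus of the
    second half minus last stimulus of the first half — so it applies to
    any sequence length.
    """
    values = sequence.values if isinstance(sequence, StimulusSequence) else np.asarray(sequence, float)
    n = values.size
    if n == 0 or n % 2:
        raise StructuralError(f"extreme metrics need an even-length sequence, got n={n}")
    k = n // 2
    first, second = values[:k], values[k:]
    return ExtremeMetrics(
        midpoint_change=float(second[0] - first[-1]),
        min2_minus_max1=float(second.min() - first.max()),
        max2_minus_min1=float(second.max() - first.min()),
        total_range=float(values.max() - values.min()),
    )


def metrics_frame(trial_set: TrialSet) -> pd.DataFrame:
    """One row per trial: condition fields plus the four metrics."""
    rows = []
    for t in trial_set.trials:
        m = extreme_metrics(t)
        c = t.condition
        rows.append(
            (t.trial_id, c.precision_level, c.mean_change_level, c.direction,
             t.exemplar_index, m.midpoint_change, m.min2_minus_max1,
             m.max2_minus_min1, m.total_range)
        )
    return pd.DataFrame(
        rows,
        columns=["trial_id", *CONDITION_KEYS, "exemplar_index", *ALL_METRICS],
    )


def _attach_conditions(responses: pd.DataFrame, trial_set: TrialSet) -> pd.DataFrame:
    lookup = {
        t.trial_id: (t.condition.precision_level, t.condition.mean_change_level,
                     t.condition.direction, t.exemplar_index)
        for t in trial_set.trials
    }
    missing = set(responses["trial_id"]) - set(lookup)
    if missing:
        raise StructuralError(
            f"{len(missing)} trial_id(s) in responses not found in the trial set"
        )
    cond = pd.DataFrame(
        responses["trial_id"].map(lookup).tolist(),
        index=responses.index,
        columns=[*CONDITION_KEYS, "exemplar_index"],
    )
    return pd.concat([responses, cond], axis=1)


def condition_summaries(responses: pd.DataFrame, trial_set: TrialSet) -> pd.DataFrame:
    """Per subject x condition: mean rating, direction accuracy, trial count.

    Rows with fewer trials than the design's exemplar count (missing
    trials) are kept but logged.
    """
    df = _attach_conditions(responses, trial_set)
    agg = {"psc": "mean", "trial_id": "size"}
    has_correct = "correct" in df.columns and df["correct"].notna().any()
    if has_correct:
        agg["correct"] = "mean"
    out = (
        df.groupby(["subject_id", *CONDITION_KEYS], sort=True, observed=True)
        .agg(agg)
        .reset_index()
        .rename(columns={"psc": "mean_psc", "trial_id": "n_trials", "correct": "accuracy"})
    )
    expected = trial_set.config.n_exemplars_per_condition
    short = out["n_trials"] < expected
    if short.any():
        logger.warning(
            "%d subject x condition cell(s) have fewer than %d trials",
            int(short.sum()), expected,
        )
    if not has_correct:
        out["accuracy"] = np.nan
    return out


def exemplar_group_means(responses: pd.DataFrame, trial_set: TrialSet) -> pd.DataFrame:
    """Mean rating of each exemplar across all subjects (one row per trial)."""
    df = _attach_conditions(responses, trial_set)
    out = (
        df.groupby(["trial_id", *CONDITION_KEYS, "exemplar_index"], sort=True,
                   observed=True)["psc"]
        .mean()
        .reset_index()
        .rename(columns={"psc": "mean_psc"})
    )
    return out
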