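"""Synthetic Likert + direction responders.

The paradigm's three canonical precision–salience regimes are realised
by a minimal latent-variable responder: perceived salience is a linear
combination of change magnitude, (standardised) stimulus precision, an
upward-direction bias and optionally an extreme-value heuristic, plus
Gaussian noise, discretised through three ordered thresholds into a 1–4
rating. The sign of ``beta_prec`` is the regime knob:

* ``beta_prec > 0`` — Bayesian / signal-to-noise pattern,
* ``beta_prec = 0`` — non-Bayesian / precision-indifferent,
* ``beta_prec < 0`` — counter-Bayesian.

The direction choice is a logistic read-out of signed change evidence;
``direction_bias > 0`` encodes a looming-type bias towards reporting
upward changes. This responder is a modelling device for validating the
analysis pipeline by parameter recovery, not a claim about mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, DomainError
from .metrics import extreme_metrics
from .observer import estimate_change
from .paradigm import (
    _RESPONDER_STREAM,
    StimulusSequence,
    TrialSet,
    subject_order,
)

#: standardised precision level entering the latent model
PRECISION_Z = {"low": -1.0, "med": 0.0, "high": 1.0}

EVIDENCE_SOURCES = ("true_params", "ideal_observer", "extreme_heuristic")


@dataclass(frozen=True)
class ResponderParams:
    """Parameters of the latent-salience / logistic-direction responder."""

    beta_mc: float = 1.0  # slope on change magnitude
    beta_prec: float = 0.5  # slope on standardised precision level (regime knob)
    beta_dir: float = 0.25  # additive bonus for upward changes
    beta_extreme: float = 0.0  # weight on the max2-min1 extreme metric
    noise_sd: float = 1.0
    likert_thresholds: tuple[float, float, float] = (-0.5, 0.5, 1.5)
    direction_slope: float = 3.0
    direction_bias: float = 0.0
    evidence_source: str = "true_params"
    lapse_rate: float = 0.0  # probability of a uniform random rating
    between_subject_sd: float = 0.0  # SD of per-subject beta perturbations

    def __post_init__(self) -> None:
        t = self.likert_thresholds
        if len(t) != 3 or not (t[0] < t[1] < t[2]):
            raise ConfigurationError(
                f"likert_thresholds must be 3 strictly increasing reals, got {t}"
            )
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.direction_slope < 0:
            raise DomainError("direction_slope must be >= 0")
        if not 0 <= self.lapse_rate <= 1:
            raise DomainError("lapse_rate must be in [0, 1]")
        if self.evidence_source not in EVIDENCE_SOURCES:
            raise ConfigurationError(
                f"evidence_source must be one of {EVIDENCE_SOURCES}"
            )


#: regime presets used for parameter-recovery validation
REGIMES = {
    "bayesian": ResponderParams(beta_prec=0.5, noise_sd=1.0),
    "non_bayesian": ResponderParams(beta_prec=0.0, noise_sd=1.0),
    "counter_bayesian": ResponderParams(beta_prec=-0.5, noise_sd=1.0),
}


# ---------------------------------------------------------------------------
# per-trial evidence


def _trial_features(trial: StimulusSequence, params: ResponderParams):
    """(magnitude m, signed evidence e, extreme metric x, z(lambda), is_up)."""
    cond = trial.condition
    x = extreme_metrics(trial).max2_minus_min1
    if params.evidence_source == "true_params":
        e = cond.sign * cond.mean_change_value
        m = abs(e)
    elif params.evidence_source == "ideal_observer":
        est = estimate_change(trial, cond.precision_value)
        e = est.delta_hat
        m = abs(e)
    else:  # extreme_heuristic: midpoint jump as signed evidence, x as magnitude
        e = extreme_metrics(trial).midpoint_change
        m = abs(x)
    return m, e, x, PRECISION_Z[cond.precision_level], cond.direction == "up"


def latent_salience(
    trial: StimulusSequence, params: ResponderParams, rng: np.random.Generator
) -> float:
    """Draw the latent salience of one trial for one responder."""
    m, _, x, z, is_up = _trial_features(trial, params)
    noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
    return (
        params.beta_mc * m
        + params.beta_prec * z
        + params.beta_dir * float(is_up)
        + params.beta_extreme * x
        + noise
    )


def to_likert(latent: float | np.ndarray, thresholds: Sequence[float]) -> np.ndarray | int:
    """Ordered-threshold read-out: 1 + #(thresholds strictly below latent).

    A latent exactly equal to a threshold falls in the lower category.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size != 3 or not np.all(np.diff(t) > 0):
        raise ConfigurationError(
            f"thresholds must be 3 strictly increasing reals, got {thresholds}"
        )
    out = np.searchsorted(t, np.asarray(latent, dtype=float), side="left") + 1
    if np.isscalar(latent) or np.ndim(latent) == 0:
        return int(out)
    return out


def choose_direction(
    trial: StimulusSequence, params: ResponderParams, rng: np.random.Generator
) -> str:
    """Logistic choice: P(up) = expit(slope * evidence + bias)."""
    _, e, _, _, _ = _trial_features(trial, params)
    p_up = expit(params.direction_slope * e + params.direction_bias)
    return "up" if rng.random() < p_up else "down"


# ---------------------------------------------------------------------------
# cohorts

RESPONSE_COLUMNS = [
    "subject_id", "trial_id", "presentation_rank", "psc", "direction_choice", "correct",
]


def simulate_cohort(
    trial_set: TrialSet,
    params: ResponderParams,
    n_subjects: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a cohort; one row per subject x trial.

    Each subject gets an independent presentation order and response
    noise stream derived from ``seed``; with ``between_subject_sd > 0``
    the four salience slopes additionally vary across subjects.
    """
    if n_subjects < 2:
        raise ConfigurationError("n_subjects must be >= 2")
    trials = trial_set.trials
    n_trials = len(trials)
    direction_task = trial_set.config.direction_task

    feats = np.array([_trial_features(t, params)[:4] for t in trials], dtype=float)
    m, e, x, z = feats.T
    is_up = np.array([t.condition.direction == "up" for t in trials], dtype=float)
    true_dir_up = is_up.astype(bool)
    trial_ids = np.array([t.trial_id for t in trials])
    thresholds = np.asarray(params.likert_thresholds, dtype=float)

    frames = []
    for s in range(n_subjects):
        ss = np.random.SeedSequence((int(seed), _RESPONDER_STREAM, s))
        rng = np.random.default_rng(ss)
        subject_seed = int(ss.generate_state(1)[0] >> 1)  # < 2**31
        order = subject_order(trial_set, subject_seed)

        b_mc, b_prec, b_dir, b_ext = (
            params.beta_mc, params.beta_prec, params.beta_dir, params.beta_extreme,
        )
        if params.between_subject_sd > 0:
            b_mc, b_prec, b_dir, b_ext = rng.normal(
                [b_mc, b_prec, b_dir, b_ext], params.between_subject_sd
            )

        latent = b_mc * m + b_prec * z + b_dir * is_up + b_ext * x
        if params.noise_sd > 0:
            latent = latent + rng.normal(0.0, params.noise_sd, n_trials)
        psc = np.searchsorted(thresholds, latent, side="left") + 1
        if params.lapse_rate > 0:
            lapse = rng.random(n_trials) < params.lapse_rate
            psc = np.where(lapse, rng.integers(1, 5, n_trials), psc)

        if direction_task:
            p_up = expit(params.direction_slope * e + params.direction_bias)
            chose_up = rng.random(n_trials) < p_up
            direction_choice = np.where(chose_up, "up", "down")
            correct = chose_up == true_dir_up
        else:
            direction_choice = np.full(n_trials, None, dtype=object)
            correct = np.full(n_trials, np.nan)

        rank = np.empty(n_trials, dtype=int)
        rank[order] = np.arange(1, n_trials + 1)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"s{s:03d}",
                    "trial_id": trial_ids,
                    "presentation_rank": rank,
                    "psc": psc.astype(int),
                    "direction_choice": direction_choice,
                    "correct": correct,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if direction_task:
        out["correct"] = out["correct"].astype(float)
    return out


def cohort_accuracy(responses: pd.DataFrame) -> float:
    """Overall proportion of correct direction choices."""
    return float(responses["correct"].mean())
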