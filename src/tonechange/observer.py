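"""Closed-form Gaussian ideal observer.

The observer holds a conjugate Gaussian belief over the sequence mean,
parameterised as (mean, precision). With known observation precision
``lambda`` every update is exact:

    precision' = precision + lambda
    mean'      = (precision * mean + lambda * x) / precision'

Two notions of surprise are computed and kept distinct:

* predictive surprise: -log p(x) under the prior predictive
  Normal(mean, 1/precision + 1/lambda) — the improbability of a single
  input under current beliefs;
* Bayesian surprise: KL(posterior || prior) — the size of the belief
  update itself, which for the halfway mean shift is the quantity the
  change-salience rating is meant to track.

The observer knows the generative precision and the change point (both
fixed by the paradigm); it estimates only the means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import norm

from .errors import DomainError, StructuralError
from .paradigm import StimulusSequence

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ObserverBelief:
    """Gaussian belief over the sequence mean; precision 0 is the flat prior."""

    mean: float
    precision: float

    def __post_init__(self) -> None:
        if self.precision < 0:
            raise DomainError(f"belief precision must be >= 0, got {self.precision}")

    @property
    def variance(self) -> float:
        if self.precision == 0:
            return math.inf
        return 1.0 / self.precision


@dataclass(frozen=True)
class ChangeEstimate:
    """Observer's verdict on the halfway change of one trial."""

    delta_hat: float  # estimated mean change (second half - first half)
    standard_error: float
    p_up: float  # posterior probability the change was upward
    bayesian_surprise: float  # nats


def posterior_update(
    belief: ObserverBelief, observation: float, observation_precision: float
) -> ObserverBelief:
    """Conjugate update of a Gaussian mean-belief by one observation."""
    if not observation_precision > 0:
        raise DomainError(
            f"observation_precision must be > 0, got {observation_precision}"
        )
    new_prec = belief.precision + observation_precision
    new_mean = (
        belief.precision * belief.mean + observation_precision * observation
    ) / new_prec
    return ObserverBelief(mean=new_mean, precision=new_prec)


def predictive_surprise(
    belief: ObserverBelief, observation: float, observation_precision: float
) -> float:
    """-log density of ``observation`` under the prior predictive (nats).

    Under a flat prior the predictive is improper; by convention the
    surprise of the first observation is the minimum achievable value,
    -log Normal(x; x, 1/observation_precision) (a warning is issued).
    """
    if not observation_precision > 0:
        raise DomainError(
            f"observation_precision must be > 0, got {observation_precision}"
        )
    if belief.precision == 0:
        warnings.warn(
            "flat prior: predictive surprise returned as the minimum "
            "-log N(x; x, 1/observation_precision) by convention",
            stacklevel=2,
        )
        var_pred = 1.0 / observation_precision
        return 0.5 * (_LOG_2PI + math.log(var_pred))
    var_pred = 1.0 / belief.precision + 1.0 / observation_precision
    z = observation - belief.mean
    return 0.5 * (_LOG_2PI + math.log(var_pred) + z * z / var_pred)


def gaussian_kl(posterior: ObserverBelief, prior: ObserverBelief) -> float:
    """KL(posterior || prior) between univariate Gaussian beliefs (nats).

    With equal variances this reduces to ``lambda * Delta**2 / 2``.
    """
    if posterior.precision <= 0 or prior.precision <= 0:
        raise DomainError("gaussian_kl requires strictly positive precisions")
    v_post, v_prior = posterior.variance, prior.variance
    dm = posterior.mean - prior.mean
    return 0.5 * (v_post / v_prior + dm * dm / v_prior - 1.0 + math.log(v_prior / v_post))


def observer_frame(trial_set) -> "pd.DataFrame":
    """Ideal-observer verdicts for every trial of a trial set.

    Columns: trial_id, delta_hat, p_up, bayes_surprise_nats — the
    optional observer annotations of the response CSV.
    """
    import pandas as pd

    rows = []
    for t in trial_set.trials:
        est = estimate_change(t, t.condition.precision_value)
        rows.append((t.trial_id, est.delta_hat, est.p_up, est.bayesian_surprise))
    return pd.DataFrame(
        rows, columns=["trial_id", "delta_hat", "p_up", "bayes_surprise_nats"]
    )


def estimate_change(
    sequence: StimulusSequence, known_precision: float
) -> ChangeEstimate:
    """Ideal-observer inference on one trial's halfway mean shift.

    ``delta_hat`` is the difference of half means; its standard error is
    sqrt(2 / (k * lambda)) for k observations per half; ``p_up`` is the
    posterior probability of an upward change under a flat prior on the
    means; ``bayesian_surprise`` is KL from the belief held after the
    first half to the belief after additionally absorbing the second half.
    """
    if not known_precision > 0:
        raise DomainError(f"known_precision must be > 0, got {known_precision}")
    if sequence.n % 2:
        raise StructuralError(f"sequence length {sequence.n} is odd")
    k = sequence.half
    m1 = float(sequence.first_half.mean())
    m2 = float(sequence.second_half.mean())
    delta_hat = m2 - m1
    se = math.sqrt(2.0 / (k * known_precision))
    p_up = float(norm.cdf(delta_hat / se))

    prior = ObserverBelief(mean=m1, precision=k * known_precision)
    posterior = ObserverBelief(mean=(m1 + m2) / 2.0, precision=2 * k * known_precision)
    bs = gaussian_kl(posterior, prior)
    return ChangeEstimate(
        delta_hat=delta_hat, standard_error=se, p_up=p_up, bayesian_surprise=bs
    )
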