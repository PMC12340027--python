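"""Stimulus-side generation: conditions, Gaussian tone sequences, orders, audio.

A trial is an ordered sequence of pure-tone values drawn i.i.d. from a
Gaussian whose mean shifts by +/- Delta exactly halfway through the
sequence while its precision lambda (inverse variance) stays fixed. The
full design crosses 3 precision levels x 3 mean-change magnitudes x 2
directions = 18 conditions, with a fixed set of exemplar sequences per
condition shared by every subject; only the presentation order is
randomised per subject.

Randomness is organised as named sub-streams of one root seed: the
stream for exemplar ``e`` of a condition is keyed by the condition's
level indices, so regenerating with the same seed is bit-reproducible
and adding conditions or exemplars never perturbs existing ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .config import DIRECTIONS, LEVELS, ExperimentConfig
from .errors import ConfigurationError, DomainError, StructuralError

logger = logging.getLogger(__name__)

# domain tags keeping stimulus / subject-order / responder streams disjoint
_STIM_STREAM = 1
_ORDER_STREAM = 2
_RESPONDER_STREAM = 3


@dataclass(frozen=True)
class Condition:
    """One cell of the 3 x 3 x 2 factorial design."""

    precision_level: str
    precision_value: float
    mean_change_level: str
    mean_change_value: float
    direction: str  # "up" | "down"

    @property
    def sign(self) -> int:
        return 1 if self.direction == "up" else -1

    @property
    def key(self) -> str:
        return f"{self.precision_level}-{self.mean_change_level}-{self.direction}"


@dataclass(frozen=True)
class StimulusSequence:
    """One trial's ordered stimulus values plus its provenance."""

    condition: Condition
    exemplar_index: int  # 1-based
    values: np.ndarray  # octaves re base, or dB re reference
    pre_change_mean: float
    onsets: np.ndarray  # seconds
    trial_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def half(self) -> int:
        if self.n % 2:
            raise StructuralError(f"sequence length {self.n} is odd")
        return self.n // 2

    @property
    def first_half(self) -> np.ndarray:
        return self.values[: self.half]

    @property
    def second_half(self) -> np.ndarray:
        return self.values[self.half :]


@dataclass(frozen=True)
class TrialSet:
    """All trials of one experiment: 18 conditions x exemplars, fixed by seed."""

    config: ExperimentConfig
    trials: tuple[StimulusSequence, ...]
    generation_seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def by_id(self, trial_id: str) -> StimulusSequence:
        return self._index[trial_id]

    @property
    def _index(self) -> dict[str, StimulusSequence]:
        idx = getattr(self, "__idx", None)
        if idx is None:
            idx = {t.trial_id: t for t in self.trials}
            object.__setattr__(self, "__idx", idx)
        return idx


# ---------------------------------------------------------------------------
# condition grid


def build_condition_grid(config: ExperimentConfig) -> list[Condition]:
    """Enumerate the 18 conditions in deterministic order.

    Order is precision-major, then mean change, then direction (up before
    down), so condition indices are stable across runs and presets.
    """
    config.validate()
    grid = [
        Condition(
            precision_level=p,
            precision_value=config.precision(p),
            mean_change_level=m,
            mean_change_value=config.mean_change(m),
            direction=d,
        )
        for p in LEVELS
        for m in LEVELS
        for d in DIRECTIONS
    ]
    return grid


# ---------------------------------------------------------------------------
# sequence generation


def trial_duration(n_stimuli: int, stimulus_duration: float, isi: float) -> float:
    """``n * duration + (n - 1) * ISI`` — the last tone has no trailing gap."""
    if n_stimuli < 1:
        raise ConfigurationError("need at least one stimulus")
    if stimulus_duration <= 0 or isi < 0:
        raise ConfigurationError("durations must be non-negative")
    return n_stimuli * stimulus_duration + (n_stimuli - 1) * isi


def sequence_timing(config: ExperimentConfig) -> tuple[np.ndarray, float]:
    """Tone onsets and total trial duration.

    For the shipped presets this reproduces the published trial lengths
    (3.36 s and 2.36 s), which pin the inter-stimulus interval at 0.04 s.
    """
    n = config.n_stimuli
    total = trial_duration(n, config.stimulus_duration, config.inter_stimulus_interval)
    step = config.stimulus_duration + config.inter_stimulus_interval
    onsets = np.arange(n) * step
    return onsets, float(total)


def draw_sequence(
    condition: Condition,
    config: ExperimentConfig,
    pre_change_mean: float,
    rng: np.random.Generator,
) -> StimulusSequence:
    """Draw one trial: i.i.d. Normal(mu0, 1/lambda) then Normal(mu0 + s*Delta, 1/lambda).

    ``precision_value = inf`` is the noiseless limit (variance 0).
    """
    lam = condition.precision_value
    if not lam > 0:
        raise DomainError(f"precision must be positive, got {lam}")
    sd = 0.0 if math.isinf(lam) else math.sqrt(1.0 / lam)
    k = config.half
    mu1 = pre_change_mean
    mu2 = pre_change_mean + condition.sign * condition.mean_change_value
    values = np.concatenate(
        [mu1 + sd * rng.standard_normal(k), mu2 + sd * rng.standard_normal(k)]
    )
    onsets, _ = sequence_timing(config)
    return StimulusSequence(
        condition=condition,
        exemplar_index=0,
        values=values,
        pre_change_mean=mu1,
        onsets=onsets,
    )


def _trial_stream(
    seed: int, p_idx: int, m_idx: int, d_idx: int, exemplar: int
) -> np.random.Generator:
    ss = np.random.SeedSequence((int(seed), _STIM_STREAM, p_idx, m_idx, d_idx, exemplar))
    return np.random.default_rng(ss)


def generate_trial_set(config: ExperimentConfig, seed: int) -> TrialSet:
    """Generate the full, subject-independent trial set (18 x exemplars).

    The pre-change mean of each exemplar is roved uniformly within
    ``centre_value +/- rove_range`` (set ``rove_range=0`` for a fixed mean).
    """
    grid = build_condition_grid(config)
    trials: list[StimulusSequence] = []
    for cond in grid:
        p_idx = LEVELS.index(cond.precision_level)
        m_idx = LEVELS.index(cond.mean_change_level)
        d_idx = DIRECTIONS.index(cond.direction)
        for e in range(1, config.n_exemplars_per_condition + 1):
            rng = _trial_stream(seed, p_idx, m_idx, d_idx, e)
            mu0 = config.centre_value
            if config.rove_range > 0:
                mu0 += rng.uniform(-config.rove_range, config.rove_range)
            seq = draw_sequence(cond, config, mu0, rng)
            seq = StimulusSequence(
                condition=cond,
                exemplar_index=e,
                values=seq.values,
                pre_change_mean=mu0,
                onsets=seq.onsets,
                trial_id=f"{cond.key}-{e:02d}",
            )
            trials.append(seq)
    return TrialSet(config=config, trials=tuple(trials), generation_seed=int(seed))


def subject_order(trial_set: TrialSet, subject_seed: int) -> np.ndarray:
    """Uniform-random presentation order (permutation of trial indices)."""
    if len(trial_set) == 0:
        raise StructuralError("empty trial set")
    rng = np.random.default_rng(
        np.random.SeedSequence((int(subject_seed), _ORDER_STREAM))
    )
    return rng.permutation(len(trial_set))


# ---------------------------------------------------------------------------
# tabular I/O

TRIAL_COLUMNS = [
    "experiment_id",
    "trial_id",
    "precision_level",
    "precision_value",
    "mean_change_level",
    "mean_change_value",
    "direction",
    "exemplar_index",
    "stimulus_index",
    "value",
    "onset_s",
]


def trials_to_frame(trial_set: TrialSet) -> pd.DataFrame:
    """Long-format trial metadata: one row per stimulus."""
    rows = []
    exp = trial_set.config.experiment_id
    for t in trial_set.trials:
        c = t.condition
        for i, (v, on) in enumerate(zip(t.values, t.onsets), start=1):
            rows.append(
                (exp, t.trial_id, c.precision_level, c.precision_value,
                 c.mean_change_level, c.mean_change_value, c.direction,
                 t.exemplar_index, i, v, on)
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def trial_set_from_frame(frame: pd.DataFrame, config: ExperimentConfig) -> TrialSet:
    """Rebuild a :class:`TrialSet` from the long-format CSV table."""
    trials = []
    for trial_id, g in frame.groupby("trial_id", sort=False):
        g = g.sort_values("stimulus_index")
        r = g.iloc[0]
        cond = Condition(
            precision_level=r["precision_level"],
            precision_value=float(r["precision_value"]),
            mean_change_level=r["mean_change_level"],
            mean_change_value=float(r["mean_change_value"]),
            direction=r["direction"],
        )
        trials.append(
            StimulusSequence(
                condition=cond,
                exemplar_index=int(r["exemplar_index"]),
                values=g["value"].to_numpy(),
                pre_change_mean=float("nan"),
                onsets=g["onset_s"].to_numpy(),
                trial_id=str(trial_id),
            )
        )
    return TrialSet(config=config, trials=tuple(trials), generation_seed=-1)


# ---------------------------------------------------------------------------
# audio rendering

#: fraction of the reference amplitude tones may never reach
AMPLITUDE_CAP = 0.9
#: fixed tone amplitude for frequency experiments (re reference_level)
FREQUENCY_EXP_AMPLITUDE = 0.5


def render_audio(
    sequence: StimulusSequence,
    config: ExperimentConfig,
    sample_rate: int = 44100,
    ramp: float = 0.005,
) -> np.ndarray:
    """Render one trial as a mono waveform of pure tones.

    Frequency experiments map each value ``v`` (octaves) to a tone at
    ``base_frequency * 2**v`` with fixed amplitude; intensity experiments
    play the carrier at ``reference_level * 10**(v / 20)``, hard-capped
    (with a warning) strictly below 90% of the reference. Raised-cosine
    on/off ramps; silence during the inter-stimulus interval.
    """
    cfg = config
    if cfg.varied_parameter == "frequency":
        freqs = cfg.base_frequency * np.power(2.0, sequence.values)
        amps = np.full_like(freqs, FREQUENCY_EXP_AMPLITUDE * cfg.reference_level)
    else:
        freqs = np.full(sequence.n, cfg.base_frequency)
        amps = cfg.reference_level * np.power(10.0, sequence.values / 20.0)
        cap = AMPLITUDE_CAP * cfg.reference_level
        over = amps >= cap
        if over.any():
            logger.warning(
                "trial %s: %d stimulus amplitude(s) at/above %.0f%% of the "
                "reference; clipped to the cap",
                sequence.trial_id or "<anon>", int(over.sum()), 100 * AMPLITUDE_CAP,
            )
            amps = np.where(over, np.nextafter(cap, 0.0), amps)
    if sample_rate < 2 * float(freqs.max()):
        raise DomainError(
            f"sample_rate {sample_rate} below Nyquist for {freqs.max():.1f} Hz"
        )

    n_tone = round(cfg.stimulus_duration * sample_rate)
    n_gap = round(cfg.inter_stimulus_interval * sample_rate)
    n_ramp = min(round(ramp * sample_rate), n_tone // 2)
    t = np.arange(n_tone) / sample_rate
    envelope = np.ones(n_tone)
    if n_ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        envelope[:n_ramp] = r
        envelope[-n_ramp:] = r[::-1]

    segments = []
    gap = np.zeros(n_gap)
    for i, (f, a) in enumerate(zip(freqs, amps)):
        tone = a * envelope * np.sin(2 * np.pi * f * t)
        segments.append(tone)
        if i < sequence.n - 1:
            segments.append(gap)
    return np.concatenate(segments)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int = 44100) -> None:
    """Write a waveform in [-1, 1] as 16-bit PCM mono WAV."""
    clipped = np.clip(waveform, -1.0, 1.0)
    wavfile.write(str(path), sample_rate, (clipped * 32767).astype(np.int16))
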