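"""Synthetic 8-channel EEG with condition-dependent signal complexity.

The generator emulates the structure of an auditory-attention experiment:
13 subjects, each recorded once per attention condition (Rest, AOA1, AOA2)
for 60 s at 500 Hz on the 8 scalp sites T7, T8, P7, P8, Cz, Fz, P3, P4.

Each trial is the sum of a broadband ``1/f**alpha`` stochastic background,
narrowband delta/theta/alpha/beta oscillations and a small white
measurement-noise floor.  A per-condition *complexity* knob in [0, 1]
maps monotonically onto the spectral exponent (higher complexity ->
whiter spectrum -> higher sample entropy).  Like any spectral-slope
model, the induced entropy ordering holds at coarse-graining scales up
to roughly tau = 10 and crosses over at the largest scales, where whiter
signals lose entropy faster under averaging.

Channels share a common broadband source (mixing weight 0.3 by default) on
top of independent channel noise, so per-channel features correlate without
being identical.  Subjects carry a random gain (+/-20 %) and a complexity
jitter (+/-0.05) drawn from the seeded generator, which keeps leave-one-out
cross-validation non-trivial.

All randomness derives from one master seed through stable integer hashing
of (seed, subject, condition, trial_seed), so any subset of the dataset is
reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

#: Canonical electrode order used for every trial, feature vector and table.
CHANNELS: tuple = ("T7", "T8", "P7", "P8", "Cz", "Fz", "P3", "P4")

#: Attention conditions, in the fixed order Rest < AOA1 < AOA2.
CONDITIONS: tuple = ("Rest", "AOA1", "AOA2")

#: Band centre frequencies (Hz) for the oscillatory component.
_BAND_FREQS: Dict[str, float] = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0}

_DEFAULT_COMPLEXITY: Dict[str, float] = {"Rest": 0.36, "AOA1": 0.60, "AOA2": 0.47}
_DEFAULT_OSCILLATIONS: Dict[str, float] = {
    "delta": 0.6,
    "theta": 0.5,
    "alpha": 0.8,
    "beta": 0.3,
}


def normalize_condition(label: str) -> str:
    """Map a case/spacing variant like ``"aoa1"`` onto the canonical label."""
    key = label.strip().lower()
    for cond in CONDITIONS:
        if key == cond.lower():
            return cond
    raise ValueError(f"unknown condition label {label!r}; expected one of {CONDITIONS}")


@dataclass
class EEGTrial:
    """One labelled single-trial recording: ``samples`` is channels x time."""

    samples: np.ndarray
    fs: float
    subject_id: str
    condition: str
    channels: Sequence[str] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.channels != CHANNELS:
            raise ValueError(
                f"channels must be exactly {CHANNELS} in order, got {self.channels}"
            )
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"samples must be [{len(self.channels)} x time], got {self.samples.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.condition = normalize_condition(self.condition)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults reproduce the experiment geometry (13 subjects x 3 conditions =
    39 trials of 60 s at 500 Hz) with complexity ordered
    AOA1 > AOA2 > Rest so that sample-entropy-family features separate the
    conditions.
    """

    n_subjects: int = 13
    fs: float = 500.0
    duration: float = 60.0
    complexity_by_condition: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPLEXITY)
    )
    oscillation_spec: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OSCILLATIONS)
    )
    noise_floor: float = 0.05
    mixing_weight: float = 0.3
    subject_gain_jitter: float = 0.20
    complexity_jitter: float = 0.05
    trial_complexity_noise: float = 0.08
    channel_complexity_noise: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        missing = [c for c in CONDITIONS if c not in self.complexity_by_condition]
        if missing:
            raise ValueError(f"complexity_by_condition missing conditions: {missing}")
        for cond, value in self.complexity_by_condition.items():
            normalize_condition(cond)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"complexity for {cond} must be in [0, 1], got {value}")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def subject_ids(self) -> List[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


def _stable_hash(text: str) -> int:
    """CRC32 of a string: stable across runs and platforms, < 2**32."""
    return zlib.crc32(text.encode("utf-8"))


def _trial_rng(config: SimulationConfig, subject_id: str, condition: str, trial_seed: int):
    ss = np.random.SeedSequence(
        [int(config.seed), _stable_hash(subject_id), _stable_hash(condition), int(trial_seed)]
    )
    return np.random.default_rng(ss)


def _subject_rng(config: SimulationConfig, subject_id: str):
    ss = np.random.SeedSequence([int(config.seed), _stable_hash(subject_id), 0x5EED])
    return np.random.default_rng(ss)


def _powerlaw_noise(rng, n: int, fs: float, alpha: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f**alpha.

    Realised by shaping the spectrum of white noise; frequencies below
    0.5 Hz are clamped to avoid a divergent DC tail.  Output has unit
    sample standard deviation.
    """
    white = rng.standard_normal(n)
    if alpha == 0.0:
        return white / white.std(ddof=1)
    spectrum = rfft(white)
    freqs = rfftfreq(n, d=1.0 / fs)
    shaped = np.maximum(freqs, 0.5) ** (-alpha / 2.0)
    shaped[0] = 0.0  # remove DC
    x = irfft(spectrum * shaped, n=n)
    return x / x.std(ddof=1)


def _complexity_to_alpha(complexity: float) -> float:
    """Map the [0, 1] complexity knob to a 1/f exponent in [0, 2].

    complexity 1 -> white noise (maximal irregularity); complexity 0 ->
    brown-ish noise (smooth, predictable).  Sample entropy increases
    monotonically with complexity.
    """
    return 2.0 * (1.0 - complexity)


def generate_trial(
    subject_id: str,
    condition: str,
    config: SimulationConfig | None = None,
    trial_seed: int = 0,
) -> EEGTrial:
    """Simulate one 8-channel trial for (subject, condition).

    Deterministic given (config.seed, subject_id, condition, trial_seed).
    """
    config = config or SimulationConfig()
    config.validate()
    condition = normalize_condition(condition)

    n = config.n_samples
    fs = config.fs
    rng = _trial_rng(config, subject_id, condition, trial_seed)
    srng = _subject_rng(config, subject_id)

    gain = 1.0 + srng.uniform(-config.subject_gain_jitter, config.subject_gain_jitter)
    jitter = srng.uniform(-config.complexity_jitter, config.complexity_jitter)
    # per-trial brain-state drift, independent of condition, so the three
    # trials of one subject are not feature-space replicas of each other
    drift = config.trial_complexity_noise * rng.standard_normal()
    complexity = float(
        np.clip(config.complexity_by_condition[condition] + jitter + drift, 0.0, 1.0)
    )
    t = np.arange(n) / fs
    w = config.mixing_weight
    alpha = _complexity_to_alpha(complexity)
    common = _powerlaw_noise(rng, n, fs, alpha)

    samples = np.empty((len(CHANNELS), n))
    for ci in range(len(CHANNELS)):
        # each site sees its own small complexity offset, so the eight
        # features are correlated but not redundant copies of one another
        ch_complexity = float(
            np.clip(complexity + config.channel_complexity_noise * rng.standard_normal(), 0.0, 1.0)
        )
        own = _powerlaw_noise(rng, n, fs, _complexity_to_alpha(ch_complexity))
        broadband = np.sqrt(w) * common + np.sqrt(1.0 - w) * own
        osc = np.zeros(n)
        for band, amplitude in config.oscillation_spec.items():
            f0 = _BAND_FREQS[band] * (1.0 + rng.uniform(-0.05, 0.05))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            osc += amplitude * np.sin(2.0 * np.pi * f0 * t + phase)
        noise = config.noise_floor * rng.standard_normal(n)
        samples[ci] = 10.0 * gain * (broadband + osc + noise)

    return EEGTrial(samples=samples, fs=fs, subject_id=subject_id, condition=condition)


def generate_dataset(config: SimulationConfig | None = None) -> List[EEGTrial]:
    """Simulate the full dataset: one trial per (subject, condition).

    With defaults this is 13 subjects x 3 conditions = 39 trials, matching
    the sample count available to the attention classifier.
    """
    config = config or SimulationConfig()
    config.validate()
    trials = []
    for subject_id in config.subject_ids():
        for condition in CONDITIONS:
            trials.append(generate_trial(subject_id, condition, config))
    return trials
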