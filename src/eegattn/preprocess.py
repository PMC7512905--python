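"""Detrending and wavelet denoising of EEG channels.

Each channel is linearly detrended (least-squares polynomial fit subtracted)
and then denoised by a 9-level discrete wavelet transform with Daubechies
db4: the two finest detail bands D1 (125-250 Hz at fs = 500) and D2
(62.5-125 Hz) and the coarsest approximation A9 (0-0.49 Hz) are zeroed
before reconstruction, leaving an effective passband of roughly
0.5-62.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pywt

from eegattn.simulate import EEGTrial


@dataclass
class PreprocessConfig:
    detrend_degree: int = 1
    wavelet_name: str = "db4"
    levels: int = 9
    drop_bands: Tuple[str, ...] = ("D1", "D2", "A9")

    def validate(self) -> None:
        if self.detrend_degree < 0:
            raise ValueError("detrend_degree must be >= 0")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        valid = {f"D{k}" for k in range(1, self.levels + 1)} | {f"A{self.levels}"}
        unknown = set(self.drop_bands) - valid
        if unknown:
            raise ValueError(f"unknown subband names {sorted(unknown)}; valid: {sorted(valid)}")


def detrend(signal: np.ndarray, degree: int = 1) -> np.ndarray:
    """Subtract the least-squares polynomial fit of the given degree."""
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("detrend expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if x.size < degree + 1:
        raise ValueError(f"signal of length {x.size} too short for degree-{degree} fit")
    t = np.arange(x.size, dtype=np.float64)
    coeffs = np.polynomial.polynomial.polyfit(t, x, deg=degree)
    trend = np.polynomial.polynomial.polyval(t, coeffs)
    return x - trend


def _band_index(name: str, levels: int) -> int:
    # pywt.wavedec returns [A_levels, D_levels, D_{levels-1}, ..., D1]
    if name == f"A{levels}":
        return 0
    if name.startswith("D"):
        k = int(name[1:])
        if 1 <= k <= levels:
            return levels - k + 1
    raise ValueError(f"unknown subband {name!r} for {levels}-level decomposition")


def wavelet_denoise(signal: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """DWT-based denoise: zero the configured subbands and reconstruct.

    Uses symmetric signal extension at the boundaries; the output is
    truncated to the input length.
    """
    config = config or PreprocessConfig()
    config.validate()
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("wavelet_denoise expects a 1-D signal")
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(config.wavelet_name).dec_len)
    if max_level < config.levels:
        raise ValueError(
            f"signal of length {x.size} supports at most {max_level} levels; "
            f"{config.levels} requested"
        )
    coeffs = pywt.wavedec(x, config.wavelet_name, level=config.levels, mode="symmetric")
    for band in config.drop_bands:
        coeffs[_band_index(band, config.levels)][:] = 0.0
    y = pywt.waverec(coeffs, config.wavelet_name, mode="symmetric")
    return y[: x.size]


def preprocess_trial(trial: EEGTrial, config: PreprocessConfig | None = None) -> EEGTrial:
    """Detrend then wavelet-denoise every channel independently."""
    config = config or PreprocessConfig()
    config.validate()
    cleaned = np.empty_like(trial.samples)
    for ci in range(trial.samples.shape[0]):
        cleaned[ci] = wavelet_denoise(
            detrend(trial.samples[ci], config.detrend_degree), config
        )
    return EEGTrial(
        samples=cleaned,
        fs=trial.fs,
        subject_id=trial.subject_id,
        condition=trial.condition,
        channels=trial.channels,
    )
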