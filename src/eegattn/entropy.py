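"""Entropy estimators for EEG complexity features.

Implements the four regularity statistics used as classifier features —
approximate entropy (ApEn), sample entropy (SampEn), composite multiscale
entropy (CmpMSE) and fuzzy entropy (FuzzyEn) — plus normalized permutation
entropy, all with Chebyshev distance and a tolerance expressed as a
multiple of the signal's standard deviation.

Parameterization follows the study defaults: embedding dimension m = 2,
time delay t = 1, tolerance r = 0.15 x STD, scale factor tau = 30 for
CmpMSE, data length N = 30,000 (60 s at 500 Hz).

Conventions
-----------
* ApEn (Pincus): self-matches included; both dimensions are evaluated over
  the same N - m*t templates, so ApEn = Phi(m) - Phi(m+1) >= 0 always.
* SampEn (Richman-Moorman): pair counts B (dim m) and A (dim m+1) over
  i != j, self-matches excluded; SampEn = -ln(A/B).  Zero counts raise
  :class:`UndefinedEntropyError`.
* CmpMSE (composite coarse-graining): the mean of SampEn over all tau
  phase-shifted coarse-grained series; the absolute tolerance is anchored
  to the STD of the *original* scale-1 series, per multiscale convention.
* FuzzyEn: baseline-removed templates, exponential membership
  exp(-(d/r)**n) with fuzzy power n = 2, self-pairs excluded; the
  dimensionless d/r ratio makes FuzzyEn invariant under affine
  transformations of the signal when r is a multiple of STD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import factorial, log
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from eegattn import _kernels
from eegattn.simulate import CHANNELS, EEGTrial

MEASURES = ("apen", "sampen", "cmpmse", "fuzzyen", "permen")


class DegenerateInputError(ValueError):
    """Constant input: relative tolerance r x STD collapses to zero."""


class UndefinedEntropyError(ValueError):
    """SampEn is undefined because a pair count is zero."""

    def __init__(self, a: int, b: int):
        self.a = int(a)
        self.b = int(b)
        super().__init__(f"sample entropy undefined: A={a}, B={b} template pairs")


@dataclass(frozen=True)
class EntropyParams:
    """The (N, t, m, r, tau) parameter tuple shared by all measures.

    ``r`` is a multiple of the signal STD; pass ``r_abs`` to use an
    absolute tolerance instead (required for constant signals).
    ``fuzzy_power`` is the exponent of the exponential membership
    function used by FuzzyEn.
    """

    m: int = 2
    t: int = 1
    r: float = 0.15
    tau: int = 1
    fuzzy_power: float = 2.0
    r_abs: Optional[float] = None

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.t < 1:
            raise ValueError("time delay t must be >= 1")
        if self.r <= 0 and self.r_abs is None:
            raise ValueError("tolerance r must be positive")
        if self.tau < 1:
            raise ValueError("scale factor tau must be >= 1")
        if self.r_abs is not None and self.r_abs <= 0:
            raise ValueError("absolute tolerance r_abs must be positive")


def _as_vector(x, params: EntropyParams) -> np.ndarray:
    v = np.ascontiguousarray(x, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("entropy measures expect a 1-D signal")
    if not np.all(np.isfinite(v)):
        raise ValueError("signal contains non-finite values")
    if v.size < params.m * params.t + 1:
        raise ValueError(
            f"signal of length {v.size} too short for m={params.m}, t={params.t}"
        )
    return v


def _tolerance(x: np.ndarray, params: EntropyParams) -> float:
    if params.r_abs is not None:
        return float(params.r_abs)
    std = float(np.std(x, ddof=1))
    if std == 0.0:
        raise DegenerateInputError(
            "constant signal: r x STD is zero; supply an absolute tolerance r_abs"
        )
    return params.r * std


def apen(x, params: EntropyParams | None = None) -> float:
    """Approximate entropy: Phi(m) - Phi(m+1), self-matches included."""
    params = params or EntropyParams()
    params.validate()
    v = _as_vector(x, params)
    r = _tolerance(v, params)
    phi_m, phi_m1 = _kernels.apen_phis(v, params.m, params.t, r)
    return float(phi_m - phi_m1)


def sampen(x, params: EntropyParams | None = None) -> float:
    """Sample entropy: -ln(A/B) over self-excluded template pairs."""
    params = params or EntropyParams()
    params.validate()
    v = _as_vector(x, params)
    r = _tolerance(v, params)
    a, b = _kernels.sampen_counts(v, params.m, params.t, r)
    if a == 0 or b == 0:
        raise UndefinedEntropyError(a, b)
    return float(-np.log(a / b))


def composite_coarse_grain(x, tau: int) -> List[np.ndarray]:
    """All tau phase-shifted coarse-grainings of ``x`` at scale ``tau``.

    The k-th series (k = 1..tau) averages consecutive non-overlapping
    length-tau blocks starting at offset k-1; its length is
    floor((N - k + 1) / tau).
    """
    v = np.asarray(x, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("coarse-graining expects a 1-D signal")
    if tau < 1:
        raise ValueError("scale factor tau must be >= 1")
    if v.size < 2 * tau:
        raise ValueError(f"signal of length {v.size} too short for tau={tau}")
    if tau == 1:
        return [v.copy()]
    out = []
    for k in range(1, tau + 1):
        n_blocks = (v.size - k + 1) // tau
        out.append(v[k - 1 : k - 1 + n_blocks * tau].reshape(n_blocks, tau).mean(axis=1))
    return out


def cmpmse(x, params: EntropyParams | None = None) -> float:
    """Composite multiscale entropy: mean SampEn over the tau coarse series.

    The tolerance is fixed from the original series STD and reused at
    every coarse-grained series.  Component series with undefined SampEn
    (zero matches) are skipped with a warning; if all tau components are
    undefined an :class:`UndefinedEntropyError` is raised.
    """
    params = params or EntropyParams()
    params.validate()
    v = _as_vector(x, params)
    r = _tolerance(v, params)
    component_params = replace(params, r_abs=r, tau=1)
    values = []
    last_error: Optional[UndefinedEntropyError] = None
    for series in composite_coarse_grain(v, params.tau):
        try:
            values.append(sampen(series, component_params))
        except UndefinedEntropyError as err:
            last_error = err
            warnings.warn(
                f"undefined SampEn (A={err.a}, B={err.b}) in one coarse-grained "
                f"series at tau={params.tau}; skipping it",
                RuntimeWarning,
                stacklevel=2,
            )
    if not values:
        raise last_error if last_error is not None else UndefinedEntropyError(0, 0)
    return float(np.mean(values))


def fuzzyen(x, params: EntropyParams | None = None) -> float:
    """Fuzzy entropy: ln(phi_m) - ln(phi_{m+1}) with exponential membership."""
    params = params or EntropyParams()
    params.validate()
    v = _as_vector(x, params)
    r = _tolerance(v, params)
    n_templates = v.size - params.m * params.t
    phi_m = _kernels.fuzzy_phi(v, n_templates, params.m, params.t, r, params.fuzzy_power)
    phi_m1 = _kernels.fuzzy_phi(v, n_templates, params.m + 1, params.t, r, params.fuzzy_power)
    return float(np.log(phi_m) - np.log(phi_m1))


def perm_entropy(x, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy of the ordinal-pattern distribution.

    Shannon entropy of the empirical distribution of ordinal patterns of
    the given order, divided by ln(order!) so the result lies in [0, 1].
    Ties are broken by order of occurrence (stable sort).
    """
    if order < 2:
        raise ValueError("order must be >= 2")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    v = np.asarray(x, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("perm_entropy expects a 1-D signal")
    n_patterns = v.size - (order - 1) * delay
    if n_patterns < 1:
        raise ValueError(f"signal of length {v.size} too short for order={order}, delay={delay}")
    idx = np.arange(n_patterns)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(v[idx], axis=1, kind="stable")
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / log(factorial(order))


_MEASURE_FUNCS = {
    "apen": apen,
    "sampen": sampen,
    "cmpmse": cmpmse,
    "fuzzyen": fuzzyen,
}


@dataclass
class FeatureTable:
    """Trials x features matrix with per-trial labels.

    Feature columns are named ``<channel>_<measure>`` (with ``_tau<k>``
    appended for multiscale features), in canonical channel order.
    """

    values: np.ndarray
    feature_names: List[str]
    labels: List[str]
    subject_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.subject_ids) == n):
            raise ValueError("labels/subject_ids must match the number of rows")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "condition", self.labels)
        frame.insert(0, "subject", self.subject_ids)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        feature_cols = [c for c in frame.columns if c not in ("subject", "condition")]
        return cls(
            values=frame[feature_cols].to_numpy(dtype=np.float64),
            feature_names=list(feature_cols),
            labels=list(frame["condition"]),
            subject_ids=list(frame["subject"]),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def extract_features(
    trials: Sequence[EEGTrial],
    measure: str,
    params: EntropyParams | None = None,
    channels: Sequence[str] | None = None,
) -> FeatureTable:
    """Per-channel entropy features for a list of (preprocessed) trials.

    One column per requested channel; rows follow trial order.  A trial
    whose entropy is undefined on some channel yields NaN in that cell
    with a warning; downstream classification refuses non-finite rows.
    """
    params = params or EntropyParams()
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    channels = tuple(channels) if channels is not None else CHANNELS
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    if not trials:
        raise ValueError("no trials given")

    suffix = f"_tau{params.tau}" if measure == "cmpmse" else ""
    feature_names = [f"{ch}_{measure}{suffix}" for ch in channels]
    ch_index = {ch: CHANNELS.index(ch) for ch in channels}

    values = np.empty((len(trials), len(channels)))
    for ti, trial in enumerate(trials):
        for fi, ch in enumerate(channels):
            x = trial.samples[ch_index[ch]]
            try:
                if measure == "permen":
                    values[ti, fi] = perm_entropy(x)
                else:
                    values[ti, fi] = _MEASURE_FUNCS[measure](x, params)
            except UndefinedEntropyError as err:
                warnings.warn(
                    f"undefined {measure} for trial ({trial.subject_id}, "
                    f"{trial.condition}), channel {ch}: {err}; storing NaN",
                    RuntimeWarning,
                    stacklevel=2,
                )
                values[ti, fi] = np.nan
    return FeatureTable(
        values=values,
        feature_names=feature_names,
        labels=[t.condition for t in trials],
        subject_ids=[t.subject_id for t in trials],
    )
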