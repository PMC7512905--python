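"""Entropy estimators: oracle equivalence, identities and invariances."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegattn as ea
from eegattn.entropy import (
    DegenerateInputError,
    EntropyParams,
    UndefinedEntropyError,
    extract_features,
)
from oracles import apen_naive, cmpmse_naive, coarse_grain_naive, fuzzyen_naive, sampen_naive

RNG = np.random.default_rng(2024)


@pytest.mark.parametrize("m,t,r_coef", [(1, 1, 0.2), (2, 1, 0.15), (2, 2, 0.25), (3, 1, 0.2)])
@pytest.mark.parametrize("measure", ["apen", "sampen", "fuzzyen", "cmpmse"])
def test_fast_path_matches_naive_oracle(measure, m, t, r_coef):
    import zlib

    rng = np.random.default_rng(zlib.crc32(f"{measure}-{m}-{t}".encode()))
    for _ in range(5):
        n = int(rng.integers(120, 320))
        x = rng.standard_normal(n)
        r_abs = r_coef * np.std(x, ddof=1)
        tau = 3 if measure == "cmpmse" else 1
        params = EntropyParams(m=m, t=t, r=r_coef, tau=tau)
        try:
            fast = getattr(ea, measure)(x, params)
        except UndefinedEntropyError:
            # legitimately undefined (zero matches, e.g. m=3 on short
            # vectors); the oracle must agree that it is undefined
            with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if measure == "cmpmse":
                    assert not np.isfinite(cmpmse_naive(x, m, t, r_abs, tau))
                else:
                    assert not np.isfinite(sampen_naive(x, m, t, r_abs))
            continue
        naive = {
            "apen": lambda: apen_naive(x, m, t, r_abs),
            "sampen": lambda: sampen_naive(x, m, t, r_abs),
            "fuzzyen": lambda: fuzzyen_naive(x, m, t, r_abs),
            "cmpmse": lambda: cmpmse_naive(x, m, t, r_abs, tau),
        }[measure]()
        assert abs(fast - naive) < 1e-10


class TestApEn:
    def test_constant_vector_with_absolute_tolerance_is_zero(self):
        assert ea.apen(np.full(80, 3.0), EntropyParams(r_abs=0.1)) == pytest.approx(0.0)

    def test_scale_invariance_with_relative_tolerance(self):
        x = RNG.standard_normal(250)
        assert ea.apen(5.0 * x) == pytest.approx(ea.apen(x), abs=1e-12)

    def test_constant_input_without_absolute_tolerance_errors(self):
        with pytest.raises(DegenerateInputError):
            ea.apen(np.full(50, 1.0))

    @given(st.integers(0, 2**31 - 1), st.integers(30, 80))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_nonnegative_on_random_signals(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        assert ea.apen(x, EntropyParams(r=0.2)) >= 0.0


class TestSampEn:
    def test_periodic_alternation_is_zero(self):
        x = np.tile([1.0, 2.0], 50)
        assert ea.sampen(x, EntropyParams(r_abs=0.1)) == pytest.approx(0.0)

    def test_translation_invariance(self):
        x = RNG.standard_normal(300)
        assert ea.sampen(x + 100.0) == pytest.approx(ea.sampen(x), abs=1e-12)

    def test_zero_matches_raise_with_counts(self):
        x = RNG.standard_normal(60)
        with pytest.raises(UndefinedEntropyError) as err:
            ea.sampen(x, EntropyParams(r_abs=1e-12))
        assert err.value.b == 0

    def test_tolerance_monotonicity(self):
        x = RNG.standard_normal(400)
        values = [ea.sampen(x, EntropyParams(r=r)) for r in (0.10, 0.15, 0.20, 0.25)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestCoarseGraining:
    def test_worked_example(self):
        series = ea.composite_coarse_grain(np.arange(1.0, 7.0), 2)
        assert np.allclose(series[0], [1.5, 3.5, 5.5])
        assert np.allclose(series[1], [2.5, 4.5])

    def test_scale_one_is_identity(self):
        x = RNG.standard_normal(40)
        (only,) = ea.composite_coarse_grain(x, 1)
        assert np.array_equal(only, x)

    def test_lengths_and_values_match_naive(self):
        x = RNG.standard_normal(101)
        fast = ea.composite_coarse_grain(x, 3)
        naive = coarse_grain_naive(x, 3)
        assert [len(s) for s in fast] == [(101 - k + 1) // 3 for k in (1, 2, 3)]
        for f, n in zip(fast, naive):
            assert np.allclose(f, n, atol=1e-12)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            ea.composite_coarse_grain(np.arange(10.0), 0)


class TestCmpMSE:
    def test_scale_one_equals_sampen_exactly(self):
        x = RNG.standard_normal(500)
        assert ea.cmpmse(x, EntropyParams(tau=1)) == ea.sampen(x)

    def test_white_noise_below_pink_noise_at_large_scale(self):
        """The classic multiscale crossing: beyond scale ~5, 1/f noise is
        more entropic than white noise (tolerance anchored to the scale-1
        STD, so white noise's coarse series shrink relative to r)."""
        from numpy.fft import irfft, rfft, rfftfreq

        params = EntropyParams(tau=10)
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            white = rng.standard_normal(1500)
            f = rfftfreq(1500)
            shape = np.where(f > 0, np.maximum(f, 1 / 1500) ** -0.5, 0.0)
            pink = irfft(rfft(rng.standard_normal(1500)) * shape, n=1500)
            diffs.append(ea.cmpmse(pink, params) - ea.cmpmse(white, params))
        assert np.mean(diffs) > 0.0


class TestFuzzyEn:
    def test_constant_vector_with_absolute_tolerance_is_zero(self):
        assert ea.fuzzyen(np.full(60, 2.0), EntropyParams(r_abs=0.1)) == pytest.approx(0.0)

    def test_larger_tolerance_gives_smaller_entropy(self):
        x = RNG.standard_normal(300)
        r = 0.15 * np.std(x, ddof=1)
        assert ea.fuzzyen(x, EntropyParams(r_abs=2 * r)) < ea.fuzzyen(x, EntropyParams(r_abs=r))

    def test_affine_invariance(self):
        x = RNG.standard_normal(250)
        assert ea.fuzzyen(3.0 * x - 2.0) == pytest.approx(ea.fuzzyen(x), abs=1e-10)


class TestPermEntropy:
    def test_monotone_signal_has_zero_entropy(self):
        assert ea.perm_entropy(np.arange(200.0)) == pytest.approx(0.0)

    def test_uniform_noise_approaches_one(self):
        x = np.random.default_rng(3).uniform(size=10_000)
        assert ea.perm_entropy(x, order=3) == pytest.approx(1.0, abs=0.01)

    def test_reversal_symmetry(self):
        x = np.random.default_rng(4).standard_normal(2000)
        assert ea.perm_entropy(-x[::-1]) == pytest.approx(ea.perm_entropy(x), abs=1e-12)

    def test_order_below_two_rejected(self):
        with pytest.raises(ValueError):
            ea.perm_entropy(np.arange(10.0), order=1)


class TestExtractFeatures:
    def test_whole_head_and_single_channel_shapes(self, tiny_trials):
        table = extract_features(tiny_trials, "sampen")
        assert table.values.shape == (6, 8)
        assert table.feature_names[0] == "T7_sampen"
        single = extract_features(tiny_trials, "sampen", channels=["Cz"])
        assert single.values.shape == (6, 1)
        assert np.allclose(single.values[:, 0], table.values[:, list(ea.CHANNELS).index("Cz")])

    def test_duplicated_trials_give_identical_rows(self, tiny_trials):
        table = extract_features([tiny_trials[0], tiny_trials[0]], "sampen")
        assert np.array_equal(table.values[0], table.values[1])

    def test_undefined_entropy_flagged_as_nan(self, tiny_trials):
        with pytest.warns(RuntimeWarning, match="undefined"):
            table = extract_features(
                tiny_trials[:1], "sampen", EntropyParams(r_abs=1e-15), channels=["T7"]
            )
        assert np.isnan(table.values[0, 0])

    def test_unknown_measure_and_channel_rejected(self, tiny_trials):
        with pytest.raises(ValueError):
            extract_features(tiny_trials, "spectral")
        with pytest.raises(ValueError):
            extract_features(tiny_trials, "sampen", channels=["Oz"])

    def test_roundtrip_through_delimited_text(self, tiny_trials, tmp_path):
        table = extract_features(tiny_trials, "sampen")
        path = tmp_path / "features.tsv"
        table.to_csv(path)
        back = type(table).read_csv(path)
        assert back.feature_names == table.feature_names
        assert back.labels == table.labels
        assert np.allclose(back.values, table.values)


def test_group_mean_ordering_on_synthetic_data(effect_runs, cmpmse_table):
    """AOA1 > AOA2 > Rest group means for SampEn and CmpMSE on >= 7/8
    channels (CmpMSE at a moderate scale; the spectral-slope generator's
    ordering crosses over at the largest scales)."""
    from conftest import group_means

    for table in (effect_runs[0]["table"], cmpmse_table):
        means = group_means(table)
        ordered = (means["AOA1"] > means["AOA2"]) & (means["AOA2"] > means["Rest"])
        assert ordered.sum() >= 7
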