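"""Fuzzy entropy, Welch band powers and spectral power ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preictal import (
    BandSet,
    FuzzyEnParams,
    WelchParams,
    fuzzy_entropy,
    rpsd,
    spr,
    temporal_feature_block,
    welch_psd,
)
from preictal.features_temporal import SPR_PAIRS, temporal_feature_names
from preictal.preprocess import ConfigError


def fuzzyen_literal(u, m=2, r_factor=0.2):
    """Literal double-loop transcription of the fuzzy-entropy definition.

    Independent oracle: no vectorization, no shared code with the
    implementation. Templates are baseline-removed windows; similarity is
    exp(-ln2 (d/r)^2) with Chebyshev d; self-matches excluded.
    """
    u = list(map(float, u))
    n = len(u)
    r = r_factor * float(np.std(u))

    def phi(d):
        nv = n - d + 1
        templates = []
        for i in range(nv):
            window = u[i : i + d]
            u0 = sum(window) / d
            templates.append([v - u0 for v in window])
        total = 0.0
        for i in range(nv):
            ci = 0.0
            for j in range(nv):
                if j == i:
                    continue
                dij = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                ci += math.exp(-math.log(2.0) * (dij / r) ** 2)
            total += ci / (nv - 1)
        return total / nv

    return math.log(phi(m)) - math.log(phi(m + 1))


class TestFuzzyEntropy:
    def test_matches_literal_oracle_on_fixed_sequence(self):
        x = np.array([1, 3, 2, 5, 4, 6, 2, 7, 1, 8, 3, 9], dtype=float)
        assert fuzzy_entropy(x) == pytest.approx(fuzzyen_literal(x), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_literal_oracle_on_random_sequences(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(int(r.integers(10, 41)))
        assert fuzzy_entropy(x) == pytest.approx(fuzzyen_literal(x), abs=1e-10)

    def test_zero_variance_returns_zero(self):
        assert fuzzy_entropy(np.full(100, 3.7)) == 0.0

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="m\\+2"):
            fuzzy_entropy(np.array([1.0, 2.0, 3.0]))

    @given(
        a=st.floats(min_value=0.1, max_value=50).filter(lambda v: v != 0),
        b=st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_and_shift_invariance(self, a, b):
        # r scales with the standard deviation and templates are
        # baseline-removed, so affine maps leave the value unchanged
        x = np.random.default_rng(99).standard_normal(60)
        assert fuzzy_entropy(a * x + b) == pytest.approx(
            fuzzy_entropy(x), rel=1e-9, abs=1e-9
        )

    def test_nonnegative_on_random_inputs(self):
        for seed in range(30):
            x = np.random.default_rng(seed).standard_normal(50)
            assert fuzzy_entropy(x) >= 0.0

    def test_noise_more_complex_than_sinusoid(self):
        n, fs = 640, 128.0
        t = np.arange(n) / fs
        sine = np.sin(2 * np.pi * 10 * t)
        for seed in range(10):
            noise = np.random.default_rng(seed).standard_normal(n)
            assert fuzzy_entropy(noise) > fuzzy_entropy(sine)


class TestWelch:
    def test_peak_at_tone_frequency(self):
        fs = 256.0
        t = np.arange(int(5 * fs)) / fs
        f, p = welch_psd(np.sin(2 * np.pi * 10 * t), fs)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=f[1] - f[0])

    def test_zero_signal_zero_psd(self):
        _, p = welch_psd(np.zeros(1280), 256.0)
        np.testing.assert_array_equal(p, 0.0)

    def test_white_noise_estimates_agree_across_realizations(self):
        # Monte-Carlo oracle: two disjoint sets of 100 realizations give
        # mean PSDs that agree within averaged-periodogram variance
        fs, n = 256.0, 1280
        rng = np.random.default_rng(0)

        def mean_psd():
            acc = None
            for _ in range(100):
                _, p = welch_psd(rng.standard_normal(n), fs)
                acc = p if acc is None else acc + p
            return acc / 100

        a, b = mean_psd(), mean_psd()
        core = slice(2, -2)  # edge bins carry window leakage
        assert np.max(np.abs(a[core] - b[core]) / b[core]) < 0.2

    def test_segment_longer_than_epoch_rejected(self):
        with pytest.raises(ConfigError):
            welch_psd(np.zeros(100), 256.0, WelchParams(segment_seconds=1.0))

    def test_psd_integrates_to_variance(self, rng):
        # Parseval check: integrated density ~ signal variance for
        # zero-mean input, within window-loss tolerance
        x = rng.standard_normal(2560)
        x -= x.mean()
        f, p = welch_psd(x, 256.0)
        total = np.trapezoid(p, f)
        assert total == pytest.approx(x.var(), rel=0.15)


class TestBandPowers:
    def test_alpha_dominates_for_alpha_tone(self):
        fs = 256.0
        t = np.arange(int(5 * fs)) / fs
        f, p = welch_psd(np.sin(2 * np.pi * 10 * t), fs)
        bp = rpsd(f, p)
        names = BandSet().names
        assert names[int(np.argmax(bp))] == "alpha"

    def test_five_bands_ten_ratios(self):
        bp = rpsd(*welch_psd(np.random.default_rng(0).standard_normal(1280),
                             256.0))
        assert bp.shape == (5,)
        assert spr(bp).shape == (10,)

    def test_amplitude_doubling_shifts_rpsd_by_log4(self, rng):
        fs = 256.0
        x = rng.standard_normal(1280)
        f, p1 = welch_psd(x, fs)
        _, p2 = welch_psd(2 * x, fs)
        np.testing.assert_allclose(
            rpsd(f, p2) - rpsd(f, p1), np.log(4.0), atol=1e-9
        )

    def test_unresolvable_band_is_named(self):
        # 0.125-s segments give 8 Hz resolution: nothing lands in delta
        with pytest.raises(ValueError, match="delta"):
            rpsd(*welch_psd(np.ones(64), 64.0,
                            WelchParams(segment_seconds=0.125)))

    def test_spr_zero_for_equal_bands_and_fixed_naming(self):
        np.testing.assert_array_equal(spr(np.full(5, 2.5)), 0.0)
        assert [p[0] for p in SPR_PAIRS] == [
            "TD", "AD", "BD", "GD", "AT", "BT", "GT", "BA", "GA", "GB",
        ]
        # higher band minus lower band, e.g. AT = alpha - theta
        v = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        out = dict(zip([p[0] for p in SPR_PAIRS], spr(v)))
        assert out["TD"] == 1.0 and out["AT"] == 2.0 and out["GB"] == 8.0
        assert out["GD"] == 15.0

    def test_spr_antisymmetry(self, rng):
        v = rng.standard_normal(5)
        out = dict(zip([p[0] for p in SPR_PAIRS], spr(v)))
        # reversing a pair negates the difference
        assert out["AT"] == pytest.approx(-(v[1] - v[2]))


class TestTemporalBlock:
    @pytest.mark.parametrize("n_ch,expected", [(16, 256), (23, 368)])
    def test_sixteen_features_per_channel(self, n_ch, expected):
        assert len(temporal_feature_names(n_ch)) == expected

    def test_block_values_and_stable_order(self, rng):
        data = rng.standard_normal((4, 320))
        v1, n1 = temporal_feature_block(data, 64.0,
                                        bands=BandSet.default(31.0))
        v2, n2 = temporal_feature_block(data, 64.0,
                                        bands=BandSet.default(31.0))
        assert n1 == n2
        assert len(n1) == 64
        np.testing.assert_array_equal(v1, v2)
        assert n1[0] == "ch0_fuzzyen" and n1[1] == "ch0_rpsd_delta"
        assert n1[6] == "ch0_spr_TD"
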