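"""Feature pipeline: preprocessing, the five subsets, standardization."""

import numpy as np
import pytest

from gliadbn import (EEGTrial, FeatureSchema, SimConfig, apply_standardization,
                     band_psd, extract, hhs_features, power_differences,
                     preprocess, simulate_subject, standardize_subject,
                     time_stats)
from gliadbn.features import (DIFF_BANDS, PSD_BANDS, approximate_entropy, emd,
                              zero_crossing_rate)
from gliadbn.synthetic import DEAP_CHANNELS


def _trial(data, fs=128.0, label=(0, 0)):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = DEAP_CHANNELS[: data.shape[0]]
    return EEGTrial(data=data, fs=fs, channels=names, label=label)


def _tone(freq, fs=128.0, seconds=8.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def test_downsample_512_to_128_quarters_samples(self):
        trial = _trial(_tone(10, fs=512.0), fs=512.0)
        out = preprocess(trial, 128.0)
        assert out.fs == 128.0
        assert out.n_samples == trial.n_samples // 4
        assert out.channels == trial.channels and out.label == trial.label

    def test_stopband_and_passband(self):
        low = preprocess(_trial(_tone(1.0)), 128.0)
        assert np.sqrt(np.mean(low.data**2)) < 0.05  # 1 Hz attenuated
        mid = preprocess(_trial(_tone(10.0)), 128.0)
        assert np.sqrt(np.mean(mid.data**2)) >= 0.9 / np.sqrt(2)  # 10 Hz kept

    def test_errors(self):
        with pytest.raises(ValueError):
            preprocess(_trial(_tone(10, fs=64.0), fs=64.0), 128.0)
        with pytest.raises(ValueError):
            preprocess(_trial(np.zeros(10)), 128.0)  # shorter than warm-up


class TestTimeStats:
    def test_mean_variance_direct_formulas(self):
        ramp = np.arange(1.0, 51.0)
        stats = time_stats(_trial(ramp))
        assert stats[0] == pytest.approx(ramp.mean())
        assert stats[1] == pytest.approx(ramp.var())  # population convention
        assert time_stats(_trial([1.0, 2.0, 3.0] * 10))[0] == pytest.approx(2.0)

    def test_alternating_signal_unit_zero_crossing_rate(self):
        x = np.tile([1.0, -1.0], 32)
        assert zero_crossing_rate(x) == pytest.approx(1.0)

    def test_constant_signal_zero_apen(self):
        assert approximate_entropy(np.full(100, 3.7)) == 0.0

    def test_apen_orders_regular_below_random(self):
        t = np.arange(512)
        periodic = np.sin(2 * np.pi * t / 16)
        noise = np.random.default_rng(0).standard_normal(512)
        assert approximate_entropy(periodic) < approximate_entropy(noise)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.ones(3), m=2)


class TestBandPSD:
    def test_alpha_tone_maximal_in_alpha(self):
        vals = band_psd(_trial(_tone(10.0))).reshape(1, 5)[0]
        assert np.argmax(vals) == PSD_BANDS.index("alpha")

    def test_zero_signal_all_zero_and_quadratic_scaling(self):
        assert np.all(band_psd(_trial(np.zeros(1024))) == 0)
        v1 = band_psd(_trial(_tone(10.0)))
        v2 = band_psd(_trial(_tone(10.0, amp=2.0)))
        assert np.allclose(v2, 4 * v1)

    def test_band_beyond_nyquist_errors(self):
        with pytest.raises(ValueError):
            band_psd(_trial(_tone(10.0, fs=80.0), fs=80.0))


class TestPowerDifferences(object):
    def test_symmetry_antisymmetry_and_count(self, schema):
        rng = np.random.default_rng(4)
        psd = np.abs(rng.standard_normal(160))
        grid = psd.reshape(32, 5)
        idx = {c: i for i, c in enumerate(schema.channels)}
        # make left/right identical -> all zeros
        sym = grid.copy()
        for r, l in schema.pair_list:
            sym[idx[l]] = sym[idx[r]]
        assert np.allclose(power_differences(sym.ravel(), schema), 0.0)
        # swapping hemispheres negates
        swp = grid.copy()
        for r, l in schema.pair_list:
            swp[idx[l]], swp[idx[r]] = grid[idx[r]].copy(), grid[idx[l]].copy()
        d1 = power_differences(grid.ravel(), schema)
        d2 = power_differences(swp.ravel(), schema)
        assert d1.shape == (56,)
        assert np.allclose(d2, -d1)

    def test_wrong_width_errors(self, schema):
        with pytest.raises(ValueError):
            power_differences(np.zeros(100), schema)


class TestHHS:
    def test_pure_tone_band_amplitude_and_frequency(self):
        vals = hhs_features(_trial(_tone(6.0)))  # single channel: 2 x 5 values
        amp2, ifreq = vals[:5], vals[5:]
        j = 1  # theta slot
        assert amp2[j] == pytest.approx(1.0, rel=0.05)
        assert ifreq[j] == pytest.approx(6.0, rel=0.05)

    def test_zero_signal_all_zero_and_count(self):
        vals = hhs_features(_trial(np.zeros((32, 1024))))
        assert vals.shape == (320,)  # 2 features x 5 bands x 32 channels
        assert np.all(vals == 0)

    def test_tone_energy_concentrated_in_band(self):
        vals = hhs_features(_trial(_tone(10.0)))
        amp2 = vals[:5]
        assert amp2[2] >= 0.8 * amp2.sum()  # alpha slot holds >= 80% of mass

    def test_emd_recovers_two_tone_mixture(self):
        # independent check: IMFs of a fast+slow mixture sum back to the
        # signal and the first IMF carries the fast component
        fs, t = 128.0, np.arange(1024) / 128.0
        fast = np.sin(2 * np.pi * 20 * t)
        slow = 2 * np.sin(2 * np.pi * 3 * t)
        imfs = emd(fast + slow)
        assert len(imfs) >= 2
        recon = np.sum(imfs, axis=0)
        resid = fast + slow - recon
        interior = slice(64, -64)
        assert np.corrcoef(imfs[0][interior], fast[interior])[0, 1] > 0.95

    def test_non_finite_input_names_channel(self):
        bad = np.zeros((1, 1024))
        bad[0, 5] = np.nan
        with pytest.raises(ValueError, match="Fp1"):
            hhs_features(_trial(bad))


class TestExtract:
    def test_full_vector_layout_and_determinism(self, schema):
        cfg = SimConfig(n_subjects=1, n_trials_per_subject=1, duration=4.0,
                        seed=9)
        trial = preprocess(simulate_subject(cfg, 0)[0])
        fv = extract(trial, schema)
        assert fv.values.shape == (664,)
        sizes = [len(schema.subset_index[k]) for k in
                 ("F1", "F2", "F3", "F4", "F5")]
        assert sizes == [128, 160, 56, 160, 160]
        fv2 = extract(trial, schema)
        assert np.array_equal(fv.values, fv2.values)

    def test_schema_closure(self, schema):
        covered = sorted(i for r in schema.subset_index.values() for i in r)
        assert covered == list(range(664))
        assert len(schema.pair_list) == 14
        assert len(schema.names) == len(set(schema.names)) == 664

    def test_channel_mismatch_errors(self, schema):
        trial = _trial(np.zeros((2, 1024)))
        with pytest.raises(ValueError):
            extract(trial, schema)


class TestScaleCovariance:
    def test_scaling_acts_as_expected_per_domain(self):
        cfg = SimConfig(n_subjects=1, n_trials_per_subject=1, duration=4.0,
                        seed=2)
        trial = preprocess(simulate_subject(cfg, 0)[0])
        k = 3.0
        scaled = EEGTrial(k * trial.data, trial.fs, trial.channels, trial.label)
        s1, s2 = time_stats(trial), time_stats(scaled)
        assert np.allclose(s2[0::4], k * s1[0::4])        # means scale by k
        assert np.allclose(s2[1::4], k**2 * s1[1::4])     # variances by k^2
        assert np.allclose(s2[2::4], s1[2::4])            # zcr unchanged
        assert np.allclose(band_psd(scaled), k**2 * band_psd(trial))


class TestStandardize:
    def test_zscore_columns_and_degenerate_rule(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        X[:, 3] = 2.5  # constant column
        Z, mu, sd = standardize_subject(X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-10)
        assert np.allclose(Z.std(axis=0)[[0, 1, 2, 4]], 1.0)
        assert np.all(Z[:, 3] == 0) and sd[3] == 0

    def test_stored_statistics_apply_to_heldout(self):
        train = np.array([[1.0, 10.0], [2.0, 10.0], [3.0, 10.0]])
        _, mu, sd = standardize_subject(train)
        held = np.array([[4.0, 10.0]])
        out = apply_standardization(held, mu, sd)
        # hand computation: mean 2, population sd sqrt(2/3); constant col -> 0
        assert out[0, 0] == pytest.approx((4 - 2) / np.sqrt(2 / 3))
        assert out[0, 1] == 0.0

    def test_single_instance_errors(self):
        with pytest.raises(ValueError):
            standardize_subject(np.ones((1, 4)))
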