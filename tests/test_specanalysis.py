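"""Frequency-domain statistics: spectra, local-baseline z-scores, harmonic
selection and summation, SNR, individual-level significance."""

import numpy as np
import pytest
from scipy import stats

from fpas.preprocess import Epoch
from fpas.specanalysis import (
    ADJACENT_ONLY,
    AmplitudeSpectrum,
    BaselineConfig,
    amplitude_spectrum,
    average_epochs,
    baseline_subtract,
    baseline_subtracted_at,
    critical_z,
    individual_significance,
    local_baseline,
    null_exceedance,
    pool_channels,
    significant_harmonics,
    snr_spectrum,
    sum_harmonics,
    zscore_at,
    zscore_spectrum,
)

RES = 1.0 / 60  # 60-s epochs


def flat_spectrum(value=1.0, n_bins=200, n_ch=1):
    return AmplitudeSpectrum(
        freqs=np.arange(n_bins) * RES,
        amplitude=np.full((n_ch, n_bins), float(value)),
        ch_names=[f"c{i}" for i in range(n_ch)],
    )


class TestAveraging:
    def test_single_epoch_identity(self):
        ep = Epoch(np.random.default_rng(0).standard_normal((2, 100)), 256.0, ["a", "b"])
        assert np.array_equal(average_epochs([ep]).data, ep.data)

    def test_epoch_plus_negation_cancels(self):
        ep = Epoch(np.random.default_rng(1).standard_normal((2, 100)), 256.0, ["a", "b"])
        neg = ep.replace(data=-ep.data)
        assert np.allclose(average_epochs([ep, neg]).data, 0.0)

    def test_phase_locked_signal_kept_noise_reduced(self):
        rng = np.random.default_rng(2)
        rate, n = 256.0, 15360
        t = np.arange(n) / rate
        sig = 1.0 * np.sin(2 * np.pi * 4.0 * t)
        N = 16
        epochs = [
            Epoch((sig + rng.standard_normal(n))[None, :], rate, ["a"]) for _ in range(N)
        ]
        avg = average_epochs(epochs)
        resid = avg.data[0] - sig
        # noise power shrinks by ~1/N
        assert np.mean(resid**2) == pytest.approx(1.0 / N, rel=0.25)
        spec = amplitude_spectrum(avg)
        assert spec.amplitude[0, spec.bin_of(4.0)] == pytest.approx(1.0, abs=0.02)

    def test_shape_mismatch_rejected(self):
        a = Epoch(np.zeros((2, 10)), 256.0, ["a", "b"])
        b = Epoch(np.zeros((2, 11)), 256.0, ["a", "b"])
        with pytest.raises(ValueError):
            average_epochs([a, b])


class TestAmplitudeSpectrum:
    def test_resolution_is_inverse_duration(self):
        ep = Epoch(np.zeros((1, 15360)), 256.0, ["a"])
        spec = amplitude_spectrum(ep)
        assert spec.resolution == pytest.approx(1.0 / 60, abs=1e-12)

    def test_on_bin_sine_amplitude_exact(self):
        rate, n = 256.0, 15360
        t = np.arange(n) / rate
        ep = Epoch(2.0 * np.sin(2 * np.pi * (4.0 / 3) * t)[None, :], rate, ["a"])
        spec = amplitude_spectrum(ep)
        b = spec.bin_of(4.0 / 3)
        assert spec.amplitude[0, b] == pytest.approx(2.0, rel=1e-9)
        others = np.delete(spec.amplitude[0], b)
        assert np.abs(others).max() < 1e-9

    def test_zero_signal_zero_spectrum(self):
        spec = amplitude_spectrum(Epoch(np.zeros((3, 256)), 256.0, list("abc")))
        assert np.all(spec.amplitude == 0.0)


class TestLocalBaseline:
    def test_flat_spectrum(self):
        mean, sd = local_baseline(flat_spectrum(3.0), 100, ADJACENT_ONLY)
        assert mean[0] == pytest.approx(3.0) and sd[0] == pytest.approx(0.0)

    def test_spike_at_tested_bin_ignored(self):
        spec = flat_spectrum(1.0)
        spec.amplitude[0, 100] = 50.0
        mean, _ = local_baseline(spec, 100, ADJACENT_ONLY)
        assert mean[0] == pytest.approx(1.0)

    def test_hand_computed_toy_minmax(self):
        # 27 bins, tested bin 13: candidates are 12 per side beyond the
        # adjacent bins; each side drops its min and max
        rng = np.random.default_rng(3)
        vals = rng.uniform(1.0, 2.0, 27)
        spec = AmplitudeSpectrum(np.arange(27) * RES, vals[None, :], ["a"])
        left = sorted(vals[0:12])[1:-1]
        right = sorted(vals[15:27])[1:-1]
        pool = left + right
        exp_mean = sum(pool) / 20
        exp_sd = np.sqrt(sum((v - exp_mean) ** 2 for v in pool) / 19)
        mean, sd = local_baseline(spec, 13, BaselineConfig())
        assert mean[0] == pytest.approx(exp_mean, rel=1e-12)
        assert sd[0] == pytest.approx(exp_sd, rel=1e-12)
        assert len(pool) == 20

    def test_hand_computed_toy_adjacent_only(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1.0, 2.0, 23)
        spec = AmplitudeSpectrum(np.arange(23) * RES, vals[None, :], ["a"])
        pool = list(vals[0:10]) + list(vals[13:23])
        mean, sd = local_baseline(spec, 11, ADJACENT_ONLY)
        assert mean[0] == pytest.approx(np.mean(pool), rel=1e-12)
        assert sd[0] == pytest.approx(np.std(pool, ddof=1), rel=1e-12)

    def test_edge_bin_rejected(self):
        with pytest.raises(ValueError):
            local_baseline(flat_spectrum(), 5, ADJACENT_ONLY)


class TestZScore:
    def test_amplitude_at_baseline_mean_gives_zero(self):
        spec = flat_spectrum(2.0)
        assert zscore_at(spec, 100 * RES, ADJACENT_ONLY)[0] == 0.0

    def test_injected_three_sd_bin(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 1.5, 201)
        spec = AmplitudeSpectrum(np.arange(201) * RES, vals[None, :], ["a"])
        mean, sd = local_baseline(spec, 100, ADJACENT_ONLY)
        spec.amplitude[0, 100] = mean[0] + 3 * sd[0]
        assert zscore_at(spec, 100 * RES, ADJACENT_ONLY)[0] == pytest.approx(3.0, rel=1e-9)

    def test_null_calibration_matches_t_oracle(self):
        """With an estimated 20-bin baseline, z = sqrt(21/20) * t19 under a
        Gaussian null: the empirical exceedance follows the t prediction,
        not the nominal Gaussian tail."""
        rng = np.random.default_rng(6)
        n_ch, n_bins = 64, 2000
        amp = 10.0 + rng.standard_normal((n_ch, n_bins))
        spec = AmplitudeSpectrum(np.arange(n_bins) * RES, amp, [f"c{i}" for i in range(n_ch)])
        z = zscore_spectrum(spec, ADJACENT_ONLY)
        sel = z[:, ADJACENT_ONLY.margin : n_bins - ADJACENT_ONLY.margin : 23].ravel()
        expect = null_exceedance(2.32)  # ~0.0177
        p_hat = np.mean(sel > 2.32)
        se = np.sqrt(expect * (1 - expect) / sel.size)
        assert abs(p_hat - expect) < 4 * se
        expect164 = null_exceedance(1.64)
        se164 = np.sqrt(expect164 * (1 - expect164) / sel.size)
        assert abs(np.mean(sel > 1.64) - expect164) < 4 * se164

    def test_critical_values(self):
        assert critical_z(0.01) == pytest.approx(2.3263, abs=1e-3)
        assert critical_z(0.05) == pytest.approx(1.6449, abs=1e-3)


def spectrum_with_peaks(peaks, n_bins=800, floor=1.0, jitter=0.01, seed=0):
    """Baseline floor with small known jitter and designed peak amplitudes;
    peaks maps bin -> amplitude."""
    rng = np.random.default_rng(seed)
    vals = floor + jitter * rng.standard_normal(n_bins)
    for b, a in peaks.items():
        vals[b] = a
    return AmplitudeSpectrum(np.arange(n_bins) * RES, vals[None, :], ["pooled"])


class TestSignificantHarmonics:
    def test_walk_skips_base_multiples_and_stops(self):
        # target 4/3 Hz, base 4 Hz: harmonics k=3, 6 are base multiples;
        # signal injected at k=1,2,4,5; k=7 is noise-level -> stop there,
        # even though k=8 is made large (never reached)
        f = 4.0 / 3
        peaks = {int(round(k * f / RES)): 5.0 for k in (1, 2, 4, 5)}
        peaks[int(round(8 * f / RES))] = 5.0
        spec = spectrum_with_peaks(peaks)
        resp = significant_harmonics(spec, f, z_thresh=2.32, exclude=[4.0])
        assert resp.harmonics == pytest.approx([f, 2 * f, 4 * f, 5 * f])
        assert resp.skipped == pytest.approx([3 * f, 6 * f])
        assert all(z > 2.32 for z in resp.z)

    def test_no_signal_no_harmonics(self):
        spec = spectrum_with_peaks({}, seed=1)
        resp = significant_harmonics(spec, 4.0 / 3, exclude=[4.0])
        assert resp.harmonics == []

    def test_base_rate_walk_without_exclusion(self):
        peaks = {int(round(k * 4.0 / RES)): 5.0 for k in (1, 2)}
        spec = spectrum_with_peaks(peaks, n_bins=2000, seed=2)
        resp = significant_harmonics(spec, 4.0)
        assert resp.harmonics == pytest.approx([4.0, 8.0])


class TestBaselineSubtraction:
    def test_flat_spectrum_all_zero(self):
        out = baseline_subtract(flat_spectrum(2.5), ADJACENT_ONLY)
        core = out.amplitude[0, ADJACENT_ONLY.margin : -ADJACENT_ONLY.margin]
        assert np.allclose(core, 0.0)

    def test_peak_recovers_injected_amplitude(self):
        spec = flat_spectrum(0.5)
        spec.amplitude[0, 100] += 2.0  # peak rides on the floor
        out = baseline_subtract(spec, ADJACENT_ONLY)
        assert out.amplitude[0, 100] == pytest.approx(2.0, rel=1e-9)

    def test_noise_only_mean_near_zero(self):
        rng = np.random.default_rng(7)
        amp = 5.0 + rng.standard_normal((1, 4000))
        spec = AmplitudeSpectrum(np.arange(4000) * RES, amp, ["a"])
        out = baseline_subtract(spec, ADJACENT_ONLY)
        core = out.amplitude[0, 21:-21]
        assert abs(np.mean(core)) < 0.02

    def test_edges_are_nan(self):
        out = baseline_subtract(flat_spectrum(1.0), ADJACENT_ONLY)
        assert np.isnan(out.amplitude[0, 0]) and np.isnan(out.amplitude[0, -1])

    def test_targeted_matches_full(self):
        rng = np.random.default_rng(8)
        amp = 2.0 + 0.1 * rng.standard_normal((3, 400))
        spec = AmplitudeSpectrum(np.arange(400) * RES, amp, list("abc"))
        freqs = [100 * RES, 200 * RES]
        full = baseline_subtract(spec, ADJACENT_ONLY)
        fast = baseline_subtracted_at(spec, freqs, ADJACENT_ONLY)
        assert np.allclose(fast[:, 0], full.amplitude[:, 100])
        assert np.allclose(fast[:, 1], full.amplitude[:, 200])


class TestSumHarmonics:
    def test_empty_list_zeros(self):
        assert np.all(sum_harmonics(flat_spectrum(1.0, n_ch=3), []) == 0.0)

    def test_additive_over_disjoint_sets(self):
        rng = np.random.default_rng(9)
        amp = rng.uniform(0, 1, (4, 300))
        spec = AmplitudeSpectrum(np.arange(300) * RES, amp, list("abcd"))
        fa = [50 * RES, 80 * RES]
        fb = [120 * RES, 200 * RES]
        assert np.allclose(
            sum_harmonics(spec, fa + fb),
            sum_harmonics(spec, fa) + sum_harmonics(spec, fb),
        )

    def test_recovers_injected_total_from_simulated_epoch(self):
        # injected amplitudes (0.4, 0.3, 0.2, 0.1) at the four target
        # harmonics, low noise: summed baseline-subtracted amplitude ~ 1.0
        rng = np.random.default_rng(10)
        rate, n = 256.0, 15360
        t = np.arange(n) / rate
        f = 4.0 / 3
        amps = [0.4, 0.3, 0.2, 0.1]
        ks = [1, 2, 4, 5]
        sig = sum(a * np.sin(2 * np.pi * k * f * t + rng.uniform(0, 6))
                  for a, k in zip(amps, ks))
        data = sig[None, :] + 0.02 * rng.standard_normal((1, n))
        spec = amplitude_spectrum(Epoch(data, rate, ["a"]))
        corr = baseline_subtract(spec, ADJACENT_ONLY)
        total = sum_harmonics(corr, [k * f for k in ks])[0]
        assert total == pytest.approx(1.0, rel=0.05)

    def test_noise_level_harmonic_adds_nothing_on_average(self):
        rng = np.random.default_rng(11)
        totals = []
        for _ in range(200):
            amp = 1.0 + 0.1 * rng.standard_normal((1, 100))
            spec = AmplitudeSpectrum(np.arange(100) * RES, amp, ["a"])
            corr = baseline_subtract(spec, ADJACENT_ONLY)
            totals.append(corr.amplitude[0, 50])
        assert abs(np.mean(totals)) < 0.01


class TestSNR:
    def test_flat_spectrum_unit_snr(self):
        out = snr_spectrum(flat_spectrum(2.0), ADJACENT_ONLY)
        core = out.amplitude[0, 21:-21]
        assert np.allclose(core, 1.0)

    def test_peak_seven_times_floor(self):
        spec = flat_spectrum(0.3)
        spec.amplitude[0, 90] = 7 * 0.3
        out = snr_spectrum(spec, ADJACENT_ONLY)
        assert out.amplitude[0, 90] == pytest.approx(7.0, rel=1e-9)

    def test_noise_only_median_near_one(self):
        rng = np.random.default_rng(12)
        amp = np.abs(rng.normal(3.0, 0.3, (1, 4000)))
        spec = AmplitudeSpectrum(np.arange(4000) * RES, amp, ["a"])
        out = snr_spectrum(spec, ADJACENT_ONLY)
        assert np.nanmedian(out.amplitude) == pytest.approx(1.0, abs=0.02)


class TestIndividualSignificance:
    def test_flat_windows_zero(self):
        spec = flat_spectrum(1.0)
        z, sig = individual_significance(spec, [100 * RES])
        assert z == 0.0 and not sig

    def test_hand_computed_two_windows(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(1.0, 2.0, 400)
        spec = AmplitudeSpectrum(np.arange(400) * RES, vals[None, :], ["a"])
        b1, b2 = 100, 250
        win = vals[b1 - 11 : b1 + 12] + vals[b2 - 11 : b2 + 12]
        pool = list(win[:10]) + list(win[13:])
        exp_z = (win[11] - np.mean(pool)) / np.std(pool, ddof=1)
        z, _ = individual_significance(spec, [b1 * RES, b2 * RES])
        assert z == pytest.approx(exp_z, rel=1e-12)

    def test_z_grows_with_summed_windows(self):
        # a constant response in every harmonic window accumulates linearly
        # while baseline noise grows as sqrt(k): ~sqrt(k) gain in z
        rng = np.random.default_rng(14)
        z1s, z4s = [], []
        for _ in range(300):
            vals = 1.0 + 0.1 * rng.standard_normal(400)
            for b in (100, 150, 200, 250):
                vals[b] += 0.1
            spec = AmplitudeSpectrum(np.arange(400) * RES, vals[None, :], ["a"])
            z1s.append(individual_significance(spec, [100 * RES])[0])
            z4s.append(individual_significance(spec, [b * RES for b in (100, 150, 200, 250)])[0])
        assert np.mean(z4s) / np.mean(z1s) == pytest.approx(2.0, rel=0.25)

    def test_margin_violation_rejected(self):
        with pytest.raises(ValueError):
            individual_significance(flat_spectrum(1.0, n_bins=30), [5 * RES])


class TestPooling:
    def test_pool_is_channel_mean(self):
        rng = np.random.default_rng(15)
        amp = rng.uniform(0, 1, (5, 50))
        spec = AmplitudeSpectrum(np.arange(50) * RES, amp, [f"c{i}" for i in range(5)])
        pooled = pool_channels(spec)
        assert np.allclose(pooled.amplitude[0], amp.mean(axis=0))
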