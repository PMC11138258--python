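import numpy as np
import pytest
from scipy import signal as sg

from eegretest import (
    BandScheme,
    EmptyResultError,
    EpochSet,
    Recording,
    band_powers,
    compute_features,
    fibonacci_montage,
    individual_peak_frequency,
    montage_average,
    relative_power,
    segment_epochs,
    welch_psd,
)

FS = 250.0


def _epochs(data_1d_or_2d, fs=FS):
    data = np.atleast_2d(data_1d_or_2d)
    return segment_epochs(Recording(data, fs, tuple(f"E{i+1}" for i in range(data.shape[0]))))


class TestWelch:
    def test_parseval_on_white_noise(self, rng):
        """Integrated PSD matches the sample variance within 5%."""
        x = rng.standard_normal(int(300 * FS))
        ps = welch_psd(_epochs(x))
        assert np.trapezoid(ps.absolute[0], ps.freqs) == pytest.approx(
            x.var(), rel=0.05
        )

    def test_grid_resolution_is_half_hz(self, rng):
        ps = welch_psd(_epochs(rng.standard_normal(int(10 * FS))))
        assert np.allclose(np.diff(ps.freqs), 0.5)

    def test_on_grid_tone_localised(self):
        t = np.arange(int(60 * FS)) / FS
        ps = welch_psd(_epochs(np.sin(2 * np.pi * 10 * t)))
        assert ps.freqs[np.argmax(ps.absolute[0])] == 10.0

    def test_off_grid_tone_splits_to_neighbours(self):
        """10.25 Hz leaks into the 10.0 and 10.5 bins."""
        t = np.arange(int(60 * FS)) / FS
        ps = welch_psd(_epochs(np.sin(2 * np.pi * 10.25 * t)))
        assert ps.freqs[np.argmax(ps.absolute[0])] in (10.0, 10.5)
        p = ps.absolute[0]
        both = p[ps.freqs == 10.0][0] + p[ps.freqs == 10.5][0]
        assert both / p.sum() > 0.8

    def test_matches_scipy_welch_on_gapless_data(self, rng):
        """scipy.signal.welch is the oracle when no epoch was rejected."""
        x = rng.standard_normal((3, int(60 * FS)))
        ps = welch_psd(_epochs(x))
        f2, p2 = sg.welch(
            x, FS, window="hann", nperseg=int(2 * FS), noverlap=int(FS), detrend=False
        )
        np.testing.assert_allclose(ps.freqs, f2)
        np.testing.assert_allclose(ps.absolute, p2, rtol=1e-10, atol=1e-12)

    def test_segments_do_not_span_rejection_gaps(self, rng):
        """Dropping an epoch removes exactly the segments that touched it."""
        x = rng.standard_normal((1, int(12 * FS)))
        es = _epochs(x)
        mask = es.kept_mask.copy()
        mask[2] = False
        es_gap = EpochSet(es.data, FS, es.channel_labels, 2.0, kept_mask=mask)
        ps = welch_psd(es_gap)  # runs: epochs 0-1 and 3-5
        manual = []
        for run in (es.data[[0, 1]], es.data[[3, 4, 5]]):
            chunk = run.transpose(1, 0, 2).reshape(1, -1)
            w = sg.get_window("hann", int(2 * FS), fftbins=True)
            step = int(FS)
            for s in range(0, chunk.shape[1] - int(2 * FS) + 1, step):
                seg = chunk[0, s : s + int(2 * FS)] * w
                spec = np.abs(np.fft.rfft(seg)) ** 2 / (FS * (w**2).sum())
                spec[1:-1] *= 2
                manual.append(spec)
        np.testing.assert_allclose(ps.absolute[0], np.mean(manual, axis=0), rtol=1e-10)

    def test_no_kept_epochs_rejected(self, rng):
        es = _epochs(rng.standard_normal(int(6 * FS)))
        es.kept_mask[:] = False
        with pytest.raises(EmptyResultError):
            welch_psd(es)


class TestRelativePower:
    def test_rows_sum_to_one(self, rng):
        ps = relative_power(welch_psd(_epochs(rng.standard_normal((4, int(30 * FS))))))
        in_range = (ps.freqs >= 2) & (ps.freqs <= 80)
        np.testing.assert_allclose(
            np.nansum(ps.relative[:, in_range], axis=1), 1.0, atol=1e-9
        )
        assert np.all(np.isnan(ps.relative[:, ~in_range]))

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((2, int(30 * FS)))
        r1 = relative_power(welch_psd(_epochs(x))).relative
        r2 = relative_power(welch_psd(_epochs(1000.0 * x))).relative
        np.testing.assert_allclose(r1, r2, rtol=1e-9, equal_nan=True)

    def test_flat_channel_flagged_undefined(self, rng):
        x = rng.standard_normal((2, int(10 * FS)))
        x[1] = 0.0
        ps = relative_power(welch_psd(_epochs(x)))
        assert not ps.undefined[0] and ps.undefined[1]
        assert np.all(np.isnan(ps.relative[1]))

    def test_pure_alpha_support(self):
        """Spectrum concentrated in 8-12.5 Hz -> alpha mass 1, others 0."""
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t) + 0.7 * np.sin(2 * np.pi * 11 * t)
        ps = relative_power(welch_psd(_epochs(x)))
        rbp = band_powers(ps)
        masses = {}
        scheme = BandScheme()
        for name, mask in scheme.band_masks(ps.freqs).items():
            masses[name] = np.nansum(ps.relative[0, mask])
        assert masses["alpha"] == pytest.approx(1.0, abs=1e-6)
        for other in ("delta", "theta", "beta", "gamma"):
            assert masses[other] == pytest.approx(0.0, abs=1e-6)


class TestBandPowers:
    def _spectrum(self, values_by_freq, fs=FS):
        freqs = np.fft.rfftfreq(int(2 * fs), 1 / fs)
        absolute = np.zeros((1, freqs.size))
        for f, v in values_by_freq.items():
            absolute[0, freqs == f] = v
        from eegretest import PowerSpectrum

        return relative_power(PowerSpectrum(freqs, absolute, ("E1",)))

    def test_flat_spectrum_equal_band_means(self):
        freqs = np.fft.rfftfreq(int(2 * FS), 1 / FS)
        ps = self._spectrum({f: 1.0 for f in freqs if 2 <= f <= 80})
        rbp = band_powers(ps)
        common = next(iter(rbp.values()))[0]
        for vals in rbp.values():
            assert vals[0] == pytest.approx(common, rel=1e-12)

    def test_band_means_match_bruteforce(self, rng):
        """RBP equals the hand-computed mean over the documented bins."""
        freqs = np.fft.rfftfreq(int(2 * FS), 1 / FS)
        vals = {f: rng.uniform(0.1, 5.0) for f in freqs if 2 <= f <= 80}
        ps = self._spectrum(vals)
        rbp = band_powers(ps)
        total = sum(vals.values())
        edges = {"delta": (2, 3.5), "theta": (4, 7.5), "alpha": (8, 12.5),
                 "beta": (13, 30), "gamma": (30, 80)}
        for band, (lo, hi) in edges.items():
            bins = [f for f in vals if lo <= f <= hi]
            if band == "gamma":
                bins = [f for f in bins if not (55 <= f <= 65) and f != 30.0]
            expected = np.mean([vals[f] / total for f in bins])
            assert rbp[f"rbp_{band}"][0] == pytest.approx(expected, rel=1e-10)

    def test_boundary_bin_30hz_goes_to_beta_only(self):
        masks = BandScheme().band_masks(np.fft.rfftfreq(int(2 * FS), 1 / FS))
        freqs = np.fft.rfftfreq(int(2 * FS), 1 / FS)
        i30 = int(np.flatnonzero(freqs == 30.0)[0])
        assert masks["beta"][i30] and not masks["gamma"][i30]
        stacked = np.stack(list(masks.values()))
        assert stacked.sum(axis=0).max() <= 1  # unique assignment

    def test_gamma_average_ignores_stopband(self, rng):
        freqs = np.fft.rfftfreq(int(2 * FS), 1 / FS)
        base = {f: 1.0 for f in freqs if 2 <= f <= 80}
        spiked = dict(base)
        for f in freqs:
            if 55 <= f <= 65:
                spiked[f] = 1e6
        rbp_base = band_powers(self._spectrum(base))
        rbp_spiked = band_powers(self._spectrum(spiked))
        # stopband bins enter the denominator but not gamma's average,
        # so the gamma mean over its own bins shifts only via the total
        n_gamma = int(BandScheme().band_masks(freqs)["gamma"].sum())
        base_total = sum(base.values())
        spike_total = sum(spiked.values())
        expected = rbp_base["rbp_gamma"][0] * base_total / spike_total
        assert rbp_spiked["rbp_gamma"][0] == pytest.approx(expected, rel=1e-9)

    def test_band_mass_conservation(self, rng):
        """Sum of RBP_b x bin-count_b equals the banded relative mass."""
        ps = relative_power(welch_psd(_epochs(rng.standard_normal((2, int(30 * FS))))))
        scheme = BandScheme()
        masks = scheme.band_masks(ps.freqs)
        rbp = band_powers(ps, scheme)
        for ch in range(2):
            lhs = sum(rbp[f"rbp_{b}"][ch] * masks[b].sum() for b in masks)
            rhs = sum(np.nansum(ps.relative[ch, masks[b]]) for b in masks)
            assert lhs == pytest.approx(rhs, rel=1e-10)


class TestIPF:
    def test_dominant_tone(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t) + 0.05 * np.random.default_rng(0).standard_normal(t.size)
        ps = relative_power(welch_psd(_epochs(x)))
        assert individual_peak_frequency(ps)[0] == 10.0

    def test_monotone_spectrum_returns_window_edge(self):
        from eegretest import PowerSpectrum

        freqs = np.fft.rfftfreq(int(2 * FS), 1 / FS)
        absolute = np.where(freqs > 0, 1.0 / np.maximum(freqs, 0.5) ** 1.5, 0.0)[None, :]
        ps = relative_power(PowerSpectrum(freqs, absolute, ("E1",)))
        assert individual_peak_frequency(ps)[0] == 5.0

    def test_tie_breaks_toward_lower_frequency(self):
        from eegretest import PowerSpectrum

        freqs = np.fft.rfftfreq(int(2 * FS), 1 / FS)
        absolute = np.full((1, freqs.size), 1e-6)
        absolute[0, freqs == 9.0] = 2.0
        absolute[0, freqs == 11.0] = 2.0
        ps = relative_power(PowerSpectrum(freqs, absolute, ("E1",)))
        assert individual_peak_frequency(ps)[0] == 9.0


class TestMontageAverage:
    def test_constant_field_returns_common_value(self, rng):
        m = fibonacci_montage(8)
        ps = relative_power(welch_psd(_epochs(np.tile(rng.standard_normal(int(10 * FS)), (8, 1)))))
        per_channel = {"f": np.full(8, 3.25)}
        assert montage_average(per_channel, ps, m)["f"] == 3.25

    def test_known_values_hand_mean(self, rng):
        m = fibonacci_montage(8, 2)
        ps = relative_power(welch_psd(_epochs(rng.standard_normal((8, int(10 * FS))))))
        vals = np.arange(8.0)
        keep = ~m.excluded
        expected = vals[keep].mean()
        assert montage_average({"f": vals}, ps, m)["f"] == pytest.approx(expected)

    def test_undefined_channel_excluded(self, rng):
        m = fibonacci_montage(8)
        x = rng.standard_normal((8, int(10 * FS)))
        x[3] = 0.0  # flat -> undefined
        ps = relative_power(welch_psd(_epochs(x)))
        vals = np.arange(8.0)
        expected = np.delete(vals, 3).mean()
        assert montage_average({"f": vals}, ps, m)["f"] == pytest.approx(expected)

    def test_all_undefined_rejected(self):
        m = fibonacci_montage(2)
        ps = relative_power(welch_psd(_epochs(np.zeros((2, int(10 * FS))))))
        with pytest.raises(EmptyResultError):
            montage_average({"f": np.zeros(2)}, ps, m)


def test_features_invariant_to_signal_scaling(rng):
    """RBP and IPF are unchanged when the raw signal is scaled by c > 0."""
    m = fibonacci_montage(4)
    x = rng.standard_normal((4, int(30 * FS)))
    f1 = compute_features(_epochs(x), m)
    f2 = compute_features(_epochs(123.4 * x), m)
    for name in f1:
        assert f1[name] == pytest.approx(f2[name], rel=1e-9)


@pytest.mark.parametrize("peak", [8.5, 10.0, 12.0])
def test_end_to_end_alpha_peak_recovered_exactly(peak):
    """Simulated subject with alpha at f on the 0.5 Hz grid -> IPF == f."""
    from eegretest import SimulationSpec, sample_subject_profiles, synthesize_session

    spec = SimulationSpec(
        n_subjects=1, sessions_per_subject=1, fs=FS, duration=60.0, n_channels=8,
        alpha_peak_freq_mean=peak, alpha_peak_freq_sd=0.0, alpha_peak_amp_uv=10.0,
        seed=6,
    )
    truth = sample_subject_profiles(spec)
    rec = synthesize_session(truth, 0, 0, spec)
    feats = compute_features(segment_epochs(rec), fibonacci_montage(8))
    assert feats["ipf"] == peak
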