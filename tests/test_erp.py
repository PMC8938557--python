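import numpy as np
import pytest
from scipy.special import erf

from affectbandit.erp import (
    ANALYSIS_CHANNELS,
    DEFAULT_WINDOWS,
    EVENT_CODES,
    EXPECTED_LOSS,
    EXPECTED_WIN,
    UNEXPECTED_LOSS,
    UNEXPECTED_WIN,
    ContinuousEEG,
    ErpWaveform,
    average_erp,
    bandpass,
    baseline_correct,
    classify_feedback,
    epoch,
    frn_difference,
    mean_amplitude,
    reject_artifacts,
)
from affectbandit.errors import ConfigurationError, DataError
from affectbandit.task import POOR, RICH


def make_eeg(data, events=(), sfreq=1000.0):
    data = np.atleast_2d(data)
    channels = tuple(ANALYSIS_CHANNELS[: data.shape[0]])
    return ContinuousEEG(data=data, channels=channels, sfreq=sfreq,
                         events=np.array(list(events)).reshape(-1, 2))


class TestBandpass:
    def test_passband_sine_preserved(self):
        t = np.arange(0, 60.0, 0.001)
        eeg = make_eeg(np.sin(2 * np.pi * 10 * t))
        out = bandpass(eeg)
        mid = out.data[0, 10_000:50_000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_offset_removed(self):
        eeg = make_eeg(np.full(60_000, 100.0))
        out = bandpass(eeg)
        assert np.abs(out.data[0, 20_000:40_000]).max() < 5.0

    def test_stopband_sixty_hz_attenuated(self):
        # long record; the 0.1 Hz edge has ~10 s transients, so measure the middle
        t = np.arange(0, 60.0, 0.001)
        eeg = make_eeg(np.sin(2 * np.pi * 60 * t))
        out = bandpass(eeg)
        attenuation_db = 20 * np.log10(np.abs(out.data[0, 25_000:35_000]).max())
        assert attenuation_db <= -20.0

    def test_invalid_band_rejected(self):
        eeg = make_eeg(np.zeros(1000))
        with pytest.raises(ConfigurationError):
            bandpass(eeg, low=40.0, high=0.1)
        with pytest.raises(ConfigurationError):
            bandpass(eeg, low=0.1, high=600.0)

    def test_events_preserved(self):
        eeg = make_eeg(np.zeros(2000), events=[(500, 1), (1500, 23)])
        out = bandpass(eeg)
        np.testing.assert_array_equal(out.events, eeg.events)


class TestEpoching:
    def test_shape_under_half_open_convention(self):
        eeg = make_eeg(np.zeros((2, 3000)), events=[(1000, 1), (2000, 1)])
        epochs = epoch(eeg, 1, (-100, 500))
        assert epochs.data.shape == (2, 2, 600)
        assert epochs.times_ms[0] == -100.0
        assert epochs.times_ms[-1] == 499.0

    def test_constant_signal_gives_constant_epochs(self):
        eeg = make_eeg(np.full((1, 3000), 7.0), events=[(1000, 1)])
        epochs = epoch(eeg, 1, (-100, 500))
        assert np.all(epochs.data == 7.0)

    def test_event_too_close_to_edge_skipped_and_counted(self):
        eeg = make_eeg(np.zeros((1, 3000)), events=[(50, 1), (1000, 1)])
        epochs = epoch(eeg, 1, (-100, 500))
        assert epochs.n_epochs == 1
        assert epochs.n_skipped == 1

    def test_no_usable_events_is_error(self):
        eeg = make_eeg(np.zeros((1, 300)), events=[(50, 1)])
        with pytest.raises(DataError):
            epoch(eeg, 1, (-100, 500))


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        eeg = make_eeg(np.full((1, 3000), 5.0), events=[(1000, 1)])
        corrected = baseline_correct(epoch(eeg, 1, (-100, 500)))
        assert np.allclose(corrected.data, 0.0)

    def test_prestimulus_mean_is_zero(self, rng):
        eeg = make_eeg(rng.standard_normal((3, 5000)), events=[(1000, 1), (3000, 1)])
        corrected = baseline_correct(epoch(eeg, 1, (-100, 900)))
        prestim = corrected.data[:, :, :100]
        assert np.abs(prestim.mean(axis=2)).max() < 1e-9

    def test_linear_ramp_closed_form(self):
        # ramp 0 -> 1 µV across the -100..900 ms epoch
        n = 3000
        signal = np.zeros((1, n))
        start = 1000 - 100
        ramp = np.linspace(0.0, 1.0, 1000, endpoint=False)
        signal[0, start : start + 1000] = ramp
        eeg = make_eeg(signal, events=[(1000, 1)])
        corrected = baseline_correct(epoch(eeg, 1, (-100, 900)))
        value_at_zero = corrected.data[0, 0, 100]
        expected = ramp[100] - ramp[:100].mean()
        assert value_at_zero == pytest.approx(expected, abs=1e-12)

    def test_missing_prestimulus_window_rejected(self):
        eeg = make_eeg(np.zeros((1, 3000)), events=[(1000, 1)])
        epochs = epoch(eeg, 1, (0, 500))
        with pytest.raises(ConfigurationError):
            baseline_correct(epochs)


class TestRejection:
    def make_epochs(self, amplitudes):
        """One epoch per listed peak amplitude, injected at 200 ms."""
        n = len(amplitudes)
        data = np.zeros((1, 1000 * (n + 1)))
        events = []
        for i, amp in enumerate(amplitudes):
            onset = 500 + 1000 * i
            data[0, onset + 200] = amp
            events.append((onset, 1))
        eeg = make_eeg(data, events=events)
        return baseline_correct(epoch(eeg, 1, (-100, 500)))

    def test_threshold_is_strict(self):
        epochs = self.make_epochs([51.0, 50.0, -50.0, -51.0, 10.0])
        rejected = reject_artifacts(epochs)
        assert rejected.mask.tolist() == [False, True, True, False, True]

    def test_constructed_fixture_retains_exact_count(self):
        amplitudes = [10.0] * 10
        for idx in (1, 4, 8):
            amplitudes[idx] = 80.0
        rejected = reject_artifacts(self.make_epochs(amplitudes))
        assert rejected.n_retained == 7

    def test_mask_is_label_independent(self, rng):
        data = rng.standard_normal((1, 12_000)) * 20
        events = [(500 + 1000 * i, 20 + (i % 4)) for i in range(10)]
        eeg = make_eeg(data, events=events)
        epochs = baseline_correct(epoch(eeg, list(range(20, 24)), (-100, 500)))
        relabeled = baseline_correct(epoch(
            make_eeg(data, events=[(s, 20) for s, _ in events]), 20, (-100, 500)
        ))
        np.testing.assert_array_equal(
            reject_artifacts(epochs).mask, reject_artifacts(relabeled).mask
        )


class TestClassifyFeedback:
    @pytest.mark.parametrize(
        "deck_class, reward, expected",
        [
            (POOR, 1, UNEXPECTED_WIN),
            (RICH, 0, UNEXPECTED_LOSS),
            (RICH, 1, EXPECTED_WIN),
            (POOR, 0, EXPECTED_LOSS),
        ],
    )
    def test_expectancy_map(self, deck_class, reward, expected):
        assert classify_feedback((deck_class, reward)) == expected

    def test_missing_deck_class_rejected(self):
        with pytest.raises(DataError):
            classify_feedback(("unknown", 1))


class TestAveragingAndDifference:
    def test_identical_epochs_average_to_themselves(self):
        eeg = make_eeg(np.tile(np.sin(np.arange(3000) / 50.0), (1, 1)),
                       events=[(1000, 1), (1000, 1)])
        epochs = epoch(eeg, 1, (-100, 500))
        avg = average_erp(epochs)
        np.testing.assert_allclose(avg.data, epochs.data[0])
        assert avg.n_epochs == 2

    def test_opposite_epochs_cancel(self):
        data = np.zeros((1, 4000))
        data[0, 900:1500] = 1.0
        data[0, 2900:3500] = -1.0
        eeg = make_eeg(data, events=[(1000, 1), (3000, 1)])
        avg = average_erp(epoch(eeg, 1, (-100, 500)))
        assert np.allclose(avg.data, 0.0)

    def test_noise_averages_toward_template(self, rng):
        template = 5.0 * np.exp(-0.5 * ((np.arange(600) - 300) / 40.0) ** 2)
        n_epochs, sd = 200, 10.0
        data = np.zeros((1, 1000 * (n_epochs + 1)))
        events = []
        for i in range(n_epochs):
            onset = 500 + 1000 * i
            data[0, onset - 100 : onset + 500] += template
            events.append((onset, 1))
        data += sd * rng.standard_normal(data.shape)
        avg = average_erp(epoch(make_eeg(data, events=events), 1, (-100, 500)))
        rmse = np.sqrt(np.mean((avg.data[0] - template) ** 2))
        assert rmse <= 3 * sd / np.sqrt(n_epochs)

    def test_zero_retained_epochs_is_error(self):
        eeg = make_eeg(np.zeros((1, 3000)), events=[(1000, 1)])
        epochs = epoch(eeg, 1, (-100, 500))
        epochs.mask[:] = False
        with pytest.raises(DataError):
            average_erp(epochs)

    def test_difference_wave(self):
        shape = ("Fz",)
        make = lambda c: ErpWaveform(
            data=np.full((1, 600), c), channels=shape, sfreq=1000.0,
            window_ms=(-100.0, 500.0), n_epochs=10,
        )
        diff = frn_difference(make(-5.0), make(-1.0))
        assert np.allclose(diff.data, -4.0)
        zero = frn_difference(make(2.0), make(2.0))
        assert np.allclose(zero.data, 0.0)

    def test_difference_axis_mismatch_rejected(self):
        a = ErpWaveform(np.zeros((1, 600)), ("Fz",), 1000.0, (-100.0, 500.0), 5)
        b = ErpWaveform(np.zeros((1, 500)), ("Fz",), 1000.0, (-100.0, 400.0), 5)
        with pytest.raises(DataError):
            frn_difference(a, b)


class TestMeanAmplitude:
    def test_constant_waveform(self):
        erp = ErpWaveform(np.full((2, 1000), 2.0), ("Fz", "Cz"), 1000.0, (-100.0, 900.0), 5)
        assert mean_amplitude(erp, (300, 600), ("Fz", "Cz")) == pytest.approx(2.0)

    def test_boxcar_in_frn_window(self):
        data = np.zeros((1, 1000))
        times = -100 + np.arange(1000)
        data[0, (times >= 300) & (times < 600)] = -4.0
        erp = ErpWaveform(data, ("FCz",), 1000.0, (-100.0, 900.0), 5)
        assert mean_amplitude(erp, (300, 600), ("FCz",)) == pytest.approx(-4.0)

    def test_gaussian_window_average_matches_closed_form(self):
        a, mu, sd = 6.0, 200.0, 20.0
        times = -100 + np.arange(600)
        data = a * np.exp(-0.5 * ((times - mu) / sd) ** 2)
        erp = ErpWaveform(data[None, :], ("Fz",), 1000.0, (-100.0, 500.0), 5)
        w0, w1 = 170.0, 230.0
        # analytic window average of the Gaussian over [w0, w1)
        integral = a * sd * np.sqrt(2 * np.pi) / 2 * (
            erf((w1 - mu) / (sd * np.sqrt(2))) - erf((w0 - mu) / (sd * np.sqrt(2)))
        )
        expected = integral / (w1 - w0)
        assert mean_amplitude(erp, (w0, w1), ("Fz",)) == pytest.approx(expected, abs=1e-3 * a)

    def test_window_outside_epoch_rejected(self):
        erp = ErpWaveform(np.zeros((1, 600)), ("Fz",), 1000.0, (-100.0, 500.0), 5)
        with pytest.raises(ConfigurationError):
            mean_amplitude(erp, (400, 700), ("Fz",))
        with pytest.raises(ConfigurationError):
            mean_amplitude(erp, (100, 200), ("Oz",))


class TestPipelineProperties:
    def test_linearity_under_input_scaling(self, rng):
        from affectbandit.cohort import EEGNoiseModel, ErpTemplates, synth_eeg
        from affectbandit.erp import extract_component_amplitudes
        from conftest import make_trials

        trials = make_trials([0] * 40, [1, 0] * 20, [RICH] * 40)
        eeg = synth_eeg(trials, ErpTemplates(-4.0, 5.0, -3.0),
                        EEGNoiseModel(white_sd_uv=4.0), np.random.default_rng(2),
                        dtype=np.float64)
        scaled = ContinuousEEG(data=0.5 * eeg.data, channels=eeg.channels,
                               sfreq=eeg.sfreq, events=eeg.events)
        full = extract_component_amplitudes(eeg)
        half = extract_component_amplitudes(scaled)
        for key in ("n170", "p200"):
            assert half[key] == pytest.approx(0.5 * full[key], rel=1e-6)

    def test_reject_then_average_equals_subset_average(self, rng):
        data = rng.standard_normal((1, 12_000)) * 16  # some epochs cross +/-50 µV
        events = [(500 + 1000 * i, 1) for i in range(10)]
        epochs = baseline_correct(epoch(make_eeg(data, events=events), 1, (-100, 500)))
        rejected = reject_artifacts(epochs)
        avg = average_erp(rejected)
        manual = epochs.data[rejected.mask].mean(axis=0)
        np.testing.assert_allclose(avg.data, manual)


class TestAgainstMne:
    def test_epoch_baseline_average_matches_mne(self, rng):
        mne = pytest.importorskip("mne")
        data_uv = rng.standard_normal((3, 20_000))
        events = [(2000 * (i + 1), 1) for i in range(8)]
        eeg = make_eeg(data_uv, events=events)
        ours = average_erp(baseline_correct(epoch(eeg, 1, (-100, 500))))

        info = mne.create_info(list(eeg.channels), sfreq=1000.0, ch_types="eeg")
        raw = mne.io.RawArray(data_uv * 1e-6, info, verbose="error")
        mne_events = np.array([[s, 0, 1] for s, _ in events])
        epochs = mne.Epochs(
            raw, mne_events, event_id={"stim": 1}, tmin=-0.100, tmax=0.499,
            baseline=(-0.100, -0.001), preload=True, verbose="error",
        )
        evoked = epochs.average().data * 1e6
        np.testing.assert_allclose(ours.data, evoked, atol=1e-6)
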