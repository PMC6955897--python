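"""Filtering, epoching, rejection, averaging, topography, mean amplitudes."""

import numpy as np
import pytest

from avmsi import erp, synthdata
from avmsi.erp import (ClusterSelection, ERPWaveform, PipelineError, Recording,
                       average_condition, bandpass_filter, filter_response,
                       grand_average, make_epochs, mean_amplitude,
                       reject_artifacts, sum_waveform, topographic_extrema,
                       window_samples)
from conftest import make_epochset

FS = 2048.0


def _recording(data, fs=FS, events=None, labels=None):
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data, fs, labels, events)


def _sine_recording(freq, fs=FS, seconds=4.0):
    t = np.arange(int(fs * seconds)) / fs
    return _recording(np.sin(2 * np.pi * freq * t)[None, :], fs)


class TestFilter:
    def test_dc_offset_removed(self):
        rec = _recording(np.full((1, int(FS * 4)), 50.0))
        out = bandpass_filter(rec)
        n = out.n_samples
        central = out.data[0, n // 4: 3 * n // 4]
        assert np.abs(central).max() < 1e-3 * 50.0

    def test_cutoff_attenuation_follows_documented_convention(self):
        """-3 dB single-pass at 45 Hz, hence ~-6 dB after the two passes."""
        single = filter_response(FS, [45.0])[0]
        assert 20 * np.log10(single) == pytest.approx(-3.01, abs=0.15)
        out = bandpass_filter(_sine_recording(45.0))
        n = out.n_samples
        amp = np.abs(out.data[0, n // 4: 3 * n // 4]).max()
        assert amp == pytest.approx(0.5, abs=0.05)

    def test_passband_gain_near_unity_at_10_hz(self):
        out = bandpass_filter(_sine_recording(10.0))
        n = out.n_samples
        amp = np.abs(out.data[0, n // 4: 3 * n // 4]).max()
        assert amp == pytest.approx(1.0, abs=0.05)

    def test_cutoff_beyond_nyquist_raises(self):
        rec = _sine_recording(10.0, fs=64.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, lp_hz=45.0)

    def test_response_oracle_matches_scipy_design(self):
        """Brute-force oracle: analytic Butterworth magnitude at each stage."""
        freqs = np.array([5.0, 20.0, 45.0, 90.0])
        # 2nd-order low-pass at 45, 1st-order high-pass at 1.6 (single pass)
        lp = 1 / np.sqrt(1 + (freqs / 45.0) ** 4)
        hp = (freqs / 1.6) / np.sqrt(1 + (freqs / 1.6) ** 2)
        np.testing.assert_allclose(filter_response(FS, freqs), lp * hp,
                                   rtol=2e-2)


def _scheduled_recording(fs=FS, onsets=(500.0, 2000.0, 3500.0),
                         conds=("A", "V", "AV"), n_ch=2, seconds=5.0,
                         data=None):
    import pandas as pd

    frame = pd.DataFrame({"onset_ms": onsets, "condition": conds,
                          "block": 0})
    sched = synthdata.TrialSchedule(frame)
    if data is None:
        rng = np.random.default_rng(0)
        data = rng.normal(0, 5, (n_ch, int(fs * seconds)))
    return _recording(data, fs, events=sched)


class TestEpochs:
    def test_epoch_sample_count_at_2048_hz(self):
        assert sum(window_samples(2048.0)) == 1229
        epochs = make_epochs(_scheduled_recording())
        assert epochs.epochs.shape[2] == 1229

    def test_event_near_edge_dropped_with_warning(self):
        rec = _scheduled_recording(onsets=(50.0, 2000.0, 3500.0))
        with pytest.warns(UserWarning, match="edge"):
            epochs = make_epochs(rec)
        assert epochs.epochs.shape[0] == 2
        assert epochs.dropped_events == 1

    def test_epoch_slice_equals_direct_indexing_before_baseline(self):
        rec = _scheduled_recording()
        epochs = make_epochs(rec, baseline=False)
        pre, post = window_samples(rec.fs)
        for k, onset in enumerate((500.0, 2000.0, 3500.0)):
            idx = int(round(onset / 1000.0 * rec.fs))
            np.testing.assert_array_equal(
                epochs.epochs[k], rec.data[:, idx - pre: idx + post])

    def test_baseline_correction_zeroes_prestimulus_mean(self):
        epochs = make_epochs(_scheduled_recording())
        pre, _ = window_samples(FS)
        base = epochs.epochs[:, :, :pre].mean(axis=2)
        np.testing.assert_allclose(base, 0.0, atol=1e-9)


class TestRejection:
    def test_threshold_boundary_is_strict(self):
        eps = make_epochset(np.stack([np.full((1, 10), 99.9),
                                      np.full((1, 10), 100.1)]),
                            conditions=["A", "A"])
        out = reject_artifacts(eps, 100.0)
        assert list(out.rejected) == [False, True]

    def test_three_of_ten_transients_rejected(self):
        rng = np.random.default_rng(1)
        epochs = rng.normal(0, 5, (10, 2, 50))
        for k in (1, 4, 8):
            epochs[k, 0, 25] += 150.0
        out = reject_artifacts(make_epochset(epochs), 100.0)
        assert out.n_kept == 7
        assert out.rejection_log["A"]["rejected"] == 3

    def test_huge_threshold_keeps_all(self):
        rng = np.random.default_rng(2)
        out = reject_artifacts(make_epochset(rng.normal(0, 50, (6, 2, 20))),
                               threshold_uv=1e12)
        assert out.n_kept == 6

    def test_condition_fully_rejected_raises(self):
        eps = make_epochset(np.full((2, 1, 10), 500.0), conditions=["A", "A"])
        with pytest.raises(PipelineError, match="averaging impossible"):
            reject_artifacts(eps, 100.0)

    def test_accounting_kept_plus_rejected_plus_dropped(self):
        rec = _scheduled_recording(onsets=(50.0, 2000.0, 3500.0),
                                   conds=("A", "V", "V"))
        with pytest.warns(UserWarning):
            epochs = make_epochs(rec)
        epochs.epochs[0] += 300.0
        out = reject_artifacts(epochs, 100.0)
        assert out.n_kept + out.rejected.sum() + out.dropped_events == 3


class TestAveraging:
    def test_mean_of_identical_epochs_is_the_epoch(self):
        ep = np.random.default_rng(3).normal(0, 5, (1, 2, 30))
        eps = make_epochset(np.repeat(ep, 5, axis=0), conditions=["V"] * 5)
        avg = average_condition(eps, conditions=("V",))["V"]
        np.testing.assert_allclose(avg.data, ep[0], atol=1e-12)
        assert avg.n_trials_averaged == 5

    def test_sum_waveform_is_exact_pointwise_sum(self, mini_erp_study):
        for wfs in mini_erp_study.waveforms.values():
            np.testing.assert_array_equal(
                wfs["SUM"].data, wfs["A"].data + wfs["V"].data)

    def test_grand_average_is_unweighted_mean_of_participants(self,
                                                              mini_erp_study):
        grand = mini_erp_study.grand("AV")
        oracle = np.zeros_like(grand.data)
        for wfs in mini_erp_study.waveforms.values():  # direct recomputation
            oracle += wfs["AV"].data
        oracle /= len(mini_erp_study.waveforms)
        np.testing.assert_allclose(grand.data, oracle, atol=1e-12)
        assert grand.level == "grand"

    def test_empty_condition_raises(self):
        eps = make_epochset(np.zeros((2, 1, 10)) + 1.0, conditions=["A", "A"])
        with pytest.raises(PipelineError, match="'V'"):
            average_condition(eps, conditions=("V",))


def _waveform(data, fs=512.0, labels=None):
    n = data.shape[1]
    times = np.arange(n) / fs * 1000.0 - 100.0
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return ERPWaveform("AV", data, times, labels, 10, "grand")


class TestTopography:
    def test_single_source_recovered(self):
        fs = 512.0
        t = np.arange(int(0.6 * fs)) / fs * 1000.0 - 100.0
        data = np.zeros((3, len(t)))
        data[1] = 4.0 * np.exp(-0.5 * ((t - 120) / 10.0) ** 2)
        wf = _waveform(data, fs, ["P7", "P8", "Cz"])
        sel = topographic_extrema(wf)
        assert sel.positive_electrodes == ["P8"]
        assert sel.time_bin_ms[0] <= 120 <= sel.time_bin_ms[1]

    def test_argmax_bin_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        wf = _waveform(rng.normal(0, 2, (6, 307)))
        sel = topographic_extrema(wf)
        # independent exhaustive scan over every 10 ms start
        best, best_score = None, -np.inf
        for s in np.arange(0, 161, 10.0):
            mask = (wf.times_ms >= s) & (wf.times_ms < s + 40.0)
            m = wf.data[:, mask].mean(axis=1)
            score = max(m.max(), 0) + max(-m.min(), 0)
            if score > best_score:
                best_score, best = score, s
        assert sel.time_bin_ms == (best, best + 40.0)

    def test_flat_signal_raises(self):
        with pytest.raises(PipelineError, match="flat"):
            topographic_extrema(_waveform(np.zeros((3, 307))))


class TestMeanAmplitude:
    def test_constant_waveform(self):
        wf = _waveform(np.full((2, 307), 5.0))
        assert mean_amplitude(wf, ["ch0", "ch1"], (100.0, 140.0)) == pytest.approx(5.0)

    def test_equals_double_loop_recomputation(self):
        rng = np.random.default_rng(9)
        wf = _waveform(rng.normal(0, 3, (4, 307)))
        got = mean_amplitude(wf, ["ch1", "ch3"], (60.0, 100.0))
        acc, n = 0.0, 0
        for ch in (1, 3):  # independent double loop
            for k, tms in enumerate(wf.times_ms):
                if 60.0 <= tms < 100.0:
                    acc += wf.data[ch, k]
                    n += 1
        assert got == pytest.approx(acc / n)

    def test_sum_amplitude_is_linear_in_components(self, mini_erp_study):
        wfs = next(iter(mini_erp_study.waveforms.values()))
        ch, b = ["P7", "P8"], (100.0, 140.0)
        assert mean_amplitude(wfs["SUM"], ch, b) == pytest.approx(
            mean_amplitude(wfs["A"], ch, b) + mean_amplitude(wfs["V"], ch, b))

    def test_missing_electrode_raises(self):
        wf = _waveform(np.zeros((2, 307)))
        with pytest.raises(ValueError, match="Oz"):
            mean_amplitude(wf, ["Oz"], (100.0, 140.0))


class TestLinearityChain:
    def test_pipeline_difference_equals_pipeline_of_difference(self):
        """filter/epoch/average/amplitude commute with the SUM-AV contrast."""
        task = synthdata.TaskConfig(n_blocks=1,
                                    trials_per_condition_per_block=4,
                                    sampling_rate_hz=512.0,
                                    montage=["P7", "P8", "CPz", "Cz"])
        sched = synthdata.generate_schedule(task)
        tpl = synthdata.default_templates(task.montage, fs=512.0)
        noise = synthdata.NoiseConfig(white_sd_uv=5.0, pink_sd_uv=2.0,
                                      artifact_rate=0.0, seed=4)
        tpl0 = synthdata.default_templates(task.montage, fs=512.0)
        tpl0.msi_gain = {g: 0.0 for g in synthdata.GROUPS}
        rec1 = synthdata.simulate_recording(sched, tpl, noise, "control")
        rec0 = synthdata.simulate_recording(sched, tpl0, noise, "control")

        def amp(rec):
            eps = make_epochs(bandpass_filter(rec))
            avg = average_condition(eps)
            return mean_amplitude(avg["AV"], ["P7", "P8"], (100.0, 140.0))

        diff_rec = Recording(rec1.data - rec0.data, rec1.fs,
                             list(rec1.channel_labels), sched)
        assert amp(rec1) - amp(rec0) == pytest.approx(amp(diff_rec), abs=1e-9)
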