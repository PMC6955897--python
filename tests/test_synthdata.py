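"""Generator contracts: schedule balance, signal superposition, RT architectures."""

import numpy as np
import pandas as pd
import pytest

from avmsi import erp, racemodel, synthdata
from avmsi.synthdata import (ConfigError, NoiseConfig, RtModelConfig,
                             TaskConfig, default_templates, generate_schedule,
                             simulate_recording, simulate_rts)


class TestSchedule:
    def test_default_block_condition_counts(self):
        sched = generate_schedule(TaskConfig(seed=3))
        counts = sched.condition_counts()
        assert counts.shape == (8, 3)
        assert (counts == 34).all().all()

    def test_minimal_schedule_has_one_event_per_condition(self):
        sched = generate_schedule(TaskConfig(n_blocks=1,
                                             trials_per_condition_per_block=1))
        assert sched.n_events == 3
        assert sorted(sched.frame["condition"]) == ["A", "AV", "V"]

    def test_interonset_gaps_cover_fixation_plus_stimulus(self):
        """Gap = previous stimulus duration + 1000-3000 ms fixation draw."""
        cfg = TaskConfig(seed=7)
        sched = generate_schedule(cfg)
        onsets = sched.frame["onset_ms"].to_numpy()
        durs = np.array([cfg.stimulus_duration_ms(c)
                         for c in sched.frame["condition"]])
        gaps = np.diff(onsets)
        assert len(gaps) == 815
        lo, hi = cfg.isi_range_ms
        assert np.all(gaps >= lo + durs[:-1] - 1e-9)
        assert np.all(gaps <= hi + durs[:-1] + 1e-9)
        # mean gap ~ 2000 ms fixation + mean stimulus duration (140 ms)
        assert abs(gaps.mean() - (2000 + durs[:-1].mean())) < 60

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_determinism_and_balance_across_seeds(self, seed):
        a = generate_schedule(TaskConfig(n_blocks=2, seed=seed))
        b = generate_schedule(TaskConfig(n_blocks=2, seed=seed))
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert (a.condition_counts() == 34).all().all()

    def test_invalid_config_names_offending_field(self):
        with pytest.raises(ConfigError, match="n_blocks"):
            generate_schedule(TaskConfig(n_blocks=0))
        with pytest.raises(ConfigError, match="isi_range_ms"):
            generate_schedule(TaskConfig(isi_range_ms=(3000.0, 1000.0)))
        with pytest.raises(ConfigError, match="montage"):
            generate_schedule(TaskConfig(montage=["Cz", "Cz"]))


class TestRecording:
    def _mini(self, **noise_kw):
        task = TaskConfig(n_blocks=1, trials_per_condition_per_block=4,
                          sampling_rate_hz=512.0)
        sched = generate_schedule(task)
        templates = default_templates(task.montage, fs=512.0)
        return sched, templates, NoiseConfig(**noise_kw)

    def test_noiseless_av_epoch_is_exact_template_sum(self):
        """With msi_gain=0 and zero noise, AV = A + V pointwise."""
        sched, templates, noise = self._mini(white_sd_uv=0.0, pink_sd_uv=0.0,
                                             artifact_rate=0.0)
        templates.msi_gain = {g: 0.0 for g in synthdata.GROUPS}
        rec = simulate_recording(sched, templates, noise, "control")
        expected = templates.unisensory["A"] + templates.unisensory["V"]
        n_t = templates.n_samples
        for onset, cond in zip(sched.frame["onset_ms"],
                               sched.frame["condition"]):
            if cond != "AV":
                continue
            idx = int(round(onset / 1000.0 * 512.0))
            np.testing.assert_allclose(rec.data[:, idx:idx + n_t], expected,
                                       atol=1e-12)

    def test_condition_average_noise_shrinks_as_sqrt_n(self):
        """RMS of (condition average - template) ~ sigma/sqrt(N) at N=272."""
        sigma = 10.0
        task = TaskConfig(sampling_rate_hz=512.0,
                          montage=["P7", "P8", "CPz", "Cz"])
        sched = generate_schedule(task)  # 272 trials per condition
        templates = default_templates(task.montage, fs=512.0)
        rec = simulate_recording(sched, templates,
                                 NoiseConfig(white_sd_uv=sigma, pink_sd_uv=0.0,
                                             artifact_rate=0.0), "control")
        epochs = erp.make_epochs(rec, baseline=False)
        avg = erp.average_condition(epochs)["V"]
        n_t = templates.n_samples
        mask = (avg.times_ms >= 0) & (avg.times_ms < n_t / 512.0 * 1000.0)
        resid = avg.data[:, mask] - templates.unisensory["V"]
        rms = np.sqrt((resid ** 2).mean())
        expected = sigma / np.sqrt(avg.n_trials_averaged)
        assert abs(rms - expected) / expected < 0.20

    def test_no_artifacts_keeps_epochs_below_threshold(self):
        sched, templates, noise = self._mini(white_sd_uv=5.0, pink_sd_uv=2.0,
                                             artifact_rate=0.0)
        rec = simulate_recording(sched, templates, noise, "control")
        epochs = erp.reject_artifacts(erp.make_epochs(rec), 100.0)
        assert epochs.rejected.sum() == 0

    def test_unknown_group_raises(self):
        sched, templates, noise = self._mini()
        with pytest.raises(ConfigError, match="group"):
            simulate_recording(sched, templates, noise, "patients")


class TestRtModel:
    def test_degenerate_race_equals_unisensory_distribution(self):
        """rho=1 with identical channels makes AV a copy of the channel draw."""
        task = TaskConfig(n_blocks=1, trials_per_condition_per_block=400)
        sched = generate_schedule(task)
        model = RtModelConfig(rho=1.0, participant_sd_ms=0.0,
                              condition_jitter_sd_ms=0.0)
        model.channel_params["control"] = {"A": (280.0, 40.0),
                                           "V": (280.0, 40.0)}
        rts = simulate_rts(sched, model, "control", seed=5)
        av = rts.loc[rts["condition"] == "AV", "rt_ms"].to_numpy()
        uni = rts.loc[rts["condition"] == "V", "rt_ms"].to_numpy()
        ks = _ks_distance(av, uni)
        assert ks < 0.1  # same distribution up to sampling error

    def test_condition_and_group_ordering_of_means(self):
        """AV < V < A within each group; SCNP slower than control."""
        rts = synthdata.simulate_rt_study(n_per_group=40, seed=0)
        m = rts.groupby(["group", "condition"], observed=True)["rt_ms"].mean()
        for g in synthdata.GROUPS:
            assert m[g, "AV"] < m[g, "V"] < m[g, "A"]
        assert (m["SCNP"].mean() - m["control"].mean()) > 15

    def test_race_respects_miller_bound_in_large_sample(self):
        """Empirical AV CDF never exceeds F_A + F_V beyond sampling error."""
        task = TaskConfig(n_blocks=1, trials_per_condition_per_block=2000)
        sched = generate_schedule(task)
        model = RtModelConfig(architecture="race", participant_sd_ms=0.0,
                              condition_jitter_sd_ms=0.0)
        rts = simulate_rts(sched, model, "control", seed=9)
        by = {c: rts.loc[rts["condition"] == c, "rt_ms"].to_numpy()
              for c in synthdata.CONDITIONS}
        grid = np.linspace(100, 400, 61)
        f_av = racemodel.cdf_values(by["AV"], grid)
        bound = racemodel.miller_bound(racemodel.cdf_values(by["A"], grid),
                                      racemodel.cdf_values(by["V"], grid))
        stderr = 3 * np.sqrt(0.25 / 2000)
        assert np.all(f_av <= bound + stderr)

    def test_unknown_architecture_raises(self):
        with pytest.raises(ConfigError, match="architecture"):
            RtModelConfig(architecture="diffusion").validate()

    def test_rts_deterministic_given_seed(self):
        sched = generate_schedule(TaskConfig(n_blocks=1,
                                             trials_per_condition_per_block=5))
        a = simulate_rts(sched, RtModelConfig(), "control", seed=4)
        b = simulate_rts(sched, RtModelConfig(), "control", seed=4)
        pd.testing.assert_frame_equal(a, b)


def _ks_distance(a, b):
    grid = np.sort(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    return np.abs(fa - fb).max()
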