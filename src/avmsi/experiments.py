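"""Replicate simulation studies built on the synthetic generators.

These functions run many scaled-down experiments end to end (simulate EEG or
RTs, preprocess, test) to measure operating characteristics of the analysis
chain: the false-positive rate of the SIGNAL effect under exact
superposition, the detection/false-alarm rates of the race-model violation
test under coactivation vs. race architectures, and recovery of a known
spatio-temporal interaction by the topographic selection and the time-course
ANOVA.

Problem sizes are deliberately small (reduced sampling rate, montage, and
trial counts) so that hundreds of replicates run at desk scale; the defaults
preserve the structure of the full design (two groups, three conditions,
balanced blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior, erp, msistats, racemodel, synthdata

__all__ = [
    "simulate_participant_erps",
    "erp_study",
    "signal_type1_rate",
    "violation_rates",
    "localization_study",
    "rt_anova_type1_rate",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """n independent sub-seeds derived from one integer seed, each < 2^31."""
    return [int(s) for s in
            (np.random.SeedSequence(seed).generate_state(n) >> 1)]


def simulate_participant_erps(task: synthdata.TaskConfig,
                              templates: synthdata.TemplateSet,
                              noise: synthdata.NoiseConfig,
                              group: str,
                              reject_threshold_uv: float = 100.0,
                              apply_filter: bool = True
                              ) -> dict[str, erp.ERPWaveform]:
    """One participant through simulate -> filter -> epoch -> reject -> average.

    Returns the A, V, AV averages plus the derived SUM waveform.
    """
    sched = synthdata.generate_schedule(task)
    rec = synthdata.simulate_recording(sched, templates, noise, group)
    if apply_filter:
        rec = erp.bandpass_filter(rec)
    epochs = erp.make_epochs(rec)
    epochs = erp.reject_artifacts(epochs, reject_threshold_uv)
    wfs = erp.average_condition(epochs)
    wfs["SUM"] = erp.sum_waveform(wfs["A"], wfs["V"])
    return wfs


@dataclass
class ErpStudy:
    """Per-participant waveforms plus group labels for a simulated cohort."""

    waveforms: dict[str, dict[str, erp.ERPWaveform]]
    groups: dict[str, str]

    def grand(self, role: str) -> erp.ERPWaveform:
        return erp.grand_average([w[role] for w in self.waveforms.values()])


def erp_study(n_per_group: int, task: synthdata.TaskConfig,
              templates: synthdata.TemplateSet,
              noise: synthdata.NoiseConfig, seed: int) -> ErpStudy:
    """Simulate a two-group EEG cohort, one seed pair per participant."""
    seeds = _child_seeds(seed, 2 * 2 * n_per_group)
    waveforms, groups = {}, {}
    i = 0
    for group in synthdata.GROUPS:
        for k in range(n_per_group):
            pid = f"{group[:3]}{k:02d}"
            t = synthdata.TaskConfig(**{**task.__dict__, "seed": seeds[i]})
            nz = synthdata.NoiseConfig(**{**noise.__dict__,
                                          "seed": seeds[i + 1]})
            waveforms[pid] = simulate_participant_erps(t, templates, nz, group)
            groups[pid] = group
            i += 2
    return ErpStudy(waveforms, groups)


# ---------------------------------------------------------------------------
# superposition null: type-I rate of the SIGNAL effect

_MINI_MONTAGE = ["P7", "P8", "CPz", "Cz"]


def signal_type1_rate(n_reps: int = 1000, n_per_group: int = 6,
                      seed: int = 0, alpha: float = 0.05,
                      fs: float = 256.0, trials_per_block: int = 8
                      ) -> dict:
    """False-positive rate of the Method-1 SIGNAL effect when msi_gain = 0.

    Each replicate simulates a reduced cohort (4 analysis channels, one
    block) with the AV response set to the exact sum of the unisensory
    templates, runs the ERP pipeline, and tests SUM vs. MSI in the
    100-140 ms bin on the positive cluster.  Under superposition the
    rejection rate should sit at alpha.
    """
    templates = synthdata.default_templates(_MINI_MONTAGE, fs=fs)
    templates.msi_gain = {g: 0.0 for g in synthdata.GROUPS}
    cluster = erp.ClusterSelection(["P7", "P8"], ["CPz", "Cz"], (100.0, 140.0))
    rep_seeds = _child_seeds(seed, n_reps)
    hits = 0
    for r in range(n_reps):
        task = synthdata.TaskConfig(n_blocks=1,
                                    trials_per_condition_per_block=trials_per_block,
                                    sampling_rate_hz=fs,
                                    montage=list(_MINI_MONTAGE))
        noise = synthdata.NoiseConfig(artifact_rate=0.0)
        study = erp_study(n_per_group, task, templates, noise, rep_seeds[r])
        table = msistats.amplitude_table(study.waveforms, study.groups, cluster)
        res = msistats.method1(table, cluster.time_bin_ms, "positive")
        p_signal = next(x for x in res if x.effect == "signal").p
        hits += p_signal < alpha
    return {"rate": hits / n_reps, "n_reps": n_reps, "alpha": alpha}


# ---------------------------------------------------------------------------
# race vs. coactivation discrimination


def violation_rates(architecture: str, n_reps: int = 100,
                    n_participants: int = 12, seed: int = 0,
                    group: str = "control", alpha: float = 0.05,
                    task: synthdata.TaskConfig | None = None,
                    model: synthdata.RtModelConfig | None = None) -> dict:
    """Fraction of replicate cohorts showing >=1 significant bound violation.

    Each replicate simulates ``n_participants`` of one group at full trial
    count (8 blocks x 34 trials per condition by default), filters RTs,
    estimates per-participant CDFs and runs the select-then-test violation
    procedure.  For ``architecture='race'`` the channels are independent
    (rho = 0), the configuration under which the Miller bound is exact.
    """
    task = task or synthdata.TaskConfig()
    if model is None:
        model = synthdata.RtModelConfig(architecture=architecture)
        if architecture == "race":
            model.rho = 0.0
    else:
        model.architecture = architecture
    sched = synthdata.generate_schedule(task)  # condition sequence shared
    rep_seeds = _child_seeds(seed, n_reps)
    hits = 0
    for r in range(n_reps):
        part_seeds = _child_seeds(rep_seeds[r], n_participants)
        tables = [synthdata.simulate_rts(sched, model, group,
                                         participant=f"p{i:02d}",
                                         seed=part_seeds[i])
                  for i in range(n_participants)]
        rts = behavior.filter_rts(pd.concat(tables, ignore_index=True))
        cdfs = racemodel.estimate_cdfs(rts)
        tests = racemodel.test_violations(cdfs)
        if any(t.tested and t.p < alpha and t.t < 0 for t in tests):
            hits += 1
    return {"rate": hits / n_reps, "n_reps": n_reps,
            "architecture": architecture, "n_participants": n_participants}


# ---------------------------------------------------------------------------
# localization recovery


def localization_study(seed: int = 0, n_per_group: int = 12,
                       fs: float = 512.0, n_blocks: int = 2,
                       alpha: float = 0.05) -> dict:
    """Recover the injected 100-140 ms interaction topography end to end.

    Simulates a cohort with the default study-mimicking templates (positive
    parieto-occipital / negative centro-parietal components, subadditive
    interaction confined to 100-140 ms), runs the full ERP pipeline, the
    topographic selection on the AV grand average, Method 1 in the selected
    bin and Method 2 over the fixed 60-180 ms bins.
    """
    task = synthdata.TaskConfig(n_blocks=n_blocks, sampling_rate_hz=fs)
    templates = synthdata.default_templates(task.montage, fs=fs)
    noise = synthdata.NoiseConfig()
    study = erp_study(n_per_group, task, templates, noise, seed)

    cluster = erp.topographic_extrema(study.grand("AV"))
    bins = list(msistats.METHOD2_BINS)
    if tuple(cluster.time_bin_ms) not in bins:
        bins.append(tuple(cluster.time_bin_ms))
    table = msistats.amplitude_table(study.waveforms, study.groups, cluster,
                                     bins=bins)

    m1 = {pol: msistats.method1(table, cluster.time_bin_ms, pol)
          for pol in ("positive", "negative")}
    m2 = {pol: msistats.method2_timecourse(table, pol, alpha=alpha)
          for pol in ("positive", "negative")}

    def flagged(frame: pd.DataFrame) -> set[tuple[float, float]]:
        msi_effects = frame["effect"].isin(["signal", "group * signal"])
        sig = frame[msi_effects & frame["significant"]]
        return set(zip(sig["bin_start_ms"], sig["bin_end_ms"]))

    return {
        "cluster": cluster,
        "method1": m1,
        "method2": m2,
        "flagged_bins": {pol: flagged(m2[pol]) for pol in m2},
        "table": table,
    }


# ---------------------------------------------------------------------------
# RT ANOVA calibration


def rt_anova_type1_rate(n_reps: int = 1000, n_per_group: int = 12,
                        seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I rate of the within (condition) effect under a null RT model.

    Cell means are drawn with no group or condition effect (shared subject
    offsets plus independent cell noise); the condition effect of the mixed
    ANOVA should reject at alpha.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = np.repeat(list(synthdata.GROUPS), n_per_group)
    hits = 0
    for _ in range(n_reps):
        y = (280.0 + rng.normal(0, 20, n)[:, None]
             + rng.normal(0, 10, (n, 3)))
        data = pd.DataFrame({
            "participant": np.repeat([f"p{i}" for i in range(n)], 3),
            "group": np.repeat(groups, 3),
            "condition": np.tile(list(synthdata.CONDITIONS), n),
            "value": y.ravel(),
        })
        res = behavior.mixed_anova(data)
        p_cond = next(x for x in res if x.effect == "condition").p
        hits += p_cond < alpha
    return {"rate": hits / n_reps, "n_reps": n_reps, "alpha": alpha}
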