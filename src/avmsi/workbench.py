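"""I/O, configuration, and the end-to-end simulate-to-statistics pipeline.

File formats are deliberately plain text:

* **Recording dialect** -- a tab-separated matrix, one row per sample, one
  column per channel, preceded by comment headers ``# avmsi-recording v1``,
  ``# fs_hz: <rate>`` and ``# unit: uV``; the first non-comment line is the
  channel-label header.  Amplitudes are written at 0.0001 uV resolution.
* **Events** -- TSV with columns onset_ms, duration_ms, trial_type, block.
* **RT tables** -- TSV with columns participant, group, condition, rt_ms.
* **Results** -- CSV (effect, F, df1, df2, p, partial_eta_sq and friends).
* **Config** -- YAML, round-tripping :class:`PipelineConfig` losslessly.

:func:`run_pipeline` chains simulation, behavioral analysis, race-model
testing, ERP preprocessing and the SUM-vs-MSI ANOVAs into one run directory
with a manifest (config hash, seed, stage outputs), byte-reproducible for a
fixed (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, erp, experiments, msistats, racemodel, synthdata

__all__ = [
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_rt_table",
    "write_rt_table",
    "anova_frame",
    "run_pipeline",
]


class FormatError(ValueError):
    """A file does not follow the documented dialect."""


# ---------------------------------------------------------------------------
# recording dialect

_MAGIC = "# avmsi-recording v1"


def write_recording(rec: erp.Recording, path: str | Path) -> Path:
    """Write a recording in the delimited text dialect (0.0001 uV steps)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n# fs_hz: {rec.fs!r}\n# unit: uV\n")
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.4f", delimiter="\t")
    return path


def read_recording(path: str | Path,
                   montage: list[str] | None = None) -> erp.Recording:
    """Read the delimited dialect; optionally reorder channels to ``montage``.

    Channel identity is carried by the header labels, so files whose columns
    were permuted read back into the requested canonical order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording: {path}")
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise FormatError(f"{path}: missing '{_MAGIC}' header")
        fs = None
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            if key.strip() == "fs_hz":
                fs = float(val)
            line = fh.readline()
        if fs is None:
            raise FormatError(f"{path}: no '# fs_hz:' header line")
        labels = line.rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    if montage is not None:
        missing = set(montage) - set(labels)
        if missing:
            raise FormatError(f"{path}: channels absent from file: {missing}")
        data = data[[labels.index(c) for c in montage]]
        labels = list(montage)
    return erp.Recording(data, fs, labels)


# ---------------------------------------------------------------------------
# event and RT tables


def write_events(schedule: synthdata.TrialSchedule, path: str | Path,
                 task: synthdata.TaskConfig | None = None) -> Path:
    frame = schedule.frame.rename(columns={"condition": "trial_type"}).copy()
    task = task or synthdata.TaskConfig()
    frame["duration_ms"] = [task.stimulus_duration_ms(c)
                            for c in frame["trial_type"]]
    frame[["onset_ms", "duration_ms", "trial_type", "block"]].to_csv(
        path, sep="\t", index=False)
    return Path(path)


def read_events(path: str | Path) -> synthdata.TrialSchedule:
    if not Path(path).exists():
        raise FileNotFoundError(f"no such event table: {path}")
    frame = pd.read_csv(path, sep="\t")
    need = {"onset_ms", "trial_type", "block"}
    if not need <= set(frame.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    return synthdata.TrialSchedule(
        frame.rename(columns={"trial_type": "condition"})
        [["onset_ms", "condition", "block"]])


def write_rt_table(rts: pd.DataFrame, path: str | Path) -> Path:
    cols = [c for c in ("participant", "group", "condition", "rt_ms", "kept")
            if c in rts.columns]
    rts[cols].to_csv(path, sep="\t", index=False)
    return Path(path)


def read_rt_table(path: str | Path) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"no such RT table: {path}")
    frame = pd.read_csv(path, sep="\t")
    need = {"participant", "group", "condition", "rt_ms"}
    if not need <= set(frame.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    return frame


def anova_frame(results: list[behavior.AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs; YAML round-trips losslessly.

    Defaults reproduce the study parameters wherever the design states one
    (8 x 34 trials, 2048 Hz, 1.6-45 Hz filtering, +/-100 uV rejection,
    100 ms baseline, 12 participants per group).  :meth:`demo` returns a
    size-reduced variant for quick runs.
    """

    task: synthdata.TaskConfig = field(default_factory=synthdata.TaskConfig)
    noise: synthdata.NoiseConfig = field(default_factory=synthdata.NoiseConfig)
    rt_model: synthdata.RtModelConfig = field(
        default_factory=synthdata.RtModelConfig)
    n_per_group: int = 12
    filter_hp_hz: float = 1.6
    filter_lp_hz: float = 45.0
    filter_hp_slope_db_oct: float = 12.0
    filter_lp_slope_db_oct: float = 24.0
    reject_threshold_uv: float = 100.0
    rt_filter_k_sd: float = 2.0
    selection_bin_width_ms: float = 40.0
    msi_gain_control: float = 1.0
    msi_gain_scnp: float = 0.3
    alpha: float = 0.05
    seed: int = 0
    save_recordings: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"]["isi_range_ms"] = list(self.task.isi_range_ms)
        d["rt_model"]["channel_params"] = {
            g: {ch: list(ps) for ch, ps in chans.items()}
            for g, chans in self.rt_model.channel_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        task = synthdata.TaskConfig(**d.pop("task"))
        task.isi_range_ms = tuple(task.isi_range_ms)
        noise = synthdata.NoiseConfig(**d.pop("noise"))
        rt_model = synthdata.RtModelConfig(**d.pop("rt_model"))
        rt_model.channel_params = {
            g: {ch: tuple(ps) for ch, ps in chans.items()}
            for g, chans in rt_model.channel_params.items()}
        return cls(task=task, noise=noise, rt_model=rt_model, **d)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def demo(cls, seed: int = 0) -> "PipelineConfig":
        """Desk-scale configuration: 256 Hz, 1 block x 6 trials, 4+4 subjects."""
        return cls(
            task=synthdata.TaskConfig(n_blocks=1,
                                      trials_per_condition_per_block=6,
                                      sampling_rate_hz=256.0),
            n_per_group=4, seed=seed)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and run every analysis stage, writing all tables.

    Stage order: simulate -> behavioral -> racemodel -> erp -> stats ->
    report.  Identical (config, seed) produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = config.to_yaml(out / "config.yaml")
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_path.read_bytes()).hexdigest(),
        "stages": {},
    }

    def done(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        # -- simulate ------------------------------------------------------
        seeds = experiments._child_seeds(config.seed, 6 * config.n_per_group)
        templates = synthdata.default_templates(
            config.task.montage, fs=config.task.sampling_rate_hz)
        templates.msi_gain = {"control": config.msi_gain_control,
                              "SCNP": config.msi_gain_scnp}
        rt_tables = []
        waveforms: dict[str, dict[str, erp.ERPWaveform]] = {}
        groups: dict[str, str] = {}
        accounting = []
        i = 0
        for group in synthdata.GROUPS:
            for k in range(config.n_per_group):
                pid = f"{group[:3]}{k:02d}"
                task = synthdata.TaskConfig(
                    **{**config.task.__dict__, "seed": seeds[i]})
                noise = synthdata.NoiseConfig(
                    **{**config.noise.__dict__, "seed": seeds[i + 1]})
                sched = synthdata.generate_schedule(task)
                rt_tables.append(synthdata.simulate_rts(
                    sched, config.rt_model, group, pid, seed=seeds[i + 2]))
                rec = synthdata.simulate_recording(sched, templates, noise,
                                                   group)
                if config.save_recordings:
                    write_recording(rec, out / f"recording_{pid}.tsv")
                    write_events(sched, out / f"events_{pid}.tsv", task)
                rec = erp.bandpass_filter(
                    rec, config.filter_hp_hz, config.filter_lp_hz,
                    config.filter_hp_slope_db_oct,
                    config.filter_lp_slope_db_oct)
                epochs = erp.make_epochs(rec)
                epochs = erp.reject_artifacts(epochs,
                                              config.reject_threshold_uv)
                wfs = erp.average_condition(epochs)
                wfs["SUM"] = erp.sum_waveform(wfs["A"], wfs["V"])
                waveforms[pid] = wfs
                groups[pid] = group
                accounting.append({
                    "participant": pid, "group": group,
                    "scheduled": sched.n_events,
                    "dropped": epochs.dropped_events,
                    "rejected": int(epochs.rejected.sum()),
                    "kept": epochs.n_kept})
                i += 3
        rts = pd.concat(rt_tables, ignore_index=True)
        write_rt_table(rts, out / "rts_raw.tsv")
        pd.DataFrame(accounting).to_csv(out / "epoch_accounting.csv",
                                        index=False)
        done("simulate", participants=len(groups))

        # -- behavioral ----------------------------------------------------
        rts = behavior.filter_rts(rts, config.rt_filter_k_sd)
        write_rt_table(rts, out / "rts_filtered.tsv")
        rts.attrs["rejection_log"].to_csv(out / "rt_rejection_log.csv",
                                          index=False)
        means = behavior.cell_means(rts)
        means.to_csv(out / "rt_cell_means.csv", index=False)
        rt_anova = behavior.mixed_anova(means)
        anova_frame(rt_anova).to_csv(out / "rt_anova.csv", index=False)
        behavior.tukey_hsd(means, alpha=config.alpha).to_csv(
            out / "rt_tukey.csv", index=False)
        done("behavioral", effects=len(rt_anova))

        # -- race model ----------------------------------------------------
        viol_frames = []
        for group in synthdata.GROUPS:
            cdfs = racemodel.estimate_cdfs(rts[rts["group"] == group])
            vf = racemodel.violations_frame(racemodel.test_violations(cdfs))
            vf.insert(0, "group", group)
            viol_frames.append(vf)
        pd.concat(viol_frames, ignore_index=True).to_csv(
            out / "race_violations.csv", index=False)
        done("racemodel", groups=len(viol_frames))

        # -- erp topography + amplitudes -----------------------------------
        grand_av = erp.grand_average([w["AV"] for w in waveforms.values()])
        cluster = erp.topographic_extrema(
            grand_av, bin_width_ms=config.selection_bin_width_ms)
        bins = list(msistats.METHOD2_BINS)
        if tuple(cluster.time_bin_ms) not in bins:
            bins.append(tuple(cluster.time_bin_ms))
        table = msistats.amplitude_table(waveforms, groups, cluster, bins=bins)
        table.to_csv(out / "amplitudes.csv", index=False)
        done("erp", positive=cluster.positive_electrodes,
             negative=cluster.negative_electrodes,
             time_bin_ms=list(cluster.time_bin_ms))

        # -- stats ---------------------------------------------------------
        m1_rows, m2_frames = [], []
        for pol in ("positive", "negative"):
            electrodes = getattr(cluster, f"{pol}_electrodes")
            if not electrodes:
                continue
            for r in msistats.method1(table, cluster.time_bin_ms, pol):
                d = r.as_dict()
                d.update(polarity=pol, bin_start_ms=cluster.time_bin_ms[0],
                         bin_end_ms=cluster.time_bin_ms[1])
                m1_rows.append(d)
            m2_frames.append(msistats.method2_timecourse(
                table, pol, alpha=config.alpha))
        pd.DataFrame(m1_rows).to_csv(out / "method1_anova.csv", index=False)
        pd.concat(m2_frames, ignore_index=True).to_csv(
            out / "method2_timecourse.csv", index=False)
        done("stats", method1_effects=len(m1_rows))

        _write_report(out, rt_anova, m1_rows, cluster)
        done("report", path="report.md")
    except Exception as exc:  # partial outputs stay; manifest names the stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    return out


def _write_report(out: Path, rt_anova, m1_rows, cluster) -> None:
    lines = ["# avmsi run report", "",
             f"Topographic selection: positive {cluster.positive_electrodes},"
             f" negative {cluster.negative_electrodes},"
             f" bin {cluster.time_bin_ms[0]:.0f}-{cluster.time_bin_ms[1]:.0f} ms",
             "", "## RT mixed ANOVA", ""]
    for r in rt_anova:
        lines.append(f"- {r.effect}: F({r.df1},{r.df2}) = {r.F:.3f}, "
                     f"p = {r.p:.4g}, eta2p = {r.partial_eta_sq:.3f}")
    lines += ["", "## Method 1 (SUM vs. MSI)", ""]
    for d in m1_rows:
        lines.append(f"- [{d['polarity']}] {d['effect']}: "
                     f"F({d['df1']},{d['df2']}) = {d['F']:.3f}, "
                     f"p = {d['p']:.4g}, eta2p = {d['partial_eta_sq']:.3f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
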