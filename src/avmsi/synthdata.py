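"""Synthetic task schedules, EEG, and reaction times with controllable MSI.

Emulates a simple audiovisual redundant-target experiment: 8 blocks of 34
auditory (A), 34 visual (V) and 34 audiovisual (AV) stimuli in randomized
order, each preceded by a 1000-3000 ms fixation, recorded at 2048 Hz.

Three generators feed the downstream analyses:

* :func:`generate_schedule` -- the ordered event sequence.
* :func:`simulate_recording` -- continuous EEG built from per-condition ERP
  templates plus white + 1/f noise.  AV events receive the A template + the
  V template + ``msi_gain x msi_interaction``, so ``msi_gain = 0`` realizes
  exact superposition (the additive-model null) and a nonzero gain injects a
  known subadditive interaction.
* :func:`simulate_rts` -- reaction times under an independent/correlated
  *race* (AV = faster of two unisensory channels; can never violate the
  Miller bound) or under *coactivation* (the race minimum shifted faster by
  a gain, which does violate it).

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .erp import Recording

__all__ = [
    "TaskConfig",
    "TrialSchedule",
    "TemplateSet",
    "NoiseConfig",
    "RtModelConfig",
    "generate_schedule",
    "default_templates",
    "simulate_recording",
    "simulate_rts",
    "simulate_rt_study",
    "CONDITIONS",
    "GROUPS",
    "DEFAULT_MONTAGE",
]

CONDITIONS = ("A", "V", "AV")
GROUPS = ("control", "SCNP")

#: The analysis electrodes (parieto-occipital positive cluster, centro-parietal
#: negative cluster, Pz, and two frontal channels that carry the blink-artifact
#: model) plus POz/Oz.
DEFAULT_MONTAGE = ["Fp1", "Fp2", "Cz", "CPz", "Pz", "POz", "Oz",
                   "P7", "P8", "PO7", "PO8"]


class ConfigError(ValueError):
    """A configuration field violates its invariant; the message names it."""


@dataclass
class TaskConfig:
    """Task schedule parameters.

    Defaults reproduce the study design: 8 blocks x 34 trials per condition,
    fixation 1000-3000 ms, 60 ms visual disk, ~180 ms auditory word,
    2048 Hz sampling.  The fixation interval precedes each stimulus, so the
    onset-to-onset gap is (previous stimulus duration + fixation draw).
    """

    n_blocks: int = 8
    trials_per_condition_per_block: int = 34
    isi_range_ms: tuple[float, float] = (1000.0, 3000.0)
    visual_duration_ms: float = 60.0
    auditory_duration_ms: float = 180.0
    sampling_rate_hz: float = 2048.0
    montage: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if self.trials_per_condition_per_block < 1:
            raise ConfigError("trials_per_condition_per_block must be >= 1")
        lo, hi = self.isi_range_ms
        if not (0 < lo < hi):
            raise ConfigError("isi_range_ms must satisfy 0 < low < high")
        if self.visual_duration_ms <= 0:
            raise ConfigError("visual_duration_ms must be positive")
        if self.auditory_duration_ms <= 0:
            raise ConfigError("auditory_duration_ms must be positive")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if len(set(self.montage)) != len(self.montage):
            raise ConfigError("montage labels must be unique")

    def stimulus_duration_ms(self, condition: str) -> float:
        if condition == "A":
            return self.auditory_duration_ms
        if condition == "V":
            return self.visual_duration_ms
        if condition == "AV":
            return max(self.auditory_duration_ms, self.visual_duration_ms)
        raise ConfigError(f"unknown condition {condition!r}")


@dataclass
class TrialSchedule:
    """Ordered A/V/AV events: columns onset_ms, condition, block."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        onsets = self.frame["onset_ms"].to_numpy()
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.frame)

    def condition_counts(self) -> pd.DataFrame:
        return (self.frame.groupby(["block", "condition"], observed=True)
                .size().unstack(fill_value=0))


def generate_schedule(config: TaskConfig) -> TrialSchedule:
    """Randomized balanced schedule; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.isi_range_ms
    rows = []
    cursor = 0.0
    for block in range(config.n_blocks):
        conds = np.repeat(CONDITIONS, config.trials_per_condition_per_block)
        rng.shuffle(conds)
        for cond in conds:
            cursor += rng.uniform(lo, hi)  # fixation precedes the stimulus
            rows.append((cursor, cond, block))
            cursor += config.stimulus_duration_ms(cond)
    frame = pd.DataFrame(rows, columns=["onset_ms", "condition", "block"])
    return TrialSchedule(frame)


# ---------------------------------------------------------------------------
# EEG signal model


@dataclass
class TemplateSet:
    """Per-channel, per-condition ERP templates and the AV interaction term.

    ``unisensory[cond]`` and ``msi_interaction`` are ``(n_channels,
    n_samples)`` arrays in microvolts, sampled at ``fs`` from stimulus
    onset.  The AV response is A + V + ``msi_gain[group] x msi_interaction``,
    all scaled by ``group_scaling[group]``; ``msi_gain = 0`` makes AV exactly
    the sum of the unisensory templates.
    """

    channels: list[str]
    fs: float
    unisensory: dict[str, np.ndarray]
    msi_interaction: np.ndarray
    group_scaling: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "SCNP": 0.8})
    msi_gain: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "SCNP": 0.3})

    @property
    def n_samples(self) -> int:
        return self.msi_interaction.shape[1]

    def condition_response(self, condition: str, group: str) -> np.ndarray:
        scale = self.group_scaling[group]
        if condition in ("A", "V"):
            return scale * self.unisensory[condition]
        if condition == "AV":
            return scale * (self.unisensory["A"] + self.unisensory["V"]
                            + self.msi_gain[group] * self.msi_interaction)
        raise ConfigError(f"unknown condition {condition!r}")


# Peak amplitudes (uV) of the default components.  The visual component is a
# parieto-occipital positive wave, the auditory component a centro-parietal
# negative wave, both peaking at 120 ms; the interaction is subadditive
# (opposes both clusters) and confined to the 100-140 ms bin.
_V_AMPLITUDES = {"PO7": 6.0, "PO8": 6.0, "P7": 5.0, "P8": 5.0, "POz": 3.0,
                 "Oz": 3.0, "Pz": 1.5, "CPz": 0.5, "Cz": 0.3,
                 "Fp1": 0.1, "Fp2": 0.1}
_A_AMPLITUDES = {"CPz": -6.0, "Cz": -5.5, "Pz": -2.5, "POz": -1.0, "Oz": -0.5,
                 "P7": -0.4, "P8": -0.4, "PO7": -0.3, "PO8": -0.3,
                 "Fp1": -1.0, "Fp2": -1.0}
_MSI_AMPLITUDES = {"P7": -2.0, "P8": -2.0, "PO7": -2.0, "PO8": -2.0,
                   "CPz": 2.0, "Cz": 1.8}


def default_templates(montage: list[str] | None = None, fs: float = 2048.0,
                      duration_ms: float = 300.0, peak_ms: float = 120.0,
                      width_ms: float = 16.0,
                      interaction_window_ms: tuple[float, float] = (100.0, 140.0),
                      interaction_width_ms: float = 8.0) -> TemplateSet:
    """Study-mimicking templates: Gaussian components peaking at 120 ms.

    The interaction term is a Gaussian at the same peak, hard-windowed to
    ``interaction_window_ms`` so the injected MSI is confined to the
    100-140 ms bin used by the topographic selection.
    """
    montage = list(DEFAULT_MONTAGE) if montage is None else list(montage)
    t = np.arange(int(round(duration_ms / 1000.0 * fs))) / fs * 1000.0
    bump = np.exp(-0.5 * ((t - peak_ms) / width_ms) ** 2)
    narrow = np.exp(-0.5 * ((t - peak_ms) / interaction_width_ms) ** 2)
    narrow = narrow * ((t >= interaction_window_ms[0])
                       & (t < interaction_window_ms[1]))

    def build(amps: dict[str, float], shape: np.ndarray) -> np.ndarray:
        return np.array([amps.get(ch, 0.0) * shape for ch in montage])

    return TemplateSet(montage, fs,
                       {"A": build(_A_AMPLITUDES, bump),
                        "V": build(_V_AMPLITUDES, bump)},
                       build(_MSI_AMPLITUDES, narrow))


@dataclass
class NoiseConfig:
    """Background-noise and artifact model (white + 1/f mixture).

    Artifacts are blink-like raised-cosine transients on the frontal-most
    channels, present so the +/-100 uV rejector has something to reject.
    """

    white_sd_uv: float = 15.0
    pink_sd_uv: float = 5.0
    artifact_rate: float = 0.02
    artifact_amplitude_uv: float = 150.0
    seed: int = 1

    def validate(self) -> None:
        if min(self.white_sd_uv, self.pink_sd_uv,
               self.artifact_amplitude_uv) < 0:
            raise ConfigError("noise amplitudes must be >= 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ConfigError("artifact_rate must be in [0, 1]")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sd: float) -> np.ndarray:
    """1/f-amplitude noise, unit-independent channels, scaled to ``sd``."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    f[0] = f[1] if n_samples > 1 else 1.0
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n=n_samples, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    return sd * pink


def simulate_recording(schedule: TrialSchedule, templates: TemplateSet,
                       noise: NoiseConfig, group: str = "control",
                       pad_ms: float = 800.0) -> Recording:
    """Continuous EEG: baseline noise + templates inserted at event onsets.

    Deterministic given ``noise.seed`` (templates and schedule are already
    deterministic).  The recording extends ``pad_ms`` beyond the last onset
    so the final epoch fits.
    """
    noise.validate()
    if group not in templates.group_scaling:
        raise ConfigError(f"unknown group {group!r}")
    fs = templates.fs
    last = schedule.frame["onset_ms"].iloc[-1]
    n_samples = int(round((last + pad_ms) / 1000.0 * fs))
    n_ch = len(templates.channels)

    rng = np.random.default_rng(noise.seed)
    data = rng.normal(0.0, noise.white_sd_uv, (n_ch, n_samples)) \
        if noise.white_sd_uv > 0 else np.zeros((n_ch, n_samples))
    data += _pink_noise(rng, n_ch, n_samples, noise.pink_sd_uv)

    n_t = templates.n_samples
    frontal = [i for i, ch in enumerate(templates.channels)
               if ch.startswith("Fp")] or [0]
    art_len = int(round(0.200 * fs))
    art_shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(art_len) / art_len))

    for onset_ms, cond in zip(schedule.frame["onset_ms"].to_numpy(),
                              schedule.frame["condition"].to_numpy()):
        idx = int(round(onset_ms / 1000.0 * fs))
        stop = min(idx + n_t, n_samples)
        data[:, idx:stop] += templates.condition_response(cond, group)[:, :stop - idx]
        if noise.artifact_rate > 0 and rng.uniform() < noise.artifact_rate:
            a0 = idx + int(rng.integers(0, max(1, n_t - art_len)))
            a1 = min(a0 + art_len, n_samples)
            data[frontal, a0:a1] += noise.artifact_amplitude_uv * art_shape[:a1 - a0]

    return Recording(data, fs, list(templates.channels), schedule)


# ---------------------------------------------------------------------------
# reaction-time model


@dataclass
class RtModelConfig:
    """Race vs. coactivation RT generator.

    ``channel_params[group][channel] = (location_ms, scale_ms)`` are Gaussian
    parameters of the unisensory processing channels.  Under ``race`` the AV
    response is the minimum of two channel draws coupled with correlation
    ``rho`` (statistical facilitation only -- cannot violate the Miller
    bound); under ``coactivation`` the minimum is additionally sped up by
    ``coactivation_gain_ms[group]``, which produces genuine violations.

    ``participant_sd_ms`` shifts a whole participant; ``condition_jitter_sd_ms``
    adds a participant x condition offset.  Both model between-subject
    variability in simple-RT experiments.
    """

    architecture: str = "race"
    channel_params: dict = field(default_factory=lambda: {
        "control": {"A": (310.0, 55.0), "V": (245.0, 50.0)},
        "SCNP": {"A": (340.0, 55.0), "V": (275.0, 50.0)},
    })
    rho: float = 0.2
    coactivation_gain_ms: dict = field(
        default_factory=lambda: {"control": 30.0, "SCNP": 0.0})
    participant_sd_ms: float = 20.0
    condition_jitter_sd_ms: float = 12.0
    min_rt_ms: float = 50.0
    seed: int = 2

    def validate(self) -> None:
        if self.architecture not in ("race", "coactivation"):
            raise ConfigError(
                f"unknown architecture {self.architecture!r}; "
                "expected 'race' or 'coactivation'")
        for group, chans in self.channel_params.items():
            for ch, (loc, scale) in chans.items():
                if loc <= 0 or scale <= 0:
                    raise ConfigError(
                        f"channel_params[{group}][{ch}]: location and scale "
                        "must be positive")
        if not -1 <= self.rho <= 1:
            raise ConfigError("rho must be in [-1, 1]")


def simulate_rts(schedule: TrialSchedule, model: RtModelConfig,
                 group: str = "control", participant: str = "p01",
                 seed: int | None = None) -> pd.DataFrame:
    """One RT per scheduled event for a single participant.

    Returns columns participant, group, condition, rt_ms, block.
    Deterministic given the seed (``model.seed`` unless overridden).
    """
    model.validate()
    if group not in model.channel_params:
        raise ConfigError(f"unknown group {group!r}")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    params = model.channel_params[group]
    loc_a, sc_a = params["A"]
    loc_v, sc_v = params["V"]

    p_off = rng.normal(0.0, model.participant_sd_ms)
    jit = {c: rng.normal(0.0, model.condition_jitter_sd_ms) for c in CONDITIONS}

    conds = schedule.frame["condition"].to_numpy()
    n = len(conds)
    # correlated standard-normal channel pair for every event
    z1 = rng.standard_normal(n)
    z2 = model.rho * z1 + np.sqrt(max(0.0, 1 - model.rho ** 2)) * rng.standard_normal(n)
    draw_a = loc_a + sc_a * z1
    draw_v = loc_v + sc_v * z2

    rt = np.empty(n)
    rt[conds == "A"] = draw_a[conds == "A"]
    rt[conds == "V"] = draw_v[conds == "V"]
    av = np.minimum(draw_a, draw_v)
    if model.architecture == "coactivation":
        av = av - model.coactivation_gain_ms[group]
    rt[conds == "AV"] = av[conds == "AV"]

    rt += p_off + np.vectorize(jit.__getitem__)(conds)
    rt = np.maximum(rt, model.min_rt_ms)

    return pd.DataFrame({
        "participant": participant,
        "group": group,
        "condition": conds,
        "rt_ms": rt,
        "block": schedule.frame["block"].to_numpy(),
    })


def simulate_rt_study(n_per_group: int = 12,
                      task: TaskConfig | None = None,
                      model: RtModelConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Full two-group RT study: one schedule + RT table per participant."""
    task = task or TaskConfig()
    model = model or RtModelConfig()
    ss = np.random.SeedSequence(seed)
    tables = []
    i = 0
    for group in GROUPS:
        for k in range(n_per_group):
            child = ss.spawn(1)[0]
            sched_seed, rt_seed = child.generate_state(2) >> 1  # keep < 2^31
            cfg = TaskConfig(**{**task.__dict__, "seed": int(sched_seed)})
            sched = generate_schedule(cfg)
            tables.append(simulate_rts(sched, model, group,
                                       participant=f"{group[:3]}{k:02d}",
                                       seed=int(rt_seed)))
            i += 1
    return pd.concat(tables, ignore_index=True)
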