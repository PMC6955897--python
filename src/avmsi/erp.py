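"""ERP preprocessing and the additive-model (SUM vs. multisensory) waveforms.

The analysis chain is the classic one for audiovisual interaction studies:
band-pass filter the continuous recording, cut stimulus-locked 600 ms epochs
(100 ms pre- to 500 ms post-onset), reject epochs exceeding +/-100 uV,
average per condition, and form the SUM waveform as the pointwise sum of the
auditory-only and visual-only averages.  Under superposition of electrical
fields, SUM equals the audiovisual (AV) response unless the two inputs
interacted -- any SUM-vs-AV divergence is the multisensory-integration
signal quantified downstream.

Every step here is linear (filtering, slicing, averaging, sum, mean
amplitude), so the SUM-vs-AV contrast commutes with the pipeline; the test
suite asserts this numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "EpochSet",
    "ERPWaveform",
    "ClusterSelection",
    "bandpass_filter",
    "make_epochs",
    "reject_artifacts",
    "average_condition",
    "sum_waveform",
    "grand_average",
    "topographic_extrema",
    "mean_amplitude",
]

#: Epoch window used throughout: 100 ms pre-stimulus to 500 ms post-stimulus.
DEFAULT_WINDOW_MS = (-100.0, 500.0)


class PipelineError(RuntimeError):
    """A stage of the ERP pipeline cannot proceed (empty condition, flat map...)."""


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        10/20-extended channel names, unique, one per row of ``data``.
    events
        The :class:`~avmsi.synthdata.TrialSchedule` that produced / annotates
        this recording (may be ``None`` for raw imports).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: object | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0


@dataclass
class EpochSet:
    """Stimulus-locked epochs plus rejection bookkeeping.

    ``epochs`` is ``(n_trials, n_channels, n_samples)``; ``times_ms`` gives
    the latency of each sample relative to stimulus onset.  ``rejected``
    marks epochs excluded from all averages; ``dropped_events`` counts
    scheduled events that never became epochs (too close to a recording
    edge), so kept + rejected + dropped always equals the number of
    scheduled events.
    """

    epochs: np.ndarray
    times_ms: np.ndarray
    conditions: np.ndarray
    fs: float
    channel_labels: list[str]
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    rejection_reason: list[str] = field(default_factory=list)
    dropped_events: int = 0
    rejection_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.conditions), dtype=bool)
        self.conditions = np.asarray(self.conditions)

    @property
    def n_kept(self) -> int:
        return int((~self.rejected).sum())

    def kept(self, condition: str | None = None) -> np.ndarray:
        mask = ~self.rejected
        if condition is not None:
            mask &= self.conditions == condition
        return self.epochs[mask]


@dataclass
class ERPWaveform:
    """A per-condition average (or the derived SUM = A + V waveform)."""

    role: str  # one of {"A", "V", "AV", "SUM"}
    data: np.ndarray  # (n_channels, n_samples), microvolts
    times_ms: np.ndarray
    channel_labels: list[str]
    n_trials_averaged: int
    level: str = "participant"  # or "grand"


@dataclass
class ClusterSelection:
    """Electrode clusters and time bin picked by the topographic scan."""

    positive_electrodes: list[str]
    negative_electrodes: list[str]
    time_bin_ms: tuple[float, float]


# ---------------------------------------------------------------------------
# filtering


def _design_bandpass(fs: float, hp_hz: float, lp_hz: float,
                     hp_slope_db_oct: float, lp_slope_db_oct: float):
    """Butterworth sections for the high- and low-pass stages.

    Slopes map to orders at 6 dB/octave per pole; because both stages are
    applied forward and backward (zero phase), the designed order is halved
    so the *two-pass* roll-off matches the nominal slope.  The nominal
    cutoff is the single-pass -3 dB point (-6 dB after two passes).
    """
    nyq = fs / 2.0
    if lp_hz >= nyq:
        raise ValueError(f"low-pass cutoff {lp_hz} Hz >= Nyquist {nyq} Hz")
    if hp_hz <= 0 or hp_hz >= lp_hz:
        raise ValueError("require 0 < hp_hz < lp_hz")
    hp_order = max(1, int(round(hp_slope_db_oct / 6.0 / 2.0)))
    lp_order = max(1, int(round(lp_slope_db_oct / 6.0 / 2.0)))
    sos_hp = sps.butter(hp_order, hp_hz, btype="highpass", fs=fs, output="sos")
    sos_lp = sps.butter(lp_order, lp_hz, btype="lowpass", fs=fs, output="sos")
    return sos_hp, sos_lp


def bandpass_filter(rec: Recording, hp_hz: float = 1.6, lp_hz: float = 45.0,
                    hp_slope_db_oct: float = 12.0,
                    lp_slope_db_oct: float = 24.0) -> Recording:
    """Zero-phase band-pass (default 1.6-45 Hz at 12/24 dB-octave slopes).

    Returns a new :class:`Recording`; the input is not modified.
    """
    sos_hp, sos_lp = _design_bandpass(rec.fs, hp_hz, lp_hz,
                                      hp_slope_db_oct, lp_slope_db_oct)
    out = sps.sosfiltfilt(sos_hp, rec.data, axis=1)
    out = sps.sosfiltfilt(sos_lp, out, axis=1)
    return Recording(out, rec.fs, list(rec.channel_labels), rec.events)


def filter_response(fs: float, freqs_hz, hp_hz: float = 1.6, lp_hz: float = 45.0,
                    hp_slope_db_oct: float = 12.0, lp_slope_db_oct: float = 24.0,
                    two_pass: bool = False) -> np.ndarray:
    """Magnitude response of the designed band-pass at ``freqs_hz``.

    ``two_pass=True`` squares the magnitude, matching the zero-phase
    forward-backward application used by :func:`bandpass_filter`.
    """
    sos_hp, sos_lp = _design_bandpass(fs, hp_hz, lp_hz,
                                      hp_slope_db_oct, lp_slope_db_oct)
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    _, h_hp = sps.sosfreqz(sos_hp, worN=freqs_hz, fs=fs)
    _, h_lp = sps.sosfreqz(sos_lp, worN=freqs_hz, fs=fs)
    mag = np.abs(h_hp * h_lp)
    return mag ** 2 if two_pass else mag


# ---------------------------------------------------------------------------
# epoching


def window_samples(fs: float, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
                   ) -> tuple[int, int]:
    """(pre, post) sample counts for the epoch window.

    Convention: the epoch covers samples ``onset - pre .. onset + post - 1``
    inclusive, with ``pre = round(|pre_ms|/1000 * fs)`` and
    ``post = round(post_ms/1000 * fs)``; at 2048 Hz and the default
    (-100, +500) ms window this is 205 + 1024 = 1229 samples.
    """
    pre = int(round(abs(window_ms[0]) / 1000.0 * fs))
    post = int(round(window_ms[1] / 1000.0 * fs))
    return pre, post


def make_epochs(rec: Recording, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
                baseline: bool = True) -> EpochSet:
    """Cut one epoch per scheduled event, baseline-corrected by default.

    Baseline correction subtracts the mean of the pre-stimulus segment
    (window start to 0 ms) per channel.  Events with insufficient data on
    either side are dropped with a warning and counted in
    ``dropped_events``.
    """
    if rec.events is None:
        raise ValueError("recording carries no event schedule")
    pre, post = window_samples(rec.fs, window_ms)
    n_total = pre + post
    times_ms = np.arange(-pre, post) / rec.fs * 1000.0

    ev = rec.events.frame
    epochs, conditions = [], []
    dropped = 0
    for onset_ms, cond in zip(ev["onset_ms"].to_numpy(),
                              ev["condition"].to_numpy()):
        idx = int(round(onset_ms / 1000.0 * rec.fs))
        if idx - pre < 0 or idx + post > rec.n_samples:
            dropped += 1
            warnings.warn(
                f"event at {onset_ms:.1f} ms too close to recording edge; "
                "epoch dropped", stacklevel=2)
            continue
        ep = rec.data[:, idx - pre: idx + post].copy()
        if baseline and pre > 0:
            ep -= ep[:, :pre].mean(axis=1, keepdims=True)
        epochs.append(ep)
        conditions.append(cond)

    if not epochs:
        raise PipelineError("no epochs could be extracted")
    arr = np.stack(epochs)
    assert arr.shape[2] == n_total
    return EpochSet(arr, times_ms, np.array(conditions), rec.fs,
                    list(rec.channel_labels), window_ms,
                    dropped_events=dropped)


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Flag epochs whose absolute amplitude exceeds the threshold anywhere.

    The comparison is strict (``|x| > threshold``): +/-100 uV is read as the
    allowed range, so a sample exactly at 100 uV survives.  Raises if every
    epoch of a condition is rejected, since averaging then is impossible.
    """
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    bad = peak > threshold_uv
    rejected = epochs.rejected | bad
    log: dict[str, dict[str, int]] = {}
    for cond in np.unique(epochs.conditions):
        mask = epochs.conditions == cond
        n_rej = int((rejected & mask).sum())
        log[str(cond)] = {"total": int(mask.sum()), "rejected": n_rej}
        if n_rej == int(mask.sum()):
            raise PipelineError(
                f"all {int(mask.sum())} epochs of condition {cond!r} exceed "
                f"+/-{threshold_uv} uV; averaging impossible")
    reasons = [f"peak {p:.1f} uV > {threshold_uv} uV" if b else ""
               for p, b in zip(peak, bad)]
    return EpochSet(epochs.epochs, epochs.times_ms, epochs.conditions,
                    epochs.fs, epochs.channel_labels, epochs.window_ms,
                    rejected=rejected, rejection_reason=reasons,
                    dropped_events=epochs.dropped_events, rejection_log=log)


# ---------------------------------------------------------------------------
# averaging and the additive model


def average_condition(epochs: EpochSet,
                      conditions: tuple[str, ...] = ("A", "V", "AV")
                      ) -> dict[str, ERPWaveform]:
    """Arithmetic mean of kept epochs, per condition."""
    out = {}
    for cond in conditions:
        kept = epochs.kept(cond)
        if kept.shape[0] == 0:
            raise PipelineError(f"condition {cond!r} has no kept epochs")
        out[cond] = ERPWaveform(cond, kept.mean(axis=0), epochs.times_ms,
                                list(epochs.channel_labels), kept.shape[0])
    return out


def sum_waveform(a: ERPWaveform, v: ERPWaveform) -> ERPWaveform:
    """SUM = auditory average + visual average, pointwise and exact."""
    if a.channel_labels != v.channel_labels:
        raise ValueError("A and V waveforms have different montages")
    if a.data.shape != v.data.shape:
        raise ValueError("A and V waveforms have different shapes")
    return ERPWaveform("SUM", a.data + v.data, a.times_ms,
                       list(a.channel_labels),
                       min(a.n_trials_averaged, v.n_trials_averaged), a.level)


def grand_average(waveforms: list[ERPWaveform]) -> ERPWaveform:
    """Unweighted mean of participant-level waveforms."""
    if not waveforms:
        raise ValueError("no waveforms to average")
    ref = waveforms[0]
    for w in waveforms[1:]:
        if w.channel_labels != ref.channel_labels or w.data.shape != ref.data.shape:
            raise ValueError("waveforms are not alignable")
        if w.role != ref.role:
            raise ValueError("cannot grand-average mixed roles")
    data = np.mean([w.data for w in waveforms], axis=0)
    return ERPWaveform(ref.role, data, ref.times_ms, list(ref.channel_labels),
                       len(waveforms), level="grand")


# ---------------------------------------------------------------------------
# topographic selection and amplitude extraction


def topographic_extrema(grand: ERPWaveform,
                        search_window_ms: tuple[float, float] = (0.0, 200.0),
                        bin_width_ms: float = 40.0,
                        grid_ms: float = 10.0,
                        n_positive: int = 4,
                        n_negative: int = 2,
                        flat_tol_uv: float = 1e-9) -> ClusterSelection:
    """Find the time bin and electrodes of greatest positive/negative voltage.

    Mirrors a voltage-map inspection: candidate bins of ``bin_width_ms``
    slide over the search window on a ``grid_ms`` grid; the winning bin
    maximizes (strongest positive channel mean + strongest negative channel
    magnitude) of the multisensory grand average.  Within that bin the top
    ``n_positive`` channels with positive mean and top ``n_negative`` with
    negative mean form the clusters.  Pass the AV grand average.
    """
    t = grand.times_ms
    starts = np.arange(search_window_ms[0],
                       search_window_ms[1] - bin_width_ms + 1e-9, grid_ms)
    if len(starts) == 0:
        raise ValueError("search window shorter than bin width")

    best, best_score = None, -np.inf
    for s in starts:
        mask = (t >= s) & (t < s + bin_width_ms)
        if not mask.any():
            continue
        ch_means = grand.data[:, mask].mean(axis=1)
        score = max(ch_means.max(), 0.0) + max(-ch_means.min(), 0.0)
        if score > best_score:
            best_score, best = score, (s, ch_means)
    if best is None or best_score < flat_tol_uv:
        raise PipelineError("flat signal: no topographic extremum found")

    s, ch_means = best
    order = np.argsort(ch_means)
    labels = grand.channel_labels
    pos = [labels[i] for i in order[::-1][:n_positive] if ch_means[i] > 0]
    neg = [labels[i] for i in order[:n_negative] if ch_means[i] < 0]
    if not pos and not neg:
        raise PipelineError("flat signal: no positive or negative cluster")
    return ClusterSelection(pos, neg, (float(s), float(s + bin_width_ms)))


def mean_amplitude(erp: ERPWaveform, channels: list[str],
                   time_bin_ms: tuple[float, float]) -> float:
    """Mean voltage over the given channels and time bin, in microvolts.

    The bin is half-open ``[start, end)`` in ms relative to stimulus onset.
    """
    missing = [c for c in channels if c not in erp.channel_labels]
    if missing:
        raise ValueError(f"electrodes not in montage: {missing}")
    rows = [erp.channel_labels.index(c) for c in channels]
    mask = (erp.times_ms >= time_bin_ms[0]) & (erp.times_ms < time_bin_ms[1])
    if not mask.any():
        raise ValueError(f"time bin {time_bin_ms} outside epoch window")
    return float(erp.data[np.ix_(rows, np.flatnonzero(mask))].mean())
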