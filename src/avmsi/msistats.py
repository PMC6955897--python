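"""SUM-vs-multisensory amplitude statistics (additive-model ANOVAs).

Two complementary quantifications of audiovisual integration on cluster
mean amplitudes:

* **Method 1** -- a 2 GROUP (control, SCNP) x 2 SIGNAL (SUM, MSI) mixed
  ANOVA on the mean amplitude in one topographically selected time bin
  (100-140 ms in the reference analysis).  A SIGNAL main effect or a
  GROUP x SIGNAL interaction indicates that the audiovisual response
  departs from the unisensory sum, i.e. integration.
* **Method 2** -- the same ANOVA repeated over fixed 20 ms bins from 60 to
  180 ms (six bins), localizing the divergence in time.

"MSI" names the multisensory (AV) waveform, mirroring the SIGNAL factor
labels in the source analyses.  A label-permutation null for the SIGNAL
effect is provided for users who prefer a resampled reference distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import AnovaResult, mixed_anova
from .erp import ClusterSelection, ERPWaveform, mean_amplitude

__all__ = [
    "amplitude_table",
    "method1",
    "method2_timecourse",
    "method1_permutation",
    "METHOD2_BINS",
]

#: Fixed Method-2 bins: 60-80, 80-100, ..., 160-180 ms.
METHOD2_BINS = [(float(s), float(s + 20)) for s in range(60, 180, 20)]

SIGNALS = ("SUM", "MSI")


def amplitude_table(participant_waveforms: dict[str, dict[str, ERPWaveform]],
                    groups: dict[str, str],
                    cluster: ClusterSelection,
                    bins: list[tuple[float, float]] | None = None
                    ) -> pd.DataFrame:
    """Tidy table of cluster mean amplitudes per participant/signal/bin.

    ``participant_waveforms[pid]`` holds the participant's ``"SUM"`` and
    ``"AV"`` waveforms; ``groups[pid]`` the group label.  One row per
    participant x signal x polarity x bin with columns participant, group,
    signal (SUM/MSI), polarity, bin_start_ms, bin_end_ms,
    mean_amplitude_uv.
    """
    bins = bins or [cluster.time_bin_ms]
    clusters = [("positive", cluster.positive_electrodes),
                ("negative", cluster.negative_electrodes)]
    rows = []
    for pid, wfs in participant_waveforms.items():
        for polarity, electrodes in clusters:
            if not electrodes:
                continue
            for b in bins:
                for signal, role in (("SUM", "SUM"), ("MSI", "AV")):
                    rows.append({
                        "participant": pid,
                        "group": groups[pid],
                        "signal": signal,
                        "polarity": polarity,
                        "bin_start_ms": b[0],
                        "bin_end_ms": b[1],
                        "mean_amplitude_uv": mean_amplitude(
                            wfs[role], electrodes, b),
                    })
    return pd.DataFrame(rows)


def _select(table: pd.DataFrame, bin_ms: tuple[float, float],
            polarity: str) -> pd.DataFrame:
    sel = table[(table["polarity"] == polarity)
                & np.isclose(table["bin_start_ms"], bin_ms[0])
                & np.isclose(table["bin_end_ms"], bin_ms[1])]
    if sel.empty:
        raise ValueError(f"no rows for bin {bin_ms} / polarity {polarity!r}")
    counts = sel.groupby("participant", observed=True)["signal"].nunique()
    if (counts != 2).any():
        raise ValueError("need exactly one SUM and one MSI row per participant")
    return sel


def method1(table: pd.DataFrame, bin_ms: tuple[float, float],
            polarity: str = "positive") -> list[AnovaResult]:
    """2 GROUP x 2 SIGNAL mixed ANOVA on one cluster and time bin.

    Returns the GROUP, SIGNAL and GROUP x SIGNAL effects; with n subjects
    all dfs are (1, n - 2).  A significant SIGNAL effect or interaction is
    the integration evidence under the superposition principle.
    """
    sel = _select(table, bin_ms, polarity)
    return mixed_anova(sel, dv="mean_amplitude_uv", within="signal",
                       between="group", subject="participant")


def method2_timecourse(table: pd.DataFrame, polarity: str = "positive",
                       bins: list[tuple[float, float]] | None = None,
                       alpha: float = 0.05, holm: bool = False
                       ) -> pd.DataFrame:
    """Method-1 ANOVA repeated over the fixed 20 ms bins (60-180 ms).

    Returns a tidy frame with one row per bin x effect.  ``holm=True``
    applies a Holm step-down correction across the bin x effect family
    (off by default, matching per-bin reporting).
    Raises if any of the six bins is missing from the table.
    """
    bins = bins or METHOD2_BINS
    rows = []
    for b in bins:
        for res in method1(table, b, polarity):
            d = res.as_dict()
            d.update(bin_start_ms=b[0], bin_end_ms=b[1], polarity=polarity)
            rows.append(d)
    out = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p"], method="holm")[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def method1_permutation(table: pd.DataFrame, bin_ms: tuple[float, float],
                        polarity: str = "positive", n_permutations: int = 1000,
                        seed: int = 0) -> dict:
    """Permutation p-value for the SIGNAL effect (label shuffling).

    SUM/MSI labels are flipped independently within each participant; the
    proportion of permuted F values >= the observed F estimates the null
    probability without distributional assumptions.
    """
    sel = _select(table, bin_ms, polarity).copy()
    observed = next(r for r in method1(table, bin_ms, polarity)
                    if r.effect == "signal")
    rng = np.random.default_rng(seed)
    pivot = sel.pivot_table(index=["participant", "group"], columns="signal",
                            values="mean_amplitude_uv", observed=True)
    count = 0
    for _ in range(n_permutations):
        flip = rng.integers(0, 2, size=len(pivot)).astype(bool)
        perm = pivot.copy()
        perm.loc[flip, ["SUM", "MSI"]] = perm.loc[flip, ["MSI", "SUM"]].to_numpy()
        long = perm.reset_index().melt(id_vars=["participant", "group"],
                                       value_vars=["SUM", "MSI"],
                                       var_name="signal", value_name="amp")
        f_perm = next(r for r in mixed_anova(
            long, dv="amp", within="signal", between="group",
            subject="participant") if r.effect == "signal").F
        if f_perm >= observed.F:
            count += 1
    return {"effect": "signal", "F": observed.F,
            "p_permutation": (count + 1) / (n_permutations + 1),
            "n_permutations": n_permutations}
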