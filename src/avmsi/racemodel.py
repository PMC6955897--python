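"""Race-model inequality (Miller bound) testing on reaction-time quantiles.

For a redundant-target experiment the race model predicts that the
audiovisual CDF can never exceed the joint probability of the unisensory
channels:

    F_AV(t) <= min(1, F_A(t) + F_V(t))        (Miller's bound)

A multisensory CDF lying *left* of that bound (faster latencies at matched
probabilities) cannot arise from statistical facilitation alone and is taken
as evidence of neural coactivation.

Per participant, empirical CDFs of the kept A, V and AV reaction times are
summarized as latencies at a fixed probability grid (10% quantiles by
default), the bound is computed from that participant's own A and V
distributions, and paired t-tests compare the AV latency with the bound
latency -- but only at the quantiles where the group-mean AV CDF is faster
than the bound, reproducing the published select-then-test procedure.

Quantile convention: order statistics x_(i) carry plotting positions
p_i = (i - 0.5)/n; latencies at other probabilities are linearly
interpolated, clamped to x_(1) / x_(n) outside the range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CdfSet",
    "ViolationTest",
    "quantile_latencies",
    "cdf_values",
    "miller_bound",
    "bound_latencies",
    "estimate_cdfs",
    "test_violations",
    "grice_bound",
    "plot_cdfs",
]

DEFAULT_PROBABILITIES = np.arange(1, 11) / 10.0


@dataclass
class CdfSet:
    """Per-participant quantile latencies for A, V, AV and the Miller bound."""

    participant: str
    probabilities: np.ndarray
    latencies: dict[str, np.ndarray]  # condition -> latency (ms) at each p
    bound: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if not (np.all(np.diff(p) > 0) and p[0] > 0 and p[-1] <= 1):
            raise ValueError("probabilities must be strictly increasing in (0, 1]")
        self.probabilities = p


@dataclass
class ViolationTest:
    """Paired t-test of AV vs. bound latency at one quantile."""

    quantile_index: int       # 1-based, matching '6th, 7th percent quantiles'
    probability: float
    mean_difference_ms: float  # mean(AV - bound); negative = AV faster
    t: float
    df: int
    p: float
    tested: bool


# ---------------------------------------------------------------------------
# empirical CDF machinery


def _order_and_positions(rts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(np.asarray(rts, dtype=float), kind="stable")
    n = len(x)
    return x, (np.arange(1, n + 1) - 0.5) / n


def quantile_latencies(rts: np.ndarray, probabilities: np.ndarray) -> np.ndarray:
    """Latency at each probability under the (i-0.5)/n plotting convention."""
    x, pos = _order_and_positions(rts)
    if len(x) == 0:
        raise ValueError("empty RT sample")
    return np.interp(probabilities, pos, x, left=x[0], right=x[-1])


def cdf_values(rts: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Empirical CDF evaluated at latencies ``t`` (same convention, inverse)."""
    x, pos = _order_and_positions(rts)
    return np.interp(t, x, pos, left=0.0, right=1.0)


def miller_bound(f_a: np.ndarray, f_v: np.ndarray) -> np.ndarray:
    """min(1, F_A + F_V) on a common latency grid."""
    f_a, f_v = np.asarray(f_a, dtype=float), np.asarray(f_v, dtype=float)
    if f_a.shape != f_v.shape:
        raise ValueError("CDFs must share a common latency grid")
    return np.minimum(1.0, f_a + f_v)


def grice_bound(f_a: np.ndarray, f_v: np.ndarray) -> np.ndarray:
    """max(F_A, F_V): the lower bound implied by any race architecture."""
    f_a, f_v = np.asarray(f_a, dtype=float), np.asarray(f_v, dtype=float)
    if f_a.shape != f_v.shape:
        raise ValueError("CDFs must share a common latency grid")
    return np.maximum(f_a, f_v)


def bound_latencies(rts_a: np.ndarray, rts_v: np.ndarray,
                    probabilities: np.ndarray) -> np.ndarray:
    """Latency at which the Miller bound reaches each probability.

    The bound B(t) = min(1, F_A(t) + F_V(t)) is evaluated on the pooled
    latency grid of both unisensory samples and inverted by linear
    interpolation (first attainment at plateaus).
    """
    grid = np.unique(np.concatenate([rts_a, rts_v]).astype(float))
    b = miller_bound(cdf_values(rts_a, grid), cdf_values(rts_v, grid))
    out = np.empty(len(probabilities))
    for i, p in enumerate(np.asarray(probabilities, dtype=float)):
        j = np.searchsorted(b, p, side="left")
        if j == 0:
            out[i] = grid[0]
        elif j >= len(grid):
            out[i] = grid[-1]
        elif b[j] == b[j - 1]:
            out[i] = grid[j]
        else:
            out[i] = grid[j - 1] + (p - b[j - 1]) / (b[j] - b[j - 1]) \
                * (grid[j] - grid[j - 1])
    return out


# ---------------------------------------------------------------------------
# per-participant estimation and group tests


def estimate_cdfs(rts: pd.DataFrame,
                  probabilities: np.ndarray | None = None,
                  conditions: tuple[str, ...] = ("A", "V", "AV")
                  ) -> list[CdfSet]:
    """Quantile latencies and the Miller bound for every participant.

    ``rts`` uses the trial-table dialect (participant, condition, rt_ms,
    optional ``kept`` flag -- only kept trials are used).  Deterministic.
    """
    p = DEFAULT_PROBABILITIES if probabilities is None else np.asarray(probabilities)
    t = rts[rts["kept"]] if "kept" in rts.columns else rts
    out = []
    for part, sub in t.groupby("participant", observed=True, sort=True):
        lats = {}
        samples = {}
        for cond in conditions:
            vals = sub.loc[sub["condition"] == cond, "rt_ms"].to_numpy(float)
            if len(vals) == 0:
                raise ValueError(
                    f"participant {part!r} has no kept {cond!r} trials")
            samples[cond] = vals
            lats[cond] = quantile_latencies(vals, p)
        bound = bound_latencies(samples["A"], samples["V"], p)
        out.append(CdfSet(str(part), p, lats, bound))
    return out


def test_violations(cdfs: list[CdfSet], av: str = "AV",
                    ) -> list[ViolationTest]:
    """Select-then-test Miller-bound violations for one group of participants.

    A quantile qualifies for testing when the group-mean AV latency is
    faster (smaller) than the group-mean bound latency; there a paired
    t-test compares per-participant AV vs. bound latencies (df = n - 1, t
    negative when AV is faster).  Unqualified quantiles are reported with
    ``tested=False``.
    """
    n = len(cdfs)
    if n < 2:
        raise ValueError("need >= 2 participants per group")
    p = cdfs[0].probabilities
    av_lat = np.array([c.latencies[av] for c in cdfs])      # (n, k)
    bd_lat = np.array([c.bound for c in cdfs])
    results = []
    for k in range(len(p)):
        diff = av_lat[:, k] - bd_lat[:, k]
        tested = diff.mean() < 0
        if tested:
            t_stat, p_val = stats.ttest_rel(av_lat[:, k], bd_lat[:, k])
            results.append(ViolationTest(k + 1, float(p[k]),
                                         float(diff.mean()), float(t_stat),
                                         n - 1, float(p_val), True))
        else:
            results.append(ViolationTest(k + 1, float(p[k]),
                                         float(diff.mean()), float("nan"),
                                         n - 1, float("nan"), False))
    return results


def violations_frame(results: list[ViolationTest]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def plot_cdfs(cdfs: list[CdfSet], ax=None, label_prefix: str = ""):
    """Group-mean A, V, AV and bound curves (probability vs. latency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    p = cdfs[0].probabilities
    for cond, style in (("A", ":"), ("V", "--"), ("AV", "-")):
        mean_lat = np.mean([c.latencies[cond] for c in cdfs], axis=0)
        ax.plot(mean_lat, p, style, label=f"{label_prefix}{cond}")
    ax.plot(np.mean([c.bound for c in cdfs], axis=0), p, "-k",
            label=f"{label_prefix}race bound")
    ax.set_xlabel("latency (ms)")
    ax.set_ylabel("cumulative probability")
    ax.legend()
    return ax
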