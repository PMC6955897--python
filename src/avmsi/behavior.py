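"""Reaction-time cleaning and the 2 GROUP x 3 CONDITION mixed ANOVA.

RTs are filtered to within +/- k standard deviations (default k = 2) of each
participant's mean for each condition, then averaged to one cell mean per
participant x condition.  Group differences are tested with a split-plot
(mixed) ANOVA -- group as the between-subject factor, stimulus condition as
the repeated measure -- and condition means are compared pairwise with
Tukey's HSD using the repeated-measures error term.

Effect sizes are partial eta squared; for any effect with a single error
term it satisfies the identity eta2p = F*df1 / (F*df1 + df2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "DegenerateDesignError",
    "filter_rts",
    "cell_means",
    "mixed_anova",
    "eta_sq_from_f",
    "tukey_hsd",
]


class DegenerateDesignError(ValueError):
    """The response has zero variance everywhere; no F ratio is defined."""


@dataclass
class AnovaResult:
    """One effect row: F, degrees of freedom, p, partial eta squared."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float

    def as_dict(self) -> dict:
        return {"effect": self.effect, "F": self.F, "df1": self.df1,
                "df2": self.df2, "p": self.p,
                "partial_eta_sq": self.partial_eta_sq}


def eta_sq_from_f(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from F and its degrees of freedom.

    eta2p = F*df1 / (F*df1 + df2), exact for single-error-term effects.
    """
    if F < 0:
        raise ValueError("F must be >= 0")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


# ---------------------------------------------------------------------------
# RT filtering


def filter_rts(table: pd.DataFrame, k_sd: float = 2.0,
               rt_col: str = "rt_ms") -> pd.DataFrame:
    """Flag RTs outside mean +/- k_sd * SD of their participant x condition cell.

    Statistics are computed on each cell's raw RTs (SD with ddof=1).  Rows
    get a boolean ``kept`` column; nothing is deleted.  A per-cell rejection
    log is attached as ``result.attrs["rejection_log"]``.  Cells with fewer
    than 2 trials are passed through unfiltered with a warning.  The filter
    is applied exactly once per pipeline run: re-filtering the kept subset
    would recompute the statistics and could trim further.
    """
    if table.empty:
        raise ValueError("RT table is empty")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    out = table.copy()
    kept = np.ones(len(out), dtype=bool)
    log = []
    for (part, cond), idx in out.groupby(
            ["participant", "condition"], observed=True).groups.items():
        vals = out.loc[idx, rt_col].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(
                f"cell ({part}, {cond}) has {len(vals)} trial(s); "
                "passed through unfiltered", stacklevel=2)
            log.append((part, cond, len(vals), 0))
            continue
        m, sd = vals.mean(), vals.std(ddof=1)
        ok = np.abs(vals - m) <= k_sd * sd
        kept[out.index.get_indexer(idx)] = ok
        log.append((part, cond, len(vals), int((~ok).sum())))
    out["kept"] = kept
    out.attrs["rejection_log"] = pd.DataFrame(
        log, columns=["participant", "condition", "n_trials", "n_rejected"])
    return out


def cell_means(table: pd.DataFrame, rt_col: str = "rt_ms") -> pd.DataFrame:
    """One mean per participant x condition (kept trials only, if flagged)."""
    t = table[table["kept"]] if "kept" in table.columns else table
    out = (t.groupby(["participant", "group", "condition"], observed=True)
           [rt_col].mean().reset_index())
    return out.rename(columns={rt_col: "value"})


# ---------------------------------------------------------------------------
# split-plot ANOVA


def mixed_anova(data: pd.DataFrame, dv: str = "value",
                within: str = "condition", between: str = "group",
                subject: str = "participant",
                gg_correction: bool = False) -> list[AnovaResult]:
    """2-factor mixed ANOVA (between-subject x repeated measure).

    Expects one value per subject x within-level (aggregate first, e.g. with
    :func:`cell_means`).  Uses the classic split-plot sums-of-squares
    decomposition: the between factor is tested against subjects-within-
    groups, the within factor and the interaction against the
    subject x within residual.  ``gg_correction`` applies Greenhouse-Geisser
    epsilon to the within-effect p-values (dfs are reported uncorrected);
    off by default, matching common uncorrected reporting.
    """
    pivot = data.pivot_table(index=[subject, between], columns=within,
                             values=dv, observed=True)
    if pivot.isna().any().any():
        raise ValueError("design incomplete: every subject needs every "
                         f"{within} level")
    y = pivot.to_numpy(dtype=float)          # (n_subjects, b)
    groups = pivot.index.get_level_values(between).to_numpy()
    levels = np.unique(groups)
    n_subj, b = y.shape
    a = len(levels)
    if a < 2:
        raise ValueError(f"between factor {between!r} needs >= 2 levels")
    if b < 2:
        raise ValueError(f"within factor {within!r} needs >= 2 levels")

    grand = y.mean()
    if np.allclose(y, grand):
        raise DegenerateDesignError(
            "response is constant; zero variance in every cell")

    subj_means = y.mean(axis=1)
    within_means = y.mean(axis=0)
    n_g = np.array([(groups == g).sum() for g in levels])
    group_means = np.array([y[groups == g].mean() for g in levels])
    cellm = np.array([y[groups == g].mean(axis=0) for g in levels])  # (a, b)

    ss_total = ((y - grand) ** 2).sum()
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_group = b * (n_g * (group_means - grand) ** 2).sum()
    ss_subj_err = ss_between_subj - ss_group
    ss_within = n_subj * ((within_means - grand) ** 2).sum()
    inter = cellm - group_means[:, None] - within_means[None, :] + grand
    ss_inter = (n_g[:, None] * inter ** 2).sum()
    ss_err_w = ss_total - ss_between_subj - ss_within - ss_inter

    df_group, df_subj = a - 1, n_subj - a
    df_within = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err_w = (n_subj - a) * (b - 1)

    eps = _gg_epsilon(y) if gg_correction else 1.0

    def effect(name, ss_eff, df1, ss_err, df2, gg=False):
        ms_err = ss_err / df2
        if ms_err <= 0:
            if ss_eff <= 1e-12:
                return AnovaResult(name, 0.0, df1, df2, 1.0, 0.0)
            raise DegenerateDesignError(
                f"zero error variance for effect {name!r} with nonzero "
                "effect sum of squares")
        F = (ss_eff / df1) / ms_err
        e = eps if gg else 1.0
        p = float(stats.f.sf(F, df1 * e, df2 * e))
        return AnovaResult(name, float(F), df1, df2, p,
                           eta_sq_from_f(F, df1, df2))

    return [
        effect(between, ss_group, df_group, ss_subj_err, df_subj),
        effect(within, ss_within, df_within, ss_err_w, df_err_w, gg=True),
        effect(f"{between} * {within}", ss_inter, df_inter, ss_err_w,
               df_err_w, gg=True),
    ]


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance."""
    b = y.shape[1]
    S = np.cov(y, rowvar=False)
    mean_diag = np.trace(S) / b
    num = (b * (mean_diag - S.mean())) ** 2
    den = (b - 1) * ((S ** 2).sum() - 2 * b * (S.mean(axis=0) ** 2).sum()
                     + b ** 2 * S.mean() ** 2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (b - 1), 1.0))


# ---------------------------------------------------------------------------
# Tukey HSD with the repeated-measures error term


def tukey_hsd(data: pd.DataFrame, dv: str = "value", within: str = "condition",
              subject: str = "participant", alpha: float = 0.05,
              ms_error: float | None = None,
              df_error: int | None = None) -> pd.DataFrame:
    """All pairwise within-level comparisons, studentized-range adjusted.

    Operates on per-subject level means (one value per subject x level).
    The error term defaults to the subject x level residual of a one-way
    repeated-measures ANOVA on the same data -- the error against which the
    within effect was tested -- but an explicit (``ms_error``, ``df_error``)
    pair from a larger design may be supplied.
    """
    pivot = data.pivot_table(index=subject, columns=within, values=dv,
                             observed=True)
    if pivot.shape[1] < 2:
        raise ValueError("need >= 2 levels for pairwise comparisons")
    y = pivot.to_numpy(dtype=float)
    n, k = y.shape
    if ms_error is None or df_error is None:
        resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0) + y.mean()
        df_error = (n - 1) * (k - 1)
        ms_error = float((resid ** 2).sum() / df_error)
    level_means = y.mean(axis=0)
    se = np.sqrt(ms_error / n)
    rows = []
    labels = list(pivot.columns)
    for i in range(k):
        for j in range(i + 1, k):
            diff = level_means[i] - level_means[j]
            if se == 0:
                q, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_error))
            rows.append({"level_1": labels[i], "level_2": labels[j],
                         "diff": float(diff), "se": float(se), "q": float(q),
                         "p_adj": p, "significant": p < alpha})
    return pd.DataFrame(rows)
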