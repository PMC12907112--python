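"""Univariate ERP statistics: P300 window means, paired effects, rmANOVA.

Effect-size conventions: for a paired t-test on n subjects, Cohen's d is the
mean within-subject difference divided by the SD of the differences, which
equals t / sqrt(n); the 95% CI reported for d is d +/- t_{0.975, n-1} /
sqrt(n).  An alternative pooled-SD d (mean difference over the pooled SD of
the two conditions) is exposed for the repeated-measures post hocs, where
reporting conventions vary, but the t/sqrt(n) convention is the default
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .epochs import EpochsSet


@dataclass
class EffectStats:
    """Paired-comparison statistics with effect size and CI."""

    t: float
    df: int
    p: float
    d: float
    ci95: tuple[float, float]
    p_bonferroni: float | None = None
    d_pooled: float | None = None


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction."""

    F: float
    df_num: float
    df_den: float
    epsilon: float
    p: float
    partial_eta_sq: float
    posthoc: list[tuple[str, EffectStats]] = field(default_factory=list)


def p300_window_mean(
    epochs: EpochsSet, electrode: str, window: tuple[float, float]
) -> dict[str, float]:
    """Per-condition mean amplitude (uV) at one electrode over a window.

    The mean is taken over trials of the condition, then over the samples in
    the closed [lo, hi] millisecond window.
    """
    if electrode not in epochs.channels:
        raise KeyError(
            f"electrode {electrode!r} not in epochs (have "
            f"{', '.join(epochs.channels)})")
    ch = epochs.channels.index(electrode)
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    out = {}
    for cond in epochs.conditions():
        trials = epochs.select(cond)[:, ch, :]
        out[cond] = float(trials.mean(axis=0)[mask].mean())
    return out


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired Cohen's d from the paired t statistic: d = t / sqrt(n)."""
    return t / np.sqrt(n)


def d_ci95(d: float, n: int) -> tuple[float, float]:
    """95% CI for paired d: d +/- t_{0.975, n-1} / sqrt(n)."""
    half = scipy.stats.t.ppf(0.975, n - 1) / np.sqrt(n)
    return (d - half, d + half)


def paired_t_effect(a, b) -> EffectStats:
    """Paired t-test with Cohen's d (= t / sqrt(n)) and its 95% CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    diffs = a - b
    n = len(diffs)
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    t = diffs.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), n - 1)
    d = cohens_d_from_t(t, n)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    d_pooled = float(diffs.mean() / pooled) if pooled > 0 else np.nan
    return EffectStats(t=float(t), df=n - 1, p=float(p), d=float(d),
                       ci95=d_ci95(d, n), d_pooled=d_pooled)


def rm_anova_gg(
    values: np.ndarray, level_names: list[str] | None = None
) -> AnovaResult:
    """One-way repeated-measures ANOVA (subjects x levels) with GG correction.

    F and the Greenhouse-Geisser epsilon come from pingouin; the reported
    degrees of freedom are epsilon-corrected, partial eta^2 is
    SS_effect / (SS_effect + SS_error), and the p-value is the GG-corrected
    one.  Post hoc pairwise comparisons are paired t-tests with
    Bonferroni-adjusted p (min(1, m * p_raw)).
    """
    import pingouin as pg

    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("values must be subjects x levels, both >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells are not supported")
    n, k = values.shape
    names = level_names or [f"level{i}" for i in range(k)]
    df = pd.DataFrame(values, columns=names)
    df["subject"] = np.arange(n)
    long = df.melt(id_vars="subject", var_name="level", value_name="y")
    res = pg.rm_anova(data=long, dv="y", within="level", subject="subject",
                      correction=True, detailed=True, effsize="np2")
    row = res.iloc[0]
    eps = float(row["eps"])
    f_stat = float(row["F"])
    p_gg = [c for c in res.columns if c in ("p-GG-corr", "p_GG_corr")]
    p_unc = [c for c in res.columns if c in ("p-unc", "p_unc")]
    p = float(row[p_gg[0]]) if p_gg and np.isfinite(row[p_gg[0]]) \
        else float(row[p_unc[0]])
    df_num = eps * (k - 1)
    df_den = eps * (k - 1) * (n - 1)
    np2 = float(row["np2"])

    m = k * (k - 1) // 2
    posthoc = []
    for i in range(k):
        for j in range(i + 1, k):
            eff = paired_t_effect(values[:, i], values[:, j])
            eff.p_bonferroni = min(1.0, m * eff.p)
            posthoc.append((f"{names[i]} vs {names[j]}", eff))
    return AnovaResult(F=f_stat, df_num=float(df_num), df_den=float(df_den),
                       epsilon=eps, p=p, partial_eta_sq=np2, posthoc=posthoc)


def effects_table(rows: list[tuple[str, EffectStats]]) -> pd.DataFrame:
    """Statistics table with one row per comparison (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "comparison": name, "t": e.t, "df": e.df,
                "p": round(e.p, 3), "d": e.d,
                "ci_lo": e.ci95[0], "ci_hi": e.ci95[1],
                "p_bonferroni": (round(e.p_bonferroni, 3)
                                 if e.p_bonferroni is not None else ""),
            }
            for name, e in rows
        ]
    )
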