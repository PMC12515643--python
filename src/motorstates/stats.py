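"""Pre/post statistical comparisons and microstate-EMG correlation analysis.

The plan implemented here: paired and independent t tests (with a
Wilcoxon signed-rank alternative gated on a Shapiro-Wilk normality check),
a mixed two-way ANOVA (between factor: group; within factor: microstate
class) with partial η² effect sizes and simple-effects decomposition, and
Pearson correlation of microstate-parameter change scores against EMG
feature change scores with Bonferroni or Benjamini-Hochberg multiplicity
correction. Reported p-values are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult", "paired_t", "independent_t", "wilcoxon_signed_rank",
    "paired_compare", "mixed_anova", "simple_effects", "pearson_corr",
    "p_adjust", "correlation_matrix", "paired_t_type1_error",
]


@dataclass
class StatResult:
    """One test's outcome: statistic, degrees of freedom, p, effect size."""

    test_name: str
    statistic: float
    df: float | tuple | None
    p: float
    effect_size: float | None = None  # partial eta squared where applicable
    correction: str | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.p) and not 0 <= self.p <= 1:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _vec(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def paired_t(pre, post) -> StatResult:
    """Two-sided paired t test on the change scores (post − pre), df = n−1.

    A positive statistic means the post values are larger on average.
    """
    pre, post = _vec(pre), _vec(post)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("paired t needs two equal-length vectors with n ≥ 2")
    diff = post - pre
    if np.std(diff, ddof=1) == 0:
        raise ValueError("degenerate data: all paired differences are equal")
    res = sps.ttest_rel(post, pre)
    return StatResult("paired_t", float(res.statistic), float(pre.size - 1),
                      float(res.pvalue))


def independent_t(group1, group2, welch: bool = False) -> StatResult:
    """Two-sided independent-samples t; pooled variance unless ``welch``."""
    g1, g2 = _vec(group1), _vec(group2)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n ≥ 2")
    if np.std(g1, ddof=1) == 0 and np.std(g2, ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(g1, g2, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else g1.size + g2.size - 2
    return StatResult("welch_t" if welch else "independent_t",
                      float(res.statistic), df, float(res.pvalue))


def wilcoxon_signed_rank(pre, post) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on post − pre.

    Zero differences are dropped; p is exact (sign-pattern enumeration) for
    n ≤ 25 remaining pairs and a normal approximation beyond.
    """
    pre, post = _vec(pre), _vec(post)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    diff = post - pre
    n_nonzero = int(np.count_nonzero(diff))
    if n_nonzero == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if n_nonzero <= 25 else "approx"
    res = sps.wilcoxon(post, pre, zero_method="wilcox", method=method,
                       correction=False)
    return StatResult(f"wilcoxon_{method}", float(res.statistic), None,
                      float(res.pvalue))


def paired_compare(pre, post, alpha: float = 0.05) -> dict:
    """Normality-gated paired comparison: report both tests, select one.

    A Shapiro-Wilk check on the change scores at ``alpha`` selects the
    paired t (normal) or the Wilcoxon signed-rank (non-normal); both
    results are always returned.
    """
    pre, post = _vec(pre), _vec(post)
    shapiro_p = float(sps.shapiro(post - pre).pvalue)
    t_res = paired_t(pre, post)
    w_res = wilcoxon_signed_rank(pre, post)
    selected = "paired_t" if shapiro_p >= alpha else "wilcoxon"
    return {"shapiro_p": shapiro_p, "paired_t": t_res, "wilcoxon": w_res,
            "selected": selected}


def mixed_anova(values: pd.DataFrame, group) -> dict[str, StatResult]:
    """Mixed two-way ANOVA: between-subject group × within-subject class.

    Parameters
    ----------
    values : DataFrame, subjects × classes
        One row per subject, one column per (complete) within-factor level.
    group : array-like
        Between-factor label per subject (row).

    Returns between, within and interaction F tests with partial
    η² = SS_effect / (SS_effect + SS_error).
    """
    import pingouin as pg

    values = pd.DataFrame(values)
    group = np.asarray(group)
    if group.shape[0] != values.shape[0]:
        raise ValueError("one group label per subject required")
    if values.isna().any().any():
        raise ValueError("missing cells: every subject needs all class levels")
    long = values.reset_index(drop=True).rename_axis("subject").reset_index()
    long["group"] = group
    long = long.melt(id_vars=["subject", "group"], var_name="class",
                     value_name="value")
    aov = pg.mixed_anova(data=long, dv="value", within="class",
                         between="group", subject="subject", effsize="np2")
    aov = aov.set_index("Source")
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    out = {}
    for key, source in (("group", "group"), ("class", "class"),
                        ("interaction", "Interaction")):
        row = aov.loc[source]
        out[key] = StatResult(f"mixed_anova_{key}", float(row["F"]),
                              (float(row["DF1"]), float(row["DF2"])),
                              float(row[p_col]),
                              effect_size=float(row["np2"]))
    return out


def simple_effects(values: pd.DataFrame, group, method: str = "bonferroni"
                   ) -> pd.DataFrame:
    """Between-group one-way test at every within level (for significant interactions).

    Returns a DataFrame with F, df, raw and multiplicity-adjusted p per class.
    """
    import pingouin as pg

    values = pd.DataFrame(values)
    group = np.asarray(group)
    rows = []
    for col in values.columns:
        d = pd.DataFrame({"value": values[col].to_numpy(), "group": group})
        a = pg.anova(data=d, dv="value", between="group", detailed=False)
        p_col = "p_unc" if "p_unc" in a.columns else "p-unc"
        rows.append({"class": col, "F": float(a["F"].iloc[0]),
                     "df1": float(a["ddof1"].iloc[0]), "df2": float(a["ddof2"].iloc[0]),
                     "p": float(a[p_col].iloc[0])})
    out = pd.DataFrame(rows).set_index("class")
    out["p_adj"] = p_adjust(out["p"].to_numpy(), method=method)
    return out


def pearson_corr(x, y) -> StatResult:
    """Pearson correlation with two-sided p from the t transform (df = n−2)."""
    x, y = _vec(x), _vec(y)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson correlation needs equal-length vectors, n ≥ 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return StatResult("pearson", float(res.statistic), float(x.size - 2),
                      float(res.pvalue))


def p_adjust(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Multiplicity adjustment: 'bonferroni' (min(1, m·p)) or 'fdr_bh' (step-up)."""
    pvals = _vec(pvals)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bonferroni", "fdr_bh"):
        raise ValueError(f"unknown method {method!r}")
    return multipletests(pvals, method=method)[1]


def correlation_matrix(microstate_deltas: pd.DataFrame, emg_deltas: pd.DataFrame,
                       method: str = "fdr_bh"):
    """Pearson r of every (microstate parameter, muscle) change-score pair.

    Both inputs are subject-indexed DataFrames (same subjects, same order):
    microstate parameter changes (typically 5 classes × 3 metrics = 15
    columns) and EMG feature changes (one column per muscle). Returns
    ``(r, p, p_adj)`` DataFrames of shape (n_parameters × n_muscles); the
    adjustment is applied over all cells jointly.
    """
    ms = pd.DataFrame(microstate_deltas)
    emg = pd.DataFrame(emg_deltas)
    if not ms.index.equals(emg.index):
        raise ValueError("subject indices of the two tables do not match")
    r = pd.DataFrame(index=ms.columns, columns=emg.columns, dtype=float)
    p = r.copy()
    for mcol in ms.columns:
        for ecol in emg.columns:
            res = pearson_corr(ms[mcol], emg[ecol])
            r.loc[mcol, ecol] = res.statistic
            p.loc[mcol, ecol] = res.p
    p_adj = pd.DataFrame(p_adjust(p.to_numpy().ravel(), method=method)
                         .reshape(p.shape), index=p.index, columns=p.columns)
    return r, p, p_adj


def paired_t_type1_error(n: int = 20, n_reps: int = 10_000, alpha: float = 0.05,
                         seed: int | None = None) -> float:
    """Monte-Carlo type-I error of the paired t under a Gaussian null.

    Simulates ``n_reps`` experiments of ``n`` i.i.d. standard-normal change
    scores and returns the fraction rejected at ``alpha`` (two-sided).
    """
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_reps, n))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    p = 2 * sps.t.sf(np.abs(t), df=n - 1)
    return float(np.mean(p < alpha))
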