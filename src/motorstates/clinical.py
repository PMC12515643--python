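"""Clinical outcome summaries and stimulation-protocol arithmetic."""

from __future__ import annotations

import pandas as pd

from .stats import paired_compare, paired_t

__all__ = ["clinical_outcomes_report", "rtms_pulse_count"]


def clinical_outcomes_report(scores: pd.DataFrame,
                             outcomes: dict[str, tuple[str, str]] | None = None
                             ) -> pd.DataFrame:
    """Pre/post summary of clinical scales with paired t statistics.

    Parameters
    ----------
    scores : DataFrame
        Subject-indexed table containing pre/post columns per outcome.
    outcomes : dict, optional
        Maps report row name to its (pre, post) column pair. Defaults to
        FMA-UE and ARAT on the standard column names.

    Returns one row per outcome: pre/post mean and SD, paired t, df, p and
    the Wilcoxon alternative with its normality gate.
    """
    if outcomes is None:
        outcomes = {"FMA-UE": ("fma_ue_pre", "fma_ue_post"),
                    "ARAT": ("arat_pre", "arat_post")}
    rows = []
    for name, (pre_col, post_col) in outcomes.items():
        pre = scores[pre_col].to_numpy(dtype=float)
        post = scores[post_col].to_numpy(dtype=float)
        t_res = paired_t(pre, post)
        gated = paired_compare(pre, post)
        rows.append({
            "outcome": name,
            "pre_mean": pre.mean(), "pre_sd": pre.std(ddof=1),
            "post_mean": post.mean(), "post_sd": post.std(ddof=1),
            "t": t_res.statistic, "df": t_res.df, "p": t_res.p,
            "wilcoxon_W": gated["wilcoxon"].statistic,
            "wilcoxon_p": gated["wilcoxon"].p,
            "shapiro_p": gated["shapiro_p"],
            "selected_test": gated["selected"],
        })
    return pd.DataFrame(rows).set_index("outcome")


def rtms_pulse_count(freq_hz: float = 10.0, train_duration_s: float = 2.0,
                     n_trains: int = 60) -> int:
    """Total pulses delivered per rTMS session: frequency × train length × trains.

    The default protocol (10 Hz trains of 2 s, 60 trains with 8 s
    inter-train intervals) delivers 1200 pulses.
    """
    if freq_hz <= 0 or train_duration_s <= 0 or n_trains <= 0:
        raise ValueError("protocol parameters must be positive")
    return int(round(freq_hz * train_duration_s * n_trains))
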