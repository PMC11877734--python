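"""Behavioural statistics: signal detection, accuracy summaries, simple tests.

Covers the descriptive/inferential layer around the learning models:
d-prime scoring of the control discrimination task (with the 0.01 adjustment
of extreme rates), group x condition x phase accuracy tables with one-sample
tests against chance, pooled-variance two-sample t-tests, and a boxplot-rule
outlier flagger.  The heavier mixed-effects analyses are deliberately out of
scope; :func:`make_long_table` exports a model-ready long table for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DPrimeResult",
    "dprime",
    "accuracy_table",
    "independent_ttest",
    "one_sample_ttest",
    "outlier_flag",
    "make_long_table",
]

EXTREME_ADJUST = 0.01


@dataclass(frozen=True)
class DPrimeResult:
    """Sensitivity index with the (possibly adjusted) hit/false-alarm rates."""

    hit_rate: float
    fa_rate: float
    dprime: float


def dprime(hits: int, misses: int, fas: int, crs: int) -> DPrimeResult:
    """d' = z(hit rate) - z(false-alarm rate).

    Rates of exactly 0 and 1 are adjusted to 0.01 and 0.99 respectively
    before the quantile transform.
    """
    for name, v in (("hits", hits), ("misses", misses), ("fas", fas), ("crs", crs)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    n_signal = hits + misses
    n_noise = fas + crs
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    hr = hits / n_signal
    fr = fas / n_noise
    hr = min(max(hr, EXTREME_ADJUST), 1 - EXTREME_ADJUST)
    fr = min(max(fr, EXTREME_ADJUST), 1 - EXTREME_ADJUST)
    d = float(sps.norm.ppf(hr) - sps.norm.ppf(fr))
    return DPrimeResult(hit_rate=hr, fa_rate=fr, dprime=d)


def one_sample_ttest(values, popmean: float = 0.5) -> tuple[float, int, float]:
    """One-sample t-test; returns (t, df, p)."""
    values = np.asarray(values, dtype=float)
    res = sps.ttest_1samp(values, popmean)
    return float(res.statistic), int(values.size - 1), float(res.pvalue)


def independent_ttest(values_a, values_b) -> tuple[float, int, float]:
    """Student's pooled-variance two-sample t-test; returns (t, df, p).

    df = n_a + n_b - 2.  Raises on zero pooled variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        return 0.0, int(a.size + b.size - 2), 1.0
    pooled = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0:
        raise ValueError("pooled variance is zero; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), int(a.size + b.size - 2), float(res.pvalue)


def outlier_flag(values) -> np.ndarray:
    """Boxplot-rule outliers: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    With zero IQR only exact deviants from the quartile value are flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 values for quartile-based flagging")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, s in _STARS:
        if p < cut:
            return s
    return ""


def accuracy_table(long_df: pd.DataFrame) -> pd.DataFrame:
    """Accuracy summary by group x task x condition x phase.

    ``long_df`` is the model-ready long table (see :func:`make_long_table`):
    one row per scoreable experimental trial with columns ``participant_id``,
    ``group``, ``task``, ``condition``, ``phase`` and boolean ``correct``.
    Each cell reports the mean and SD over participant-level proportions
    correct, the cell n, and a one-sample t-test against chance (0.5).
    Empty cells are reported as missing rows, not errors.
    """
    required = {"participant_id", "group", "task", "condition", "phase", "correct"}
    missing = required - set(long_df.columns)
    if missing:
        raise ValueError(f"long table is missing columns: {sorted(missing)}")
    df = long_df.copy()
    df["correct"] = df["correct"].astype(float)
    per_part = (
        df.groupby(["group", "task", "condition", "phase", "participant_id"], sort=True)[
            "correct"
        ]
        .mean()
        .reset_index(name="prop_correct")
    )
    rows = []
    for (group, task, cond, phase), cell in per_part.groupby(
        ["group", "task", "condition", "phase"], sort=True
    ):
        vals = cell["prop_correct"].to_numpy()
        row = {
            "group": group,
            "task": task,
            "condition": cond,
            "phase": phase,
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        }
        if vals.size > 1 and np.std(vals) > 0:
            t, dfree, p = one_sample_ttest(vals, 0.5)
            row.update(t_vs_chance=t, df=dfree, p_vs_chance=p, sig=_stars(p))
        else:
            row.update(t_vs_chance=np.nan, df=np.nan, p_vs_chance=np.nan, sig="")
        rows.append(row)
    return pd.DataFrame(rows)


def make_long_table(
    trials_df: pd.DataFrame,
    roster_df: pd.DataFrame,
    condition_map: dict[str, dict] | None = None,
    dprime_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the model-ready long table from the tidy trial CSV plus a roster.

    Joins group labels (roster columns ``participant_id``, ``group``) onto
    scoreable experimental trials, attaches a per-trial condition label —
    multi-cue: ambiguous/unambiguous from the stimulus table; single-cue:
    from ``condition_map[participant_id]`` metadata or the stimulus-id prefix
    — and optionally merges per-participant d' covariates.  Catch trials and
    timeouts are dropped.
    """
    from .tasks import MULTICUE_P_HIGH_TABLE, AMBIGUOUS_BAND

    df = trials_df.copy()
    df = df[(~df["is_catch"].astype(bool))]
    df = df[df["response"].notna() & (df["response"] != "") & (df["response"] != "timeout")]
    df = df[df["correct"].notna() & (df["correct"] != "")]
    df = df.merge(roster_df[["participant_id", "group"]], on="participant_id", how="left")

    p_by_sid = {i + 1: p for i, (_, p) in enumerate(MULTICUE_P_HIGH_TABLE)}

    def trial_condition(row) -> str:
        if row["task"] == "multi_cue":
            p = p_by_sid.get(int(row["stimulus_id"]), np.nan)
            return (
                "ambiguous"
                if AMBIGUOUS_BAND[0] <= p <= AMBIGUOUS_BAND[1]
                else "unambiguous"
            )
        if row["task"] == "single_cue":
            if condition_map and row["participant_id"] in condition_map:
                return condition_map[row["participant_id"]].get("condition", "")
            sid = str(row["stimulus_id"])
            return {"dete": "deterministic", "prob": "probabilistic"}.get(sid[:4], "")
        return "n/a"

    df["condition"] = df.apply(trial_condition, axis=1)
    df["correct"] = df["correct"].map(
        lambda v: str(v).lower() in ("true", "1", "1.0")
    )
    df["item"] = df["stimulus_id"]
    cols = [
        "participant_id",
        "group",
        "task",
        "condition",
        "phase",
        "block",
        "trial_index",
        "item",
        "correct",
    ]
    out = df[cols].reset_index(drop=True)
    if dprime_df is not None:
        out = out.merge(dprime_df, on="participant_id", how="left")
    return out
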