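"""Descriptive statistics and nonparametric tests on trial tables.

These are the data-level results: costly-choice proportions overall and
per design cell, omission rates, ceiling-effect prevalence, effort success
rates, and the paired tests relating discounting parameters within and
across tasks (Wilcoxon signed-rank, Kendall's tau-b, paired t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .design import TaskKind

__all__ = [
    "SummaryFilters",
    "ChoiceProportions",
    "choice_proportions",
    "omission_rates",
    "ceiling_proportion",
    "success_rates",
    "paired_t",
    "wilcoxon_signed_rank",
    "kendall_tau",
    "k_difference",
    "EmptySelectionWarning",
]


class EmptySelectionWarning(UserWarning):
    """No trials survived the requested filters."""


@dataclass(frozen=True)
class SummaryFilters:
    """Row filters for descriptive summaries."""

    task: str | None = None
    recipient: str | None = None
    drop_omissions: bool = True

    def apply(self, dataset: pd.DataFrame) -> pd.DataFrame:
        df = dataset
        if self.task is not None:
            df = df[df["task"] == TaskKind(self.task).value]
        if self.recipient is not None:
            df = df[df["recipient"] == self.recipient]
        if self.drop_omissions:
            df = df[df["choice"] != "omission"]
        return df


@dataclass(frozen=True)
class ChoiceProportions:
    """Costly-choice proportions at three granularities.

    ``pooled`` pools trials; ``participant_mean`` averages per-participant
    proportions (the "on average" reading); ``per_cell`` and
    ``per_participant`` carry the underlying tables.
    """

    pooled: float
    participant_mean: float
    per_cell: pd.DataFrame
    per_participant: pd.DataFrame
    empty: bool = False


def choice_proportions(
    dataset: pd.DataFrame, filters: SummaryFilters | None = None
) -> ChoiceProportions:
    """Proportion of non-omitted trials where the costly option was chosen."""
    filters = filters or SummaryFilters()
    df = filters.apply(dataset)
    if df.empty:
        warnings.warn("no trials after filtering", EmptySelectionWarning)
        return ChoiceProportions(
            pooled=float("nan"),
            participant_mean=float("nan"),
            per_cell=pd.DataFrame(),
            per_participant=pd.DataFrame(),
            empty=True,
        )
    costly = (df["choice"] == "costly").astype(float)
    per_cell = (
        df.assign(costly=costly)
        .groupby(["cost_level", "reward", "recipient"], as_index=False)
        .agg(n_trials=("costly", "size"), proportion=("costly", "mean"))
    )
    per_participant = (
        df.assign(costly=costly)
        .groupby("participant", as_index=False)
        .agg(n_trials=("costly", "size"), proportion=("costly", "mean"))
    )
    return ChoiceProportions(
        pooled=float(costly.mean()),
        participant_mean=float(per_participant["proportion"].mean()),
        per_cell=per_cell,
        per_participant=per_participant,
    )


def omission_rates(dataset: pd.DataFrame) -> pd.DataFrame:
    """Percentage of omitted trials per task x recipient."""
    g = (
        dataset.assign(omitted=(dataset["choice"] == "omission").astype(float))
        .groupby(["task", "recipient"], as_index=False)
        .agg(n_trials=("omitted", "size"), rate_pct=("omitted", "mean"))
    )
    g["rate_pct"] *= 100.0
    return g


def ceiling_proportion(
    dataset: pd.DataFrame, task: str | TaskKind, threshold: float = 0.95
) -> float:
    """Fraction of participants choosing costly on more than ``threshold`` of trials."""
    cp = choice_proportions(dataset, SummaryFilters(task=TaskKind(task).value))
    if cp.empty:
        return float("nan")
    return float((cp.per_participant["proportion"] > threshold).mean())


def success_rates(dataset: pd.DataFrame) -> pd.DataFrame:
    """Effort-task success rates on chosen-costly trials, per recipient.

    Per participant and recipient, the fraction of chosen-costly trials
    where the required force level was reached; the table carries the
    per-participant values (percent), whose mean per recipient is the
    headline statistic.  Participants with no chosen-costly trials for a
    recipient are excluded with a warning.
    """
    df = dataset[
        (dataset["task"] == TaskKind.effort.value) & (dataset["choice"] == "costly")
    ]
    if df.empty:
        warnings.warn("no chosen-costly effort trials", EmptySelectionWarning)
        return pd.DataFrame(columns=["participant", "recipient", "success_pct"])
    out = (
        df.assign(ok=df["success"].astype("boolean").fillna(False).astype(float))
        .groupby(["participant", "recipient"], as_index=False)
        .agg(n_trials=("ok", "size"), success_pct=("ok", "mean"))
    )
    out["success_pct"] *= 100.0
    n_expected = dataset["participant"].nunique() * 2
    if len(out) < n_expected:
        warnings.warn(
            "some participants had no chosen-costly trials for a recipient "
            "and are excluded from success rates"
        )
    return out


def paired_t(x, y) -> tuple[float, int, float, tuple[float, float]]:
    """Classical paired t-test: returns (t, df, mean difference, 95% CI)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-d samples with n >= 2")
    d = x - y
    n = len(d)
    se = d.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    md = float(d.mean())
    if se == 0:
        # degenerate: identical pairs give t = 0, a constant shift t = +-inf
        t = 0.0 if md == 0 else float(np.sign(md) * np.inf)
    else:
        t = float(stats.ttest_rel(x, y).statistic)
    return (t, n - 1, md, (md - tcrit * se, md + tcrit * se))


def _signrank_exact_tail(v: float, n: int) -> tuple[float, float]:
    """P(V >= v) and P(V <= v) for the null sign-rank distribution (no ties).

    Exact via the generating function over all 2^n sign assignments
    (polynomial convolution, not literal enumeration).
    """
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    total = counts.sum()  # 2**n
    v_int = int(round(v))
    p_ge = counts[v_int:].sum() / total
    p_le = counts[: v_int + 1].sum() / total
    return float(p_ge), float(p_le)


def wilcoxon_signed_rank(
    x, y=None, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns (V, p).

    ``V`` is the sum of ranks of positive differences ``x - y`` (zero
    differences dropped, midranks for ties).  The p-value is exact (sign
    pattern distribution) for n <= 25 without ties in |d|, otherwise a
    normal approximation with tie correction and continuity correction.
    ``alternative="greater"`` tests for ``x > y`` (large V).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n

    if n <= 25 and not has_ties:
        p_ge, p_le = _signrank_exact_tail(v, n)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return v, float(p)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    if sd == 0:
        raise ValueError("zero variance in signed ranks; test undefined")
    if alternative == "greater":
        z = (v - mean - 0.5) / sd
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (v - mean + 0.5) / sd
        p = stats.norm.cdf(z)
    else:
        z = (v - mean - np.sign(v - mean) * 0.5) / sd
        p = 2.0 * stats.norm.sf(abs(z))
    return v, float(min(1.0, p))


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b rank correlation with its p-value (scipy-backed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def k_difference(point_estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-subject discounting asymmetry ``k_self - k_env`` per task.

    Requires estimates from a separate-k fit; a joint-k fit has no defined
    asymmetry and raises.
    """
    if point_estimates.attrs.get("k_structure") == "joint":
        raise ValueError("k difference is undefined for a joint-k model")
    req = {"participant", "k_self", "k_env"}
    if not req <= set(point_estimates.columns):
        raise ValueError(f"point_estimates needs columns {sorted(req)}")
    out = point_estimates[
        ["participant"] + (["task"] if "task" in point_estimates.columns else [])
    ].copy()
    out["k_diff"] = (
        point_estimates["k_self"].to_numpy() - point_estimates["k_env"].to_numpy()
    )
    if not np.all(np.isfinite(out["k_diff"])):
        raise ValueError("non-finite k difference")
    return out
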