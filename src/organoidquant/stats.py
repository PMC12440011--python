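"""Statistical layer: group summaries, one-way ANOVA with Fisher's LSD,
two-sample t-tests, fold changes, and relative qPCR quantification.

Comparisons follow the study's convention: fixed-effects one-way ANOVA
followed by Fisher's LSD pairwise tests using the pooled within-group
mean square, with **no** multiple-comparison correction.  Data are
summarized as mean +/- SEM.  Relative transcript abundance uses the
2^-ddCt method against a housekeeping gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "summarize",
    "one_way_anova",
    "fisher_lsd",
    "two_sample_t",
    "fold_change",
    "ddct_fold_change",
]


@dataclass
class GroupSummary:
    mean: float
    sem: float
    n: int
    sem_defined: bool


@dataclass
class AnovaResult:
    """Classical one-way fixed-effects decomposition."""

    F: float
    df_between: int
    df_within: int
    p: float
    mse: float  # pooled within-group mean square
    ss_between: float
    ss_within: float
    group_order: list[str]
    group_means: dict[str, float]
    group_ns: dict[str, int]


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean and SEM (sample SD over sqrt(n), n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    if x.size == 1:
        return GroupSummary(mean=float(x[0]), sem=float("nan"), n=1, sem_defined=False)
    sem = float(x.std(ddof=1) / np.sqrt(x.size))
    return GroupSummary(mean=float(x.mean()), sem=sem, n=int(x.size), sem_defined=True)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across ``groups``.

    F = (SSB / (k-1)) / (SSW / (N-k)); p from the F(k-1, N-k)
    distribution.  Every group must contribute at least two values.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for name, x in g.items():
        if x.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    all_x = np.concatenate(list(g.values()))
    grand = all_x.mean()
    ssb = sum(x.size * (x.mean() - grand) ** 2 for x in g.values())
    ssw = sum(((x - x.mean()) ** 2).sum() for x in g.values())
    k = len(g)
    n_total = all_x.size
    df_b, df_w = k - 1, n_total - k
    mse = ssw / df_w
    if mse == 0:
        f_stat = float("inf") if ssb > 0 else 0.0
    else:
        f_stat = (ssb / df_b) / mse
    p = float(sps.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0
    return AnovaResult(
        F=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p=p,
        mse=float(mse),
        ss_between=float(ssb),
        ss_within=float(ssw),
        group_order=list(g),
        group_means={name: float(x.mean()) for name, x in g.items()},
        group_ns={name: int(x.size) for name, x in g.items()},
    )


def fisher_lsd(
    groups: Mapping[str, Sequence[float]], anova: AnovaResult
) -> pd.DataFrame:
    """Uncorrected pairwise comparisons using the pooled ANOVA error term.

    For each pair, t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j))
    with a two-sided p on ``df_within`` degrees of freedom.  No
    multiplicity correction is applied.
    """
    g = _as_groups(groups)
    if list(g) != anova.group_order:
        raise ValueError("groups do not match the ANOVA they are compared under")
    rows = []
    for a, b in combinations(anova.group_order, 2):
        na, nb = anova.group_ns[a], anova.group_ns[b]
        diff = anova.group_means[a] - anova.group_means[b]
        se = np.sqrt(anova.mse * (1.0 / na + 1.0 / nb))
        if se == 0:
            t = 0.0 if diff == 0 else np.sign(diff) * float("inf")
        else:
            t = diff / se
        p = float(2 * sps.t.sf(abs(t), anova.df_within)) if np.isfinite(t) else 0.0
        if t == 0:
            p = 1.0
        rows.append({"group_1": a, "group_2": b, "mean_diff": diff, "t": float(t), "p": p})
    return pd.DataFrame(rows)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance by default."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def fold_change(
    groups: Mapping[str, Sequence[float]], control: str
) -> dict[str, float]:
    """Ratio of each condition's mean to the control mean.

    A value of 1/3 corresponds to what the field reports as a "3-fold
    reduction".
    """
    g = _as_groups(groups)
    if control not in g:
        raise ValueError(f"control condition {control!r} missing")
    ctrl_mean = g[control].mean()
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; fold change undefined")
    return {name: float(x.mean() / ctrl_mean) for name, x in g.items()}


def ddct_fold_change(
    ct: pd.DataFrame,
    control: str,
    condition_col: str = "condition",
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
) -> dict[str, float]:
    """Relative expression by the 2^-ddCt method.

    Per condition, dCt = mean(Ct_target) - mean(Ct_reference) across
    replicates; ddCt = dCt_condition - dCt_control; the fold change is
    2^-ddCt.  Returns one fold change per non-control condition.
    """
    for col in (condition_col, target_col, reference_col):
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    if (ct[[target_col, reference_col]].to_numpy() <= 0).any():
        raise ValueError("Ct values must be positive")
    conditions = list(dict.fromkeys(ct[condition_col]))
    if control not in conditions:
        raise ValueError(f"missing condition {control!r} in Ct table")
    if len(conditions) < 2:
        raise ValueError("Ct table needs a control and at least one other condition")
    dct = {}
    for cond in conditions:
        sub = ct[ct[condition_col] == cond]
        dct[cond] = float(sub[target_col].mean() - sub[reference_col].mean())
    return {
        cond: float(2.0 ** (-(dct[cond] - dct[control])))
        for cond in conditions
        if cond != control
    }
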