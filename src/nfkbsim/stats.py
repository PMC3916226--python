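"""Statistical battery applied per time point to replicate assay data:
one-way ANOVA across cell types, Newman–Keuls stepwise post-hoc comparisons,
and the one-sample t test against unity used for ratio-normalized
quantifications.  Each time point is analyzed independently, matching the
design in which independent cell populations are harvested per time.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "anova_oneway",
    "newman_keuls",
    "one_sample_t_vs_unity",
    "compare_groups",
]


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least two replicates")
    return gs


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate inputs are resolved explicitly: all groups identical within
    but with unequal means → (inf, 0); everything identical → (0, 1).
    """
    gs = _as_groups(groups)
    means = np.array([g.mean() for g in gs])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0.0:
        if np.ptp(means) == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    with np.errstate(invalid="ignore"):
        f, p = sps.f_oneway(*gs)
    return float(f), float(p)


@lru_cache(maxsize=1024)
def _q_crit(alpha: float, span: int, df: int) -> float:
    # studentized-range quantiles are expensive; (span, df) pairs repeat
    # heavily across time points and simulations
    return float(sps.studentized_range.ppf(1.0 - alpha, span, df))


def newman_keuls(groups, alpha: float = 0.05) -> np.ndarray:
    """Newman–Keuls stepwise multiple comparisons on ordered group means.

    Returns the symmetric boolean significance matrix (``[i, j]`` is True
    when groups i and j differ at level ``alpha``).  The procedure is gated
    on the omnibus ANOVA: if it does not reject at ``alpha``, no pair is
    declared significant.  Means spanning r ordered groups are compared
    against ``q(alpha, r, df_within) · sqrt(MSW / n_h)``, with the harmonic
    mean n for unbalanced groups; a non-significant span blocks every pair
    nested inside it.
    """
    gs = _as_groups(groups)
    k = len(gs)
    sig = np.zeros((k, k), dtype=bool)
    _, p_omnibus = anova_oneway(gs)
    if not p_omnibus < alpha:
        return sig

    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    df_w = int(ns.sum() - k)
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    order = np.argsort(means)  # ascending
    sorted_means = means[order]

    # blocked[a, b] marks spans (in sorted order) already declared
    # non-significant; nested spans inherit the block.
    blocked = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for a in range(0, k - span + 1):
            b = a + span - 1
            if blocked[a, b]:
                continue
            n_h = span / (1.0 / ns[order[a:b + 1]]).sum()
            se = np.sqrt(msw / n_h)
            if se == 0.0:
                significant = sorted_means[b] > sorted_means[a]
            else:
                q = (sorted_means[b] - sorted_means[a]) / se
                significant = q > _q_crit(alpha, span, df_w)
            if significant:
                sig[order[a], order[b]] = sig[order[b], order[a]] = True
            else:
                for a2 in range(a, b + 1):
                    for b2 in range(a2, b + 1):
                        blocked[a2, b2] = True
    return sig


def one_sample_t_vs_unity(values) -> tuple[float, float]:
    """Two-sided one-sample t test of mean = 1 for ratio-normalized data."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two values")
    if v.std(ddof=1) == 0.0:
        raise ValueError("zero variance: the t statistic is undefined")
    res = sps.ttest_1samp(v, popmean=1.0)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """Per-time-point battery result."""

    time_min: float
    groups: dict[str, np.ndarray]
    f_statistic: float
    p_value: float
    significant_pairs: np.ndarray  # aligned with sorted(groups)
    alpha: float

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def pair_significant(self, g1: str, g2: str) -> bool:
        names = list(self.groups)
        return bool(self.significant_pairs[names.index(g1), names.index(g2)])


def compare_groups(data: pd.DataFrame, alpha: float = 0.05,
                   value_col: str = "value", group_col: str = "cell_type",
                   time_col: str = "time_min") -> list[GroupComparison]:
    """Run ANOVA + Newman–Keuls independently at every time point of a tidy table."""
    out = []
    for t, sub in data.groupby(time_col, sort=True):
        groups = {name: g[value_col].to_numpy()
                  for name, g in sub.groupby(group_col, sort=True)}
        gs = list(groups.values())
        f, p = anova_oneway(gs)
        sig = newman_keuls(gs, alpha=alpha)
        out.append(GroupComparison(time_min=float(t), groups=groups,
                                   f_statistic=f, p_value=p,
                                   significant_pairs=sig, alpha=alpha))
    return out
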