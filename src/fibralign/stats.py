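"""Group comparison of orientation indices across culture conditions.

One-way ANOVA across conditions followed by all-pairs post-hoc tests with
Holm-Sidak step-down adjustment, matching the standard analysis for OI
data. Each analyzed image contributes one OI observation to its
condition's sample.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "one_way_anova",
    "holm_sidak",
    "compare_conditions",
]


@dataclasses.dataclass
class GroupComparison:
    """Full record of a multi-condition OI comparison."""

    group_labels: list[str]
    oi_samples: dict[str, np.ndarray]
    f_statistic: float
    p_value: float
    pairwise: list[tuple[tuple[str, str], float, float]]  # (pair, raw p, adjusted p)

    def to_frame(self) -> pd.DataFrame:
        """Pairwise results as a tidy table (one row per condition pair)."""
        rows = [
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(np.mean(self.oi_samples[a])),
                "mean_b": float(np.mean(self.oi_samples[b])),
                "p_raw": p_raw,
                "p_holm_sidak": p_adj,
                "anova_f": self.f_statistic,
                "anova_p": self.p_value,
            }
            for (a, b), p_raw, p_adj in self.pairwise
        ]
        return pd.DataFrame(rows)


def _validate_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise ValueError("each group needs at least two values")
        if not np.all(np.isfinite(g)):
            raise ValueError("group values must be finite")
        out.append(g)
    return out


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: returns (F, p).

    F is the between/within mean-square ratio; p its upper-tail
    probability under F(k-1, N-k). Degenerate cases follow the usual
    conventions: identical group means give F = 0, p = 1; zero
    within-group variance with unequal means gives F = +inf, p = 0.
    """
    groups = _validate_groups(groups)
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    if ss_within <= 1e-300 * max(1.0, abs(ss_between)):
        if ss_between <= 1e-300:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def holm_sidak(p_values: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sorting the m raw p-values ascending, the i-th (1-based) is adjusted to
    1 - (1 - p_(i))^(m - i + 1), a running maximum enforces step-down
    monotonicity, and the result is unsorted back. Adjusted values never
    fall below the raw ones and stay in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def _pairwise_t_pooled(
    samples: dict[str, np.ndarray], df_within: int, ms_within: float
) -> list[tuple[tuple[str, str], float]]:
    """All-pairs t tests using the pooled ANOVA error term."""
    out = []
    for a, b in itertools.combinations(samples, 2):
        ga, gb = samples[a], samples[b]
        se = math.sqrt(ms_within * (1.0 / ga.size + 1.0 / gb.size))
        if se == 0:
            p = 1.0 if ga.mean() == gb.mean() else 0.0
        else:
            t = (ga.mean() - gb.mean()) / se
            p = float(2.0 * sps.t.sf(abs(t), df_within))
        out.append(((a, b), p))
    return out


def compare_conditions(
    table: pd.DataFrame,
    condition_col: str = "condition",
    value_col: str = "oi_percent",
    conditions: list[str] | None = None,
) -> GroupComparison:
    """ANOVA + Holm-Sidak over per-image OI values grouped by condition.

    ``table`` holds one row per analyzed image with its condition label and
    OI. ``conditions``, if given, restricts and orders the groups; an
    unknown label raises. Pairwise comparisons use two-sided t tests on the
    pooled within-group error term, Holm-Sidak adjusted across all pairs.
    """
    present = list(dict.fromkeys(table[condition_col]))
    if conditions is None:
        conditions = present
    else:
        unknown = set(conditions) - set(present)
        if unknown:
            raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    samples = {
        c: np.asarray(
            table.loc[table[condition_col] == c, value_col], dtype=float
        )
        for c in conditions
    }
    groups = _validate_groups([samples[c] for c in conditions])
    f, p = one_way_anova(groups)

    n_total = sum(g.size for g in groups)
    df_within = n_total - len(groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    ms_within = ss_within / df_within
    raw = _pairwise_t_pooled(samples, df_within, ms_within)
    adjusted = holm_sidak(np.array([pr for _, pr in raw])) if raw else np.array([])
    pairwise = [
        (pair, p_raw, float(p_adj))
        for (pair, p_raw), p_adj in zip(raw, adjusted)
    ]
    return GroupComparison(
        group_labels=list(conditions),
        oi_samples=samples,
        f_statistic=f,
        p_value=p,
        pairwise=pairwise,
    )
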