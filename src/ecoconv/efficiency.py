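"""Ecological (gross) conversion efficiency and group comparison.

E_g = 100 * G_d / C_d is the percentage of ingested food converted to
somatic growth.  Growth cannot exceed ingestion, so E_g > 100% indicates a
unit or orientation error and triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "conversion_efficiency",
    "EfficiencyRecord",
    "compare_groups",
    "GroupComparison",
    "compact_letter_display",
]


def conversion_efficiency(
    g_d: float,
    c_d: float,
    g_d_units: str | None = None,
    c_d_units: str | None = None,
) -> float:
    """Gross conversion efficiency ``100 * G_d / C_d`` in percent.

    G_d and C_d must share units for the ratio to be dimensionless; pass the
    unit tags to have this enforced.
    """
    if c_d <= 0:
        raise ValueError("daily ingestion C_d must be positive")
    if g_d < 0:
        raise ValueError("daily growth G_d must be non-negative")
    if g_d_units is not None and c_d_units is not None:
        if g_d_units.replace("/day", "") != c_d_units.replace("/day", ""):
            raise ValueError(
                f"unit mismatch: G_d in {g_d_units!r}, C_d in {c_d_units!r}"
            )
    e_g = 100.0 * g_d / c_d
    if e_g > 100.0:
        warnings.warn(
            f"E_g = {e_g:.1f}% > 100%: growth exceeding ingestion is "
            "physiologically impossible; check units and orientation",
            stacklevel=2,
        )
    return e_g


@dataclass
class EfficiencyRecord:
    """Rates for one (temperature, weight-class) group."""

    temperature: float
    weight_class: float
    g_d: float
    c_d: float
    e_g: float
    determined: bool = True
    g_d_sd: float = float("nan")
    c_d_sd: float = float("nan")
    e_g_sd: float = float("nan")


def compact_letter_display(
    groups: list, means: dict, significant_pairs: set
) -> dict:
    """Compact letter display by insert-and-absorb.

    Groups that share any letter are not significantly different.  Starting
    from one letter covering every group, each significant pair splits the
    letters containing both members; letters that become subsets of another
    are absorbed.  Letters are assigned a, b, c, ... in order of ascending
    group mean (ties broken by group order).
    """
    order = sorted(groups, key=lambda g: (means[g], groups.index(g)))
    letters: list[set] = [set(groups)]
    for a, b in significant_pairs:
        for col in [c for c in letters if a in c and b in c]:
            letters.remove(col)
            letters.append(col - {a})
            letters.append(col - {b})
        # absorb subsets
        letters = [
            c
            for i, c in enumerate(letters)
            if c and not any(c < d or (c == d and i > j) for j, d in enumerate(letters))
        ]
    letters.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict = {g: "" for g in groups}
    for i, col in enumerate(letters):
        for g in order:
            if g in col:
                out[g] += alphabet[i]
    return out


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD letter groupings for one rate."""

    f_statistic: float
    p_value: float
    letters: dict
    tukey_frame: pd.DataFrame
    group_means: dict


def compare_groups(
    records,
    value_col: str,
    group_col: str = "group",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA across groups plus Tukey HSD compact letter display.

    Groups with fewer than 2 replicates are excluded with a warning.
    """
    df = pd.DataFrame(records)
    sizes = df.groupby(group_col)[value_col].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(
            f"excluding groups with <2 replicates: {small}", stacklevel=2
        )
        df = df[~df[group_col].isin(small)]
    groups = list(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >=2 replicates")
    samples = [df.loc[df[group_col] == g, value_col].to_numpy(float) for g in groups]
    if np.ptp(np.concatenate(samples)) == 0:
        # all values identical: no variance anywhere, nothing to separate
        f_stat, p_val = 0.0, 1.0
        sig = set()
        tukey_frame = pd.DataFrame()
    else:
        f_stat, p_val = stats.f_oneway(*samples)
        tk = pairwise_tukeyhsd(
            df[value_col].to_numpy(float), df[group_col].to_numpy(), alpha=alpha
        )
        tukey_frame = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        sig = {
            (row["group1"], row["group2"])
            for _, row in tukey_frame.iterrows()
            if bool(row["reject"])
        }
    means = {g: float(s.mean()) for g, s in zip(groups, samples)}
    letters = compact_letter_display(groups, means, sig)
    return GroupComparison(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        letters=letters,
        tukey_frame=tukey_frame,
        group_means=means,
    )
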