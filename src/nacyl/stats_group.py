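"""Group-comparison statistics over feature (peak-area) tables.

Median log2 fold changes with explicit zero policies, non-parametric rank
tests (Mann-Whitney U for two groups, Kruskal-Wallis beyond), Benjamini-
Hochberg correction, and the volcano up/down/ns classification.  Exact
Mann-Whitney p-values are computed by full enumeration for small samples
(combined n <= 10), with midranks for ties and a two-sided p obtained by
doubling the smaller tail; larger samples use the tie-corrected normal
approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "log2_fold_change",
    "mann_whitney_exact",
    "rank_test",
    "bh_adjust",
    "volcano_classify",
]

ZeroPolicy = Literal["half_min", "replicate_zero", "none"]


@dataclass(frozen=True)
class GroupTestResult:
    feature: str
    log2fc: float
    p_raw: float
    p_adj: float
    test: str
    direction: str


def _impute_half_min(values: pd.Series) -> pd.Series:
    """Replace zeros with half the smallest nonzero value of the feature."""
    nonzero = values[values > 0]
    if nonzero.empty:
        return values
    return values.replace(0, nonzero.min() / 2.0)


def _replicate_zero(values: pd.Series) -> pd.Series:
    """Culture rule: any zero among the replicates zeroes the whole group."""
    if (values == 0).any():
        return pd.Series(0.0, index=values.index)
    return values


def log2_fold_change(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    zero_policy: ZeroPolicy = "half_min",
) -> pd.Series:
    """log2(median_a / median_b) per feature (rows) of a features x samples
    table.  NaN marks features undefined under the policy (both medians 0).
    """
    cols_a = [c for c in table.columns if groups.get(c) == group_a]
    cols_b = [c for c in table.columns if groups.get(c) == group_b]
    if not cols_a or not cols_b:
        raise ValueError("both groups must have at least one sample")
    if (table < 0).any().any():
        raise ValueError("negative peak areas")
    out = {}
    for feature, row in table.iterrows():
        a, b = row[cols_a].astype(float), row[cols_b].astype(float)
        if zero_policy == "half_min":
            merged = _impute_half_min(pd.concat([a, b]))
            a, b = merged[cols_a], merged[cols_b]
        elif zero_policy == "replicate_zero":
            a, b = _replicate_zero(a), _replicate_zero(b)
        med_a, med_b = float(a.median()), float(b.median())
        if med_a <= 0 or med_b <= 0:
            out[feature] = math.nan
        else:
            out[feature] = math.log2(med_a / med_b)
    return pd.Series(out, name=f"log2fc_{group_a}_vs_{group_b}")


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of group splits.

    Midranks handle ties; the two-sided p doubles the smaller one-sided tail
    of the permutation distribution of U, capped at 1.  Intended for
    combined n <= 10 (C(10,5) = 252 splits).
    """
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)
    pooled = np.asarray(x + y)
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        r = ranks[list(combo)].sum()
        us.append(float(r) - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    eps = 1e-9
    p_ge = np.mean(us >= u_obs - eps)
    p_le = np.mean(us <= u_obs + eps)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def _mwu_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> float:
    if len(x) + len(y) <= exact_max_n:
        return mann_whitney_exact(x, y)
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def rank_test(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    method: Literal["mann_whitney", "kruskal_wallis"] = "mann_whitney",
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    zero_policy: ZeroPolicy = "half_min",
) -> list[GroupTestResult]:
    """Per-feature rank test with BH adjustment and volcano direction.

    ``mann_whitney`` requires exactly two groups; ``kruskal_wallis`` at
    least two (direction is reported as ``ns`` with fold change vs the first
    two groups for more than two).  Features that are all-zero in a group
    are tested and reported, never dropped.
    """
    levels = sorted(set(groups.values()))
    cols = {g: [c for c in table.columns if groups.get(c) == g] for g in levels}
    if any(len(v) == 0 for v in cols.values()):
        raise ValueError("every group needs at least one sample")
    if method == "mann_whitney" and len(levels) != 2:
        raise ValueError("mann_whitney requires exactly two groups")
    if method == "kruskal_wallis" and len(levels) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")

    fc = log2_fold_change(
        table, groups, levels[0], levels[1], zero_policy=zero_policy
    )
    p_raw = []
    for feature, row in table.iterrows():
        samples = [row[cols[g]].astype(float).to_numpy() for g in levels]
        if np.ptp(np.concatenate(samples)) == 0:  # all values identical
            p_raw.append(1.0)
            continue
        if method == "mann_whitney":
            p_raw.append(_mwu_p(samples[0], samples[1]))
        else:
            p_raw.append(float(sps.kruskal(*samples).pvalue))
    p_adj = bh_adjust(p_raw)
    out = []
    for feature, pr, pa in zip(table.index, p_raw, p_adj):
        lfc = float(fc[feature])
        direction = volcano_classify(lfc, pr, p_thresh, fc_thresh)
        out.append(
            GroupTestResult(
                feature=str(feature),
                log2fc=lfc,
                p_raw=float(pr),
                p_adj=float(pa),
                test=method,
                direction=direction,
            )
        )
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_classify(
    log2fc: float, p: float, p_thresh: float = 0.05, fc_thresh: float = 2.0
) -> str:
    """up / down / ns per the volcano thresholds (p < 0.05, |log2FC| > 2)."""
    if math.isnan(log2fc) or math.isnan(p):
        return "ns"
    if p < p_thresh and log2fc > fc_thresh:
        return "up"
    if p < p_thresh and log2fc < -fc_thresh:
        return "down"
    return "ns"
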