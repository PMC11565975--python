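"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written without reference to the package
internals: element masses come from a separate table, peak pairing is
exhaustive enumeration, and the statistical procedures are textbook
step-by-step transcriptions.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np

# IUPAC 2021 monoisotopic masses, transcribed independently of any library.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "S": 31.972071174,
    "P": 30.973761998,
    "Se": 79.916521762,  # 80Se, the most abundant isotope
    "I": 126.904471853,
}

PROTON = 1.007276


def formula_mass(counts: Mapping[str, int]) -> float:
    """Plain sum over the element-mass table."""
    return sum(ELEMENT_MASSES[el] * n for el, n in counts.items())


def brute_force_chains(min_c: int, max_c: int, max_db: int) -> list[tuple[int, int]]:
    """Triple-loop chain enumeration under n >= 2d + 1."""
    out = []
    for n in range(min_c, max_c + 1):
        for d in range(0, max_db + 1):
            if n >= 2 * d + 1:
                out.append((n, d))
    return out


def best_pairing_score(
    mz_a: Sequence[float],
    wa: Sequence[float],
    mz_b: Sequence[float],
    wb: Sequence[float],
    tol: float,
    shift: float = 0.0,
) -> tuple[float, int]:
    """Exhaustive maximum-weight one-to-one peak pairing.

    Returns (max total weight, number of pairs in that matching, counting
    only pairs that were within tolerance).  ``shift`` admits pairs with
    mz_a ~= mz_b + shift in addition to direct matches.
    """
    pairs = []
    for i, ma in enumerate(mz_a):
        for j, mb in enumerate(mz_b):
            if abs(ma - mb) <= tol or (shift != 0.0 and abs(ma - mb - shift) <= tol):
                pairs.append((i, j, wa[i] * wb[j]))

    best = (0.0, 0)

    def recurse(k: int, used_a: int, used_b: int, total: float, count: int) -> None:
        nonlocal best
        if total > best[0] + 1e-15 or (
            abs(total - best[0]) <= 1e-15 and count > best[1]
        ):
            best = (total, count)
        for m in range(k, len(pairs)):
            i, j, w = pairs[m]
            if not (used_a >> i) & 1 and not (used_b >> j) & 1:
                recurse(m + 1, used_a | (1 << i), used_b | (1 << j), total + w, count + 1)

    recurse(0, 0, 0, 0.0, 0)
    return best


def mann_whitney_permutation(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group splits.

    Midranks for ties; two-sided p = 2 * min(tail probabilities), capped.
    """
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = np.asarray(x + y, dtype=float)
    # midranks, computed by hand
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    k = 0
    while k < len(pooled):
        j = k
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[k]]:
            j += 1
        mid = (k + j) / 2.0 + 1.0
        for m in range(k, j + 1):
            ranks[order[m]] = mid
        k = j + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = [
        sum(ranks[list(c)]) - n1 * (n1 + 1) / 2.0
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.asarray(us)
    eps = 1e-9
    p = 2.0 * min(float(np.mean(us >= u_obs - eps)), float(np.mean(us <= u_obs + eps)))
    return min(1.0, p)


def bh_step_up(p_values: Sequence[float]) -> np.ndarray:
    """Hand-coded Benjamini-Hochberg step-up."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * n / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = min(1.0, running_min)
    return adjusted
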