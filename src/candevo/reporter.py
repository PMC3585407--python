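"""Statistics for the bicistronic fluorescent reporter assay.

Each construct line carries a candidate 3' regulatory sequence downstream of
an orange fluorescent reporter, with a green fluorescent protein as internal
transfection control; the per-measurement green/orange ratio is the
comparable measure of translational output across lines.  Lines are compared
with a Kruskal-Wallis rank test (the ratios are not assumed normal — a
Shapiro-Wilk check is provided), and a leave-one-line-out sweep shows how
much any single line drives the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KWResult",
    "load_fluorescence",
    "ratios",
    "kruskal_wallis",
    "kruskal_wallis_exact_p",
    "normality_check",
    "leave_one_group_out",
]

REQUIRED_COLUMNS = ("line", "replicate", "green", "orange")


def load_fluorescence(path: str | Path) -> pd.DataFrame:
    """Read a reporter CSV with columns line, replicate, green, orange."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    _check_signals(df)
    return df


def _check_signals(df: pd.DataFrame) -> None:
    if (df["green"] <= 0).any() or (df["orange"] <= 0).any():
        raise ValueError("fluorescence signals must be positive")


def ratios(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-line green/orange ratio vectors, in line order of appearance."""
    _check_signals(table)
    out: dict[str, np.ndarray] = {}
    for line, grp in table.groupby("line", sort=False):
        out[str(line)] = (grp["green"] / grp["orange"]).to_numpy()
    return out


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal-Wallis H with chi-square approximate P."""

    h: float
    df: int
    p: float
    degenerate: bool = False


def kruskal_wallis(groups: Sequence[np.ndarray] | Mapping[str, np.ndarray]) -> KWResult:
    """Kruskal-Wallis rank test across groups (mid-ranks, tie correction).

    All-identical pooled data is a degenerate case returned as H = 0, P = 1
    with a flag, by convention.
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, k - 1, 1.0, degenerate=True)
    h, p = stats.kruskal(*groups)
    return KWResult(float(h), k - 1, float(p))


def kruskal_wallis_exact_p(
    groups: Sequence[np.ndarray], max_arrangements: int = 200_000
) -> float:
    """Exact permutation P for the Kruskal-Wallis H statistic.

    Enumerates all assignments of the pooled observations to the group sizes
    (feasible for small tables) and returns the fraction with H at least the
    observed value.  Raises when the arrangement count exceeds
    ``max_arrangements``.
    """
    from math import comb

    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    n_arr = 1
    rem = n
    for m in sizes[:-1]:
        n_arr *= comb(rem, m)
        rem -= m
    if n_arr > max_arrangements:
        raise ValueError(f"{n_arr} arrangements exceed limit {max_arrangements}")
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    observed = _h_observed(ranks, sizes, tie_term)

    count_ge = 0
    total = 0
    idx_all = tuple(range(n))

    def recurse(remaining: tuple[int, ...], gi: int, chosen_ranks: list[float]):
        nonlocal count_ge, total
        if gi == len(sizes) - 1:
            rank_sets = chosen_ranks + [sum(ranks[list(remaining)])]
            h = _h_from_rank_sums(rank_sets, sizes, n, tie_term)
            total += 1
            if h >= observed - 1e-12:
                count_ge += 1
            return
        for combo in combinations(remaining, sizes[gi]):
            rest = tuple(x for x in remaining if x not in set(combo))
            recurse(rest, gi + 1, chosen_ranks + [sum(ranks[list(combo)])])

    recurse(idx_all, 0, [])
    return count_ge / total


def _h_observed(ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    sums = []
    start = 0
    for m in sizes:
        sums.append(float(ranks[start : start + m].sum()))
        start += m
    return _h_from_rank_sums(sums, sizes, len(ranks), tie_term)


def _h_from_rank_sums(rank_sums, sizes, n, tie_term) -> float:
    h = 12.0 / (n * (n + 1)) * sum(r * r / m for r, m in zip(rank_sums, sizes)) - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and P (Royston approximation, 3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if len(values) > 5000:
        raise ValueError("Shapiro-Wilk approximation valid up to n = 5000")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def leave_one_group_out(groups: Mapping[str, np.ndarray]) -> dict[str, KWResult]:
    """Kruskal-Wallis recomputed with each group excluded in turn."""
    if len(groups) < 3:
        raise ValueError("need at least 3 groups to drop one")
    out = {}
    for name in groups:
        rest = [g for k, g in groups.items() if k != name]
        out[name] = kruskal_wallis(rest)
    return out
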