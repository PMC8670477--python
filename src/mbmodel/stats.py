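"""Comparison statistics: pairwise rank tests, Holm correction, letters.

Matched model instances (same PN–KC connectivity seed) are compared with the
Wilcoxon signed-rank test; unmatched groups with the Mann–Whitney rank-sum
test.  P-values are Holm–Bonferroni adjusted across all pairs, and a
compact-letter display summarizes the significance groups (groups sharing a
letter are not significantly different).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["pairwise_tests", "holm_adjust", "compact_letters", "bootstrap_ci"]

MIN_N = 6


def holm_adjust(pvalues) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def pairwise_tests(
    groups: dict[str, np.ndarray],
    paired: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise comparisons between named groups of observations.

    Signed-rank for paired data (equal lengths, matched order), rank-sum
    otherwise.  Returns a tidy frame with raw and Holm-adjusted p-values
    plus each group's letter from :func:`compact_letters`.  Pairs with fewer
    than 6 observations per group get NaN p-values (insufficient n).
    """
    names = list(groups)
    rows = []
    for a, b in combinations(names, 2):
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if min(len(xa), len(xb)) < MIN_N:
            p = np.nan
        elif paired:
            if len(xa) != len(xb):
                raise ValueError("paired comparison needs equal group sizes")
            d = xa - xb
            if np.allclose(d, 0):
                p = 1.0
            else:
                p = sps.wilcoxon(xa, xb).pvalue
        else:
            p = sps.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
        rows.append({"group_a": a, "group_b": b, "p_raw": p})
    df = pd.DataFrame(rows)
    defined = df["p_raw"].notna()
    adj = np.full(len(df), np.nan)
    if defined.any():
        adj[defined.to_numpy()] = holm_adjust(df.loc[defined, "p_raw"])
    df["p_holm"] = adj
    df["significant"] = df["p_holm"] < alpha

    sig = {
        (r.group_a, r.group_b): bool(r.significant)
        for r in df.itertuples()
        if not np.isnan(r.p_holm)
    }
    letters = compact_letters(names, sig, medians={k: float(np.median(v)) for k, v in groups.items()})
    df["letters_a"] = df["group_a"].map(letters)
    df["letters_b"] = df["group_b"].map(letters)
    return df


def compact_letters(
    names: list[str],
    significant: dict[tuple[str, str], bool],
    medians: dict[str, float] | None = None,
) -> dict[str, str]:
    """Greedy compact-letter display.

    Insert-and-absorb: groups are visited in descending median order; each
    joins every existing letter whose members are all non-significantly
    different from it, or opens a new letter, which then absorbs every
    earlier group compatible with all its members.  ``significant`` maps
    unordered name pairs to whether they differ; missing pairs are treated
    as not different.
    """
    def differs(a: str, b: str) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    if medians:
        names = sorted(names, key=lambda n: -medians[n])
    letter_members: list[list[str]] = []
    assignment: dict[str, set[int]] = {n: set() for n in names}
    for k, n in enumerate(names):
        placed = False
        for i, members in enumerate(letter_members):
            if all(not differs(n, m) for m in members):
                members.append(n)
                assignment[n].add(i)
                placed = True
        if not placed:
            new = [n]
            for m in names[:k]:  # absorb compatible earlier groups
                if all(not differs(m, x) for x in new):
                    new.append(m)
            idx = len(letter_members)
            letter_members.append(new)
            for m in new:
                assignment[m].add(idx)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {
        n: "".join(alphabet[i % 26] for i in sorted(idx))
        for n, idx in assignment.items()
    }


def bootstrap_ci(
    values,
    n_boot: int = 10_000,
    level: float = 0.95,
    rng_seed: int = 0,
    statistic=np.median,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval over seeds/instances."""
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    boots = statistic(x[idx], axis=1)
    lo = (1 - level) / 2
    return (
        float(np.quantile(boots, lo)),
        float(np.quantile(boots, 1 - lo)),
    )
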