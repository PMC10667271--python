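"""Phytohormone statistics: one-way ANOVA across dehydration states and
compact letter displays.

Concentrations (pmol/mg) of ABA, salicylic acid and jasmonoyl-isoleucine
are compared across dehydration states (recovery is an ordinary level of
the state factor). Significance marks follow the convention that states
sharing a letter are not significantly different in the pairwise
post-hoc test. The post-hoc default is Tukey HSD — the standard
generator of letter displays; pairwise Welch t-tests with BH adjustment
are offered as an alternative. Letters are assigned by the
insert-and-absorb algorithm over states ordered by descending mean,
which guarantees the share-a-letter relation equals the
non-significance relation exactly.
"""

from __future__ import annotations

from itertools import combinations
from string import ascii_lowercase

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .diffexpr import adjust_bh

__all__ = ["anova_oneway", "pairwise_nonsignificance", "compact_letters",
           "letters_from_nonsignificance"]


def _groups(meas: pd.DataFrame, hormone: str):
    sub = meas[meas["hormone"] == hormone]
    if sub.empty:
        raise ValueError(f"no measurements for hormone {hormone!r}")
    grouped = {s: g["conc_pmol_per_mg"].to_numpy(dtype=float)
               for s, g in sub.groupby("state", sort=False)}
    if len(grouped) < 2:
        raise ValueError(f"hormone {hormone!r} has a single state; "
                         "ANOVA needs >= 2")
    for s, v in grouped.items():
        if len(v) < 2:
            raise ValueError(f"state {s!r} has {len(v)} replicate(s); need >= 2")
    return grouped


def anova_oneway(meas: pd.DataFrame, hormone: str):
    """Classical one-way ANOVA of concentration across states.

    Returns ``(F, p)``. A panel in which every observation is equal has
    no between- or within-group variance; by convention F = 0, p = 1.
    """
    grouped = _groups(meas, hormone)
    allvals = np.concatenate(list(grouped.values()))
    if np.ptp(allvals) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*grouped.values())
    return float(f), float(p)


def pairwise_nonsignificance(meas: pd.DataFrame, hormone: str,
                             alpha: float = 0.05,
                             method: str = "tukey") -> pd.DataFrame:
    """Boolean state x state matrix: True where the pair is NOT
    significantly different at ``alpha``.

    method="tukey" uses Tukey's HSD on the pooled one-way layout;
    method="welch-bh" uses all pairwise Welch t-tests with BH
    adjustment across the pairs.
    """
    grouped = _groups(meas, hormone)
    states = list(grouped)
    nonsig = pd.DataFrame(True, index=states, columns=states)
    pairs = list(combinations(states, 2))
    if not pairs:
        return nonsig

    allvals = np.concatenate(list(grouped.values()))
    if np.ptp(allvals) == 0:  # identical data: nothing is significant
        return nonsig

    if method == "tukey":
        endog = allvals
        labels = np.concatenate([[s] * len(grouped[s]) for s in states])
        res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
        uniq = list(res.groupsunique)
        for (i, j), reject in zip(combinations(range(len(uniq)), 2), res.reject):
            a, b = uniq[i], uniq[j]
            nonsig.loc[a, b] = nonsig.loc[b, a] = not bool(reject)
    elif method == "welch-bh":
        praw = []
        for a, b in pairs:
            if np.ptp(grouped[a]) == 0 and np.ptp(grouped[b]) == 0:
                p = 1.0 if grouped[a][0] == grouped[b][0] else 0.0
            else:
                p = stats.ttest_ind(grouped[a], grouped[b], equal_var=False)[1]
            praw.append(float(p))
        padj = adjust_bh(praw)
        for (a, b), p in zip(pairs, padj):
            nonsig.loc[a, b] = nonsig.loc[b, a] = p >= alpha
    else:
        raise ValueError(f"unknown method {method!r}")
    return nonsig


def letters_from_nonsignificance(nonsig: pd.DataFrame,
                                 order: list | None = None) -> dict:
    """Insert-and-absorb compact letter display from a non-significance
    relation.

    Starts with one letter column containing every group; for each
    significant pair, every column containing both is split into two
    columns, one without each member; columns that become subsets of
    another are absorbed. Every non-significant pair then shares at
    least one column and no column contains a significant pair, so the
    share-a-letter relation equals the relation exactly.

    ``order`` fixes letter precedence (conventionally descending group
    mean); defaults to the matrix's own order.
    """
    groups = list(order) if order is not None else list(nonsig.index)
    columns = [set(groups)]
    for a, b in combinations(groups, 2):
        if nonsig.loc[a, b]:
            continue
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empties, duplicates and any proper subset
        uniq = []
        for col in new_columns:
            if col and col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < o for o in uniq)]

    # order columns by the precedence of their first member
    pos = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(pos[g] for g in col) if col else len(groups))
    columns = [c for c in columns if c]

    if len(columns) > len(ascii_lowercase):
        raise ValueError("more letter columns than available letters")
    display = {g: "" for g in groups}
    for letter, col in zip(ascii_lowercase, columns):
        for g in col:
            display[g] += letter
    return display


def compact_letters(meas: pd.DataFrame, hormone: str, alpha: float = 0.05,
                    method: str = "tukey") -> dict:
    """Compact letter display for one hormone across states.

    States sharing a letter are not significantly different at
    ``alpha`` in the chosen post-hoc test. Letters are ordered by
    descending state mean (the highest-mean state gets "a").
    """
    grouped = _groups(meas, hormone)
    nonsig = pairwise_nonsignificance(meas, hormone, alpha=alpha, method=method)
    order = sorted(grouped, key=lambda s: -float(np.mean(grouped[s])))
    return letters_from_nonsignificance(nonsig, order=order)
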