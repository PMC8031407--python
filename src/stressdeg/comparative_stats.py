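"""Comparative statistics: chi-square homogeneity with FDR-controlled
post-hoc pairwise tests, one-way ANOVA with Tukey-Kramer, Bartlett's
variance-homogeneity test, and the leaf relative-water-content formula.

Class-proportion tables (u/d/i per genotype, or u/d/m for the core set)
are compared with the uncorrected Pearson chi-square; when the omnibus
test is significant at p < 0.05, all pairwise 2xC sub-tables are tested
and BH-adjusted at a 5 % FDR, summarised as a compact letter display
(groups sharing no letter differ significantly).  All tests run on
untransformed data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de_consensus import benjamini_hochberg
from .io_model import ValidationError


def chi_square(table: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square of homogeneity, no continuity correction.

    Returns (statistic, df, pvalue); df = (rows-1)(cols-1).  Raises on a
    zero row or column margin.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("need a table with >=2 rows and >=2 columns")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValidationError("zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def letter_display(items: Sequence[str],
                   significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: items sharing a letter are NOT significantly
    different; a significant pair shares no letter.

    Letters are assigned to the maximal cliques of the non-significance
    graph (exact enumeration; group counts here are always small).
    """
    sig = {frozenset(p) for p in significant_pairs}
    n = len(items)
    adj = [[i == j or frozenset((items[i], items[j])) not in sig
            for j in range(n)] for i in range(n)]
    cliques: list[frozenset[int]] = []
    for r in range(n, 0, -1):
        for combo in itertools.combinations(range(n), r):
            if all(adj[i][j] for i, j in itertools.combinations(combo, 2)):
                cand = frozenset(combo)
                if not any(cand < c for c in cliques):
                    cliques.append(cand)
    cliques = [c for c in cliques if not any(c < o for o in cliques)]
    cliques.sort(key=lambda c: (min(c), -len(c)))
    letters: dict[str, str] = {it: "" for it in items}
    for k, clique in enumerate(cliques):
        letter = chr(ord("a") + k)
        for i in sorted(clique):
            letters[items[i]] += letter
    return letters


@dataclass
class PosthocResult:
    omnibus_stat: float
    omnibus_df: int
    omnibus_p: float
    pairs: pd.DataFrame  # group1, group2, statistic, pvalue, fdr, significant
    letters: dict[str, str]
    ran_posthoc: bool


def posthoc_pairwise(table: pd.DataFrame, fdr: float = 0.05,
                     omnibus_alpha: float = 0.05) -> PosthocResult:
    """Omnibus chi-square plus, when significant, pairwise 2xC comparisons.

    ``table`` is groups (index) x classes (columns), integer counts.
    Pairwise p-values are BH-adjusted over the set of pairs; letters
    derive from the adjusted decisions.  The post-hoc stage is skipped
    (all groups share one letter) when the omnibus p >= omnibus_alpha.
    """
    if len(table) < 3:
        raise ValidationError("post-hoc needs >=3 groups")
    groups = list(table.index)
    stat, df, p = chi_square(table.to_numpy())
    if p >= omnibus_alpha:
        empty = pd.DataFrame(columns=["group1", "group2", "statistic",
                                      "pvalue", "fdr", "significant"])
        return PosthocResult(stat, df, p, empty,
                             {g: "a" for g in groups}, False)
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        sub = table.loc[[g1, g2]].to_numpy(dtype=float)
        sub = sub[:, sub.sum(axis=0) > 0]  # drop empty classes for the pair
        if sub.shape[1] < 2:
            s, pp = 0.0, 1.0
        else:
            s, _, pp = chi_square(sub)
        rows.append({"group1": g1, "group2": g2, "statistic": s, "pvalue": pp})
    pairs = pd.DataFrame(rows)
    pairs["fdr"] = benjamini_hochberg(pairs["pvalue"].to_numpy())
    pairs["significant"] = pairs["fdr"] <= fdr
    sig_pairs = {(r.group1, r.group2)
                 for r in pairs.itertuples() if r.significant}
    return PosthocResult(stat, df, p, pairs,
                         letter_display(groups, sig_pairs), True)


def anova_tukey(groups: Mapping[str, Sequence[float]],
                alpha: float = 0.05) -> dict:
    """One-way ANOVA followed by Tukey-Kramer all-pairs comparisons.

    Returns {"F", "pvalue", "pairs": DataFrame(group1, group2, pvalue,
    significant), "letters"}.  When every observation is identical the F
    statistic is reported as 0 with p = 1 (no variance to partition).
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValidationError("need >=2 groups")
    if any(len(d) < 2 for d in data):
        raise ValidationError("every group needs n >= 2")
    flat = np.concatenate(data)
    if np.ptp(flat) == 0:
        pairs = pd.DataFrame(
            [{"group1": a, "group2": b, "pvalue": 1.0, "significant": False}
             for a, b in itertools.combinations(names, 2)])
        return {"F": 0.0, "pvalue": 1.0, "pairs": pairs,
                "letters": {g: "a" for g in names}}
    F, p = stats.f_oneway(*data)
    res = stats.tukey_hsd(*data)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        pv = float(res.pvalue[i, j])
        rows.append({"group1": names[i], "group2": names[j],
                     "pvalue": pv, "significant": pv <= alpha})
    pairs = pd.DataFrame(rows)
    sig = {(r.group1, r.group2) for r in pairs.itertuples() if r.significant}
    return {"F": float(F), "pvalue": float(p), "pairs": pairs,
            "letters": letter_display(names, sig)}


def bartlett(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]
             ) -> tuple[float, float]:
    """Bartlett's test of variance homogeneity against chi-square(k-1)."""
    data = (list(groups.values()) if isinstance(groups, Mapping) else list(groups))
    arrs = [np.asarray(d, dtype=float) for d in data]
    if any(len(a) < 2 for a in arrs):
        raise ValidationError("every group needs n >= 2")
    if any(a.var(ddof=1) == 0 for a in arrs):
        raise ValidationError("zero-variance group")
    stat, p = stats.bartlett(*arrs)
    return float(stat), float(p)


def rwc(fw: float, tw: float, dw: float) -> float:
    """Leaf relative water content, 100 * (FW - DW) / (TW - DW).

    FW, TW, DW are fresh, turgid and dry weights with TW >= FW >= DW > 0.
    """
    if not (tw >= fw >= dw > 0):
        raise ValidationError("require TW >= FW >= DW > 0")
    if tw == dw:
        raise ValidationError("TW equals DW: relative water content undefined")
    return 100.0 * (fw - dw) / (tw - dw)
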