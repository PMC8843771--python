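"""Kruskal–Wallis across community groups, Dunn post-hoc letters, and
BH-adjusted Spearman screens of community indices against environment.

The Kruskal–Wallis H (tie-corrected, chi-square reference with k−1 df)
asks which environmental variables differ among the SOM-derived community
groups.  Pairwise follow-up uses Dunn-type rank z statistics with a
Benjamini–Hochberg correction, summarised as a compact letter display:
groups that share a letter are not significantly different.

The Spearman screen correlates each of the five community indices with
each environmental variable (rho from ranked Pearson with average ranks;
two-tailed t test via t = rho·sqrt((n−2)/(1−rho²))), adjusting p within
each index's set of variables by Benjamini–Hochberg.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class KWResult:
    variable: str
    statistic: float
    df: int
    p_value: float
    n: int
    letters: dict = field(default_factory=dict)


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH adjustment, monotone, capped at 1, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def kruskal_wallis(values, groups) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p (k−1 df)."""
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups)).reset_index(drop=True)
    samples = [v[g.values == lev].to_numpy() for lev in pd.unique(g)]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    k = len(samples)
    if np.ptp(v.to_numpy()) == 0:      # all identical: no evidence at all
        return KWResult("", 0.0, k - 1, 1.0, len(v))
    h, p = sps.kruskal(*samples)
    return KWResult("", float(h), k - 1, float(p), len(v))


def dunn_pairwise(values, groups) -> pd.DataFrame:
    """Dunn-type pairwise rank comparisons with tie correction, BH-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1)))·(1/n_i + 1/n_j))
    with T = Σ(t³−t) over tied value groups.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    n = len(v)
    ranks = sps.rankdata(v)
    levels = list(pd.unique(pd.Series(g)))
    _, counts = np.unique(v, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            ia, ib = g == levels[a], g == levels[b]
            na, nb = ia.sum(), ib.sum()
            se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (ranks[ia].mean() - ranks[ib].mean()) / se
                p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": levels[a], "group_b": levels[b],
                         "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    return out


def compact_letters(pairwise: pd.DataFrame, groups, alpha: float = 0.05) -> dict:
    """Compact letter display: groups share a letter iff not significantly
    different (on the BH-adjusted pairwise p)."""
    levels = list(groups)
    graph = nx.Graph()
    graph.add_nodes_from(levels)
    for _, row in pairwise.iterrows():
        if row["p_adj"] >= alpha:
            graph.add_edge(row["group_a"], row["group_b"])
    cliques = sorted(nx.find_cliques(graph),
                     key=lambda c: min(levels.index(m) for m in c))
    letters = {lev: "" for lev in levels}
    alphabet = string.ascii_lowercase
    for i, clique in enumerate(cliques):
        ch = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for member in clique:
            letters[member] += ch
    return {lev: "".join(sorted(letters[lev])) for lev in levels}


def posthoc_letters(values, groups, alpha: float = 0.05,
                    warn_omnibus: bool = True) -> dict:
    """Dunn pairwise tests + compact letter display for one variable."""
    kw = kruskal_wallis(values, groups)
    if warn_omnibus and kw.p_value >= alpha:
        warnings.warn("omnibus Kruskal–Wallis not significant; letters are exploratory")
    pw = dunn_pairwise(values, groups)
    levels = list(pd.unique(pd.Series(np.asarray(groups))))
    return compact_letters(pw, levels, alpha=alpha)


def kruskal_by_variable(env: pd.DataFrame, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal–Wallis of every environmental variable across groups,
    with post-hoc letters for the significant ones."""
    g = pd.Series(groups).reindex(env.index)
    if g.isna().any():
        raise ValueError("group labels missing for some sites")
    rows = []
    for var in env.columns:
        kw = kruskal_wallis(env[var].to_numpy(), g.to_numpy())
        letters = {}
        if kw.p_value < alpha:
            letters = posthoc_letters(env[var].to_numpy(), g.to_numpy(),
                                      alpha=alpha, warn_omnibus=False)
        rows.append({"variable": var, "H": kw.statistic, "df": kw.df,
                     "p": kw.p_value, "n": kw.n,
                     "letters": ";".join(f"{k}:{v}" for k, v in letters.items())})
    return pd.DataFrame(rows)


def spearman_screen(indices: pd.DataFrame, env: pd.DataFrame,
                    adjust_within: str = "index") -> pd.DataFrame:
    """Spearman rho/p for every (community index, environmental variable) pair.

    p-values are BH-adjusted within each index's set of variables (one row
    of the published-style grid) by default, or globally with
    ``adjust_within="all"``.  Pairs with zero variance are flagged
    undefined (NaN rho).
    """
    common = indices.index.intersection(env.index)
    idx, ev = indices.loc[common], env.loc[common]
    rows = []
    for ind in idx.columns:
        for var in ev.columns:
            a = idx[ind].to_numpy(dtype=float)
            b = ev[var].to_numpy(dtype=float)
            mask = ~(np.isnan(a) | np.isnan(b))
            a, b = a[mask], b[mask]
            n = len(a)
            if n < 4 or np.ptp(a) == 0 or np.ptp(b) == 0:
                rows.append({"index": ind, "variable": var, "rho": np.nan,
                             "p": np.nan, "n": n, "undefined": True})
                continue
            rho, p = sps.spearmanr(a, b)
            rows.append({"index": ind, "variable": var, "rho": float(rho),
                         "p": float(p), "n": n, "undefined": False})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    if adjust_within == "all":
        ok = ~out["p"].isna()
        out.loc[ok, "p_adj"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    else:
        for ind in out["index"].unique():
            ok = (out["index"] == ind) & ~out["p"].isna()
            if ok.any():
                out.loc[ok, "p_adj"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    return out
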