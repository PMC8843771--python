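"""Dufrêne–Legendre indicator-value (IndVal) analysis with permutation tests.

For species i and site group j,

    A_ij    = mean abundance of i in group j / sum over groups of those means
    B_ij    = fraction of group-j sites where i is present
    IndVal  = A_ij * B_ij * 100

A (specificity) is 1 when the species' abundance concentrates in one group;
B (fidelity) is 1 when it occurs at every site of the group.  The species
statistic is its maximum IndVal over groups; significance comes from
permuting whole-site group labels, with the add-one estimator
p = (1 + #{permuted >= observed}) / (1 + n_perm), so p is never exactly 0.

A species is flagged an indicator of its best group when IndVal >= 50 and
p < alpha; species that are significant but peak below 50 are flagged
separately (sub-50 significant), as is conventional in biomonitoring
reports.  Raw (untransformed) densities feed the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CommunityMatrix


@dataclass
class IndValTable:
    """Per-(species, group) components and per-species summary."""

    A: pd.DataFrame          # species × group specificity
    B: pd.DataFrame          # species × group fidelity
    indval: pd.DataFrame     # species × group, 0..100
    summary: pd.DataFrame    # species-level: best_group, indval_max, p_value, flags


def _abundance_and_groups(community, partition):
    if isinstance(community, CommunityMatrix):
        ab = community.abundance
    else:
        ab = community
    groups = partition.site_group if hasattr(partition, "site_group") else partition
    groups = pd.Series(groups).reindex(ab.index)
    if groups.isna().any():
        missing = groups.index[groups.isna()].tolist()
        raise ValueError(f"sites without a group label: {missing}")
    return ab, groups


def _components(x: np.ndarray, gidx: np.ndarray, sizes: np.ndarray):
    """Vectorized A, B, IndVal for abundance x (sites × species).

    ``gidx`` maps site → group position; ``sizes`` are group site counts.
    Returns arrays of shape (species, groups).
    """
    g = sizes.shape[0]
    n, s = x.shape
    sums = np.zeros((g, s))
    pres = np.zeros((g, s))
    np.add.at(sums, gidx, x)
    np.add.at(pres, gidx, (x > 0).astype(float))
    means = sums / sizes[:, None]             # groups × species
    tot = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(tot > 0, means / np.where(tot > 0, tot, 1.0), 0.0)
    b = pres / sizes[:, None]
    return a.T, b.T, (a * b).T * 100.0


def indval_components(community, partition) -> IndValTable:
    """A, B and IndVal for every (species, group) pair.

    Species absent everywhere get IndVal 0 in every group and a warning.
    """
    ab, groups = _abundance_and_groups(community, partition)
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("IndVal needs at least 2 groups")
    gidx = groups.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    sizes = np.bincount(gidx, minlength=len(levels)).astype(float)
    a, b, iv = _components(ab.to_numpy(dtype=float), gidx, sizes)

    A = pd.DataFrame(a, index=ab.columns, columns=levels)
    B = pd.DataFrame(b, index=ab.columns, columns=levels)
    IV = pd.DataFrame(iv, index=ab.columns, columns=levels)
    absent = ab.sum(axis=0) == 0
    if absent.any():
        warnings.warn(f"species absent everywhere: {list(ab.columns[absent])}")

    best_pos = iv.argmax(axis=1)
    summary = pd.DataFrame({
        "best_group": [levels[i] for i in best_pos],
        "indval_max": iv.max(axis=1),
        "absent_flag": absent.to_numpy(),
    }, index=ab.columns)
    summary.index.name = "species"
    return IndValTable(A=A, B=B, indval=IV, summary=summary)


def indval_permutation_test(community, partition, n_perm: int = 999,
                            seed: int = 0) -> IndValTable:
    """Permutation p-values for the max-over-groups IndVal of each species.

    Whole-site group labels are permuted; ``p = (1 + #{perm >= obs}) /
    (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    table = indval_components(community, partition)
    ab, groups = _abundance_and_groups(community, partition)
    levels = list(table.indval.columns)
    gidx = groups.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    sizes = np.bincount(gidx, minlength=len(levels)).astype(float)
    x = ab.to_numpy(dtype=float)

    obs = table.indval.to_numpy().max(axis=1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(gidx)
        _, _, iv = _components(x, perm, sizes)
        exceed += iv.max(axis=1) >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    table.summary["p_value"] = p
    return table


def classify_indicators(table, threshold: float = 50.0,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Apply the indicator rule to a species-level IndVal table.

    Accepts an :class:`IndValTable` (after the permutation test) or a plain
    DataFrame with columns ``species``, ``group``, ``indval`` and ``p``
    (one row per species, e.g. a published indicator table).  Adds
    ``indicator_flag`` (IndVal >= threshold and p < alpha) and
    ``sub50_flag`` (p < alpha but IndVal below threshold) and sorts by
    group then descending IndVal.
    """
    if isinstance(table, IndValTable):
        if "p_value" not in table.summary.columns:
            raise ValueError("run indval_permutation_test first")
        df = table.summary.reset_index()[
            ["species", "best_group", "indval_max", "p_value"]]
        df = df.rename(columns={"best_group": "group", "indval_max": "indval",
                                "p_value": "p"})
    else:
        df = pd.DataFrame(table).copy()
        required = {"species", "group", "indval", "p"}
        if not required.issubset(df.columns):
            raise ValueError(f"table needs columns {sorted(required)}")
    df["indicator_flag"] = (df["indval"] >= threshold) & (df["p"] < alpha)
    df["sub50_flag"] = (df["p"] < alpha) & (df["indval"] < threshold)
    df = df.sort_values(["group", "indval"],
                        ascending=[True, False]).reset_index(drop=True)
    return df
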