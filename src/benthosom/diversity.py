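"""Per-site community indices and grouped summaries.

Five indices per site: species richness S, total abundance N (summed
density, ind./m²), biomass (g/m²), Shannon diversity H' = −Σ p_i ln p_i
(natural log) and Pielou's evenness J = H'/ln S.  J is undefined (NaN) for
S ≤ 1: a one-species community has no evenness.  Summaries report mean ±
sample SD per lake, season or community group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .data import CommunityMatrix


def shannon(counts, base: float = np.e) -> float:
    """Shannon diversity of one abundance vector (0 when ≤ 1 taxon present)."""
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        return 0.0
    return float(entropy(arr, base=base))


def diversity_per_site(community: CommunityMatrix, base: float = np.e) -> pd.DataFrame:
    """Richness, abundance, biomass, Shannon H' and Pielou J per site."""
    ab = community.abundance
    richness = (ab > 0).sum(axis=1)
    h = ab.apply(lambda row: shannon(row.to_numpy(), base=base), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = h / np.log(richness.where(richness > 1))
    out = pd.DataFrame({
        "richness": richness,
        "abundance": ab.sum(axis=1),
        "biomass": community.biomass,
        "shannon": h,
        "pielou": j,
    })
    out.index.name = "site_id"
    return out


def summarize_by(table: pd.DataFrame, by, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean ± sample SD of each index per level of a grouping key.

    ``by`` is either a per-site Series of labels, or the name of a metadata
    column (``lake`` / ``season``) looked up in ``meta``.  Levels with a
    single site get SD 0 by convention and are identifiable by ``n == 1``.
    """
    if isinstance(by, str):
        if meta is None or by not in meta.columns:
            raise KeyError(f"unknown grouping key {by!r}")
        key = meta[by]
    else:
        key = pd.Series(by).reindex(table.index)
        if key.isna().any():
            raise ValueError("grouping labels missing for some sites")
    pieces = {}
    grouped = table.groupby(key)
    pieces["n"] = grouped.size()
    for col in table.columns:
        pieces[f"{col}_mean"] = grouped[col].mean()
        sd = grouped[col].std(ddof=1)
        pieces[f"{col}_sd"] = sd.where(pieces["n"] > 1, 0.0)
    out = pd.DataFrame(pieces)
    out.index.name = key.name or "level"
    return out
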