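"""Data containers, delimited-text I/O and pre-analysis transforms.

The central object is the :class:`CommunityMatrix`: a site × taxon table of
benthic macroinvertebrate densities (individuals/m²) with per-site biomass
(g/m²) and site metadata (lake, season).  Environmental chemistry travels in
an :class:`EnvMatrix` whose canonical 13 variables are water depth (WD, m),
water temperature (WT, °C), dissolved oxygen (DO, mg/L), pH, conductivity
(COND, µS/cm), permanganate index (CODMn, mg/L), total phosphorus (TP, mg/L),
total nitrogen (TN, mg/L), ammonium (NH3N), nitrate (NO3N), nitrite (NO2N,
all mg/L), chlorophyll a (Chla, µg/L) and suspended solids (SS, mg/L).

Two transforms are applied before multivariate analysis: ln(x+1) for
abundances (and ln(x) for strictly positive environmental variables, pH
exempt), and the Hellinger transform — square roots of row-relative
abundances — which makes Euclidean-based ordination appropriate for
species data.  Missing values are refused, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENV_VARIABLES = (
    "WD", "WT", "DO", "pH", "COND", "CODMn", "TP",
    "TN", "NH3N", "NO3N", "NO2N", "Chla", "SS",
)
#: variables exempt from the log transform (already on a log scale)
LOG_EXEMPT = ("pH",)

SEASONS = ("spring", "summer", "autumn")

HIGHER_GROUPS = (
    "aquatic insect", "gastropod", "bivalve",
    "oligochaete", "leech", "crustacean",
)

META_COLUMNS = ("site_id", "lake", "season", "biomass_g_m2")


class ValidationError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass
class CommunityMatrix:
    """Site × taxon density matrix with aligned biomass and metadata.

    Parameters
    ----------
    abundance
        DataFrame indexed by site_id, one column per taxon, densities in
        individuals/m².  Non-negative, no missing cells.
    biomass
        Per-site total biomass in g/m², indexed like ``abundance``.
    meta
        Per-site metadata with columns ``lake`` and ``season``.
    taxon_groups
        Optional mapping taxon → higher group (one of
        :data:`HIGHER_GROUPS`).
    """

    abundance: pd.DataFrame
    biomass: pd.Series
    meta: pd.DataFrame
    taxon_groups: pd.Series | None = None

    def __post_init__(self) -> None:
        self.abundance.index.name = "site_id"
        self.biomass.index.name = "site_id"
        self.meta.index.name = "site_id"
        self.validate()

    # -- contract -----------------------------------------------------
    def validate(self) -> None:
        idx = self.abundance.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site_id: {dups}")
        if self.abundance.columns.has_duplicates:
            dups = self.abundance.columns[
                self.abundance.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon labels: {dups}")
        if self.abundance.isna().any().any():
            raise ValidationError("missing abundance cells; no imputation is performed")
        if (self.abundance.to_numpy() < 0).any():
            raise ValidationError("negative abundance entries")
        if not idx.equals(self.biomass.index):
            raise ValidationError("biomass index does not match abundance sites")
        if self.biomass.isna().any() or (self.biomass < 0).any():
            raise ValidationError("biomass must be present and non-negative")
        if not idx.equals(self.meta.index):
            raise ValidationError("meta index does not match abundance sites")
        for col in ("lake", "season"):
            if col not in self.meta.columns:
                raise ValidationError(f"meta lacks required column {col!r}")

    @property
    def sites(self) -> list:
        return list(self.abundance.index)

    @property
    def taxa(self) -> list:
        return list(self.abundance.columns)

    @property
    def n_sites(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.abundance.shape[1]


@dataclass
class EnvMatrix:
    """Site × environmental-variable matrix (units as sampled in the field)."""

    values: pd.DataFrame
    log_exempt: tuple = LOG_EXEMPT

    def __post_init__(self) -> None:
        self.values.index.name = "site_id"
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site_id: {dups}")
        if self.values.isna().any().any():
            raise ValidationError("missing environmental cells; no imputation")
        bad = []
        for var in self.values.columns:
            if var in self.log_exempt:
                continue
            col = self.values[var]
            for site in col.index[col <= 0]:
                bad.append((site, var))
        if bad:
            raise ValidationError(
                "non-positive values in log-scheduled variables: " + str(bad))

    @property
    def sites(self) -> list:
        return list(self.values.index)

    @property
    def variables(self) -> list:
        return list(self.values.columns)


# ---------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------

def _read_table(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=sep)


def read_community(path, sep: str | None = None,
                   taxon_groups: dict | pd.Series | None = None) -> CommunityMatrix:
    """Read a community file: site_id, lake, season, biomass_g_m2, then taxa.

    The delimiter is auto-detected (comma or tab) unless ``sep`` is given.
    Duplicate sites, negative densities and missing cells are hard errors.
    """
    df = _read_table(path, sep)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"community file lacks columns {missing}")
    dup = df["site_id"][df["site_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate site_id: {sorted(dup.unique().tolist())}")
    df = df.set_index("site_id")
    taxa = [c for c in df.columns if c not in META_COLUMNS]
    groups = None
    if taxon_groups is not None:
        groups = pd.Series(dict(taxon_groups) if not isinstance(taxon_groups, pd.Series)
                           else taxon_groups).reindex(taxa)
    return CommunityMatrix(
        abundance=df[taxa].astype(float),
        biomass=df["biomass_g_m2"].astype(float),
        meta=df[["lake", "season"]],
        taxon_groups=groups,
    )


def write_community(cm: CommunityMatrix, path, sep: str = "\t") -> None:
    out = pd.concat(
        [cm.meta[["lake", "season"]],
         cm.biomass.rename("biomass_g_m2"),
         cm.abundance], axis=1)
    out.index.name = "site_id"
    out.to_csv(path, sep=sep)


def read_environment(path, sep: str | None = None) -> EnvMatrix:
    """Read an environment file: site_id then variable codes (subset allowed)."""
    df = _read_table(path, sep)
    if "site_id" not in df.columns:
        raise ValidationError("environment file lacks a site_id column")
    dup = df["site_id"][df["site_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate site_id: {sorted(dup.unique().tolist())}")
    df = df.set_index("site_id")
    unknown = [c for c in df.columns if c not in ENV_VARIABLES]
    if unknown:
        warnings.warn(f"unrecognised environmental variables kept as-is: {unknown}")
    return EnvMatrix(values=df.astype(float))


def write_environment(env: EnvMatrix, path, sep: str = "\t") -> None:
    out = env.values.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------

def log_transform(x, applied_to: str = "abundance"):
    """ln(x+1) for abundances (zeros abound); ln(x) for environment.

    ``applied_to`` selects the mode: ``"abundance"`` requires x ≥ 0 and uses
    ln(x+1); ``"environment"`` requires x > 0 and uses ln(x).
    """
    arr = x.to_numpy() if hasattr(x, "to_numpy") else np.asarray(x, float)
    if applied_to == "abundance":
        if (arr < 0).any():
            raise ValidationError("negative values not allowed for ln(x+1)")
        out = np.log1p(arr)
    elif applied_to == "environment":
        if (arr <= 0).any():
            raise ValidationError("non-positive values not allowed for ln(x)")
        out = np.log(arr)
    else:
        raise ValueError(f"unknown transform target {applied_to!r}")
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    return out


def log_environment(env: EnvMatrix | pd.DataFrame,
                    exempt: tuple = LOG_EXEMPT) -> pd.DataFrame:
    """ln-transform every environmental variable except the exempt ones (pH)."""
    df = env.values if isinstance(env, EnvMatrix) else env
    out = df.copy().astype(float)
    for col in out.columns:
        if col in exempt:
            continue
        out[col] = log_transform(out[col], applied_to="environment")
    return out


def hellinger_transform(abundance: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: y'_ij = sqrt(y_ij / row_sum_i).

    Every transformed row has unit sum of squares.  A site with all-zero
    abundance has no defined composition and is refused.
    """
    arr = abundance.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative abundance entries")
    rowsum = arr.sum(axis=1)
    zero = np.flatnonzero(rowsum == 0)
    if zero.size:
        names = [abundance.index[i] for i in zero]
        raise ValidationError(f"zero-abundance sites cannot be Hellinger-transformed: {names}")
    out = np.sqrt(arr / rowsum[:, None])
    return pd.DataFrame(out, index=abundance.index, columns=abundance.columns)


def standardize(x: pd.DataFrame) -> pd.DataFrame:
    """Center to mean 0 and scale to sample SD 1, column-wise."""
    df = x if isinstance(x, pd.DataFrame) else pd.DataFrame(np.asarray(x, float))
    sd = df.std(ddof=1)
    const = sd.index[(sd == 0) | sd.isna()].tolist()
    if const:
        raise ValidationError(f"constant columns cannot be standardized: {const}")
    out = (df - df.mean()) / sd
    return out if isinstance(x, pd.DataFrame) else out.to_numpy()
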