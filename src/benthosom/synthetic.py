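"""Synthetic benthic community + environment generator with known truth.

The generator emulates the statistical structure the analysis chain
assumes: about 74 sampling events (13 lakes × 3 seasons), 44 taxa spread
over six higher groups (23 aquatic insects, 10 gastropods, 4 bivalves,
4 oligochaetes, 2 leeches, 1 crustacean), a planted partition of the sites
into community groups with group-specific indicator taxa, overdispersed
(negative-binomial) counts, and environmental variables whose means shift
by group on the log scale.

Indicator taxa occur with probability B* at sites of their home group and
with a (1−A*)-scaled probability elsewhere, with an in-group mean density
``baseline_mean × indicator_effect``; non-indicator taxa share one mean
across groups.  Environmental variables start from field-realistic
baselines (pH near 8.5, conductivity in the several-hundred µS/cm range)
and selected variables receive group-specific mean shifts of
``env_effect_size`` within-group SDs.  Per-site biomass is the
abundance-weighted sum of per-taxon individual mass draws, so gastropod- or
bivalve-rich sites are heavy.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (CommunityMatrix, EnvMatrix, ENV_VARIABLES, SEASONS,
                   write_community, write_environment)

LAKES = ("Aobao", "Amuta", "Beiqin", "Delong", "Habuta", "Huoshaohei",
         "Nashidai", "Rbagu", "Tiehala", "Talahong", "Xihulu",
         "Yangcaohao", "Yamenqi")

#: taxon counts per higher group (sums to 44)
TAXON_GROUP_COUNTS = {
    "aquatic insect": 23, "gastropod": 10, "bivalve": 4,
    "oligochaete": 4, "leech": 2, "crustacean": 1,
}

#: field-realistic baseline levels for the 13 environmental variables
ENV_BASELINES = {
    "WD": 3.0, "WT": 20.0, "DO": 9.0, "pH": 8.5, "COND": 600.0,
    "CODMn": 7.0, "TP": 0.12, "TN": 1.7, "NH3N": 0.7, "NO3N": 0.13,
    "NO2N": 0.07, "Chla": 12000.0, "SS": 15.0,
}

#: variables whose group means shift (pH handled separately, on its own scale)
ENV_SHIFTED = ("WT", "DO", "pH", "COND", "TP", "Chla")

#: individual mass (g) by higher group, order-of-magnitude realistic
MASS_BY_GROUP = {
    "aquatic insect": 0.005, "gastropod": 0.5, "bivalve": 5.0,
    "oligochaete": 0.01, "leech": 0.1, "crustacean": 0.3,
}


@dataclass
class GeneratorConfig:
    n_groups: int = 5
    sites_per_group: int | None = None      # None → spread n_sites evenly
    n_sites: int = 74
    n_taxa: int = 44
    indicators_per_group: int = 4
    baseline_mean: float = 20.0             # ind./m² per non-indicator taxon
    dispersion: float = 1.0                 # negative-binomial size k
    indicator_effect: float = 8.0           # in-group mean fold-change
    specificity: float = 0.9                # planted A*
    fidelity: float = 0.9                   # planted B*
    background_occupancy: float = 0.6
    env_effect_size: float = 2.0            # group shift in within-group SDs
    env_log_sd: float = 0.3
    n_env: int = 13
    seed: int = 0

    def group_sizes(self) -> list[int]:
        if self.sites_per_group is not None:
            if self.sites_per_group < 1:
                raise ValueError("sites_per_group must be >= 1")
            return [self.sites_per_group] * self.n_groups
        base, extra = divmod(self.n_sites, self.n_groups)
        if base < 1:
            raise ValueError("fewer sites than groups")
        return [base + (1 if i < extra else 0) for i in range(self.n_groups)]


@dataclass
class SyntheticTruth:
    true_group: pd.Series
    indicator_taxa: dict            # group label → list of taxa
    env_effects: dict               # variable → per-group mean shift (log scale)
    seed: int
    config: GeneratorConfig = None


def _taxon_labels() -> tuple[list[str], pd.Series]:
    labels, groups = [], []
    for grp, count in TAXON_GROUP_COUNTS.items():
        stem = grp.replace(" ", "_")
        for i in range(count):
            labels.append(f"{stem}_{i + 1:02d}")
            groups.append(grp)
    return labels, pd.Series(groups, index=labels, name="higher_group")


def _nbinom(rng, mean, k):
    """Negative-binomial draw with mean ``mean`` and dispersion size ``k``."""
    mean = np.asarray(mean, dtype=float)
    p = k / (k + np.maximum(mean, 1e-12))
    return rng.negative_binomial(k, p)


def generate(config: GeneratorConfig | None = None,
             seed: int | None = None) -> tuple[CommunityMatrix, EnvMatrix, SyntheticTruth]:
    """Draw one synthetic dataset; fully reproducible from the seed."""
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = GeneratorConfig(**{**asdict(cfg), "seed": int(seed)})
    sizes = cfg.group_sizes()
    n = sum(sizes)
    rng = np.random.default_rng(cfg.seed)

    site_ids = [f"S{i + 1:03d}" for i in range(n)]
    group_labels = np.repeat(np.arange(1, cfg.n_groups + 1), sizes)
    lakes = [LAKES[i % len(LAKES)] for i in range(n)]
    seasons = [SEASONS[(i // len(LAKES)) % len(SEASONS)] for i in range(n)]
    meta = pd.DataFrame({"lake": lakes, "season": seasons}, index=site_ids)

    if cfg.n_taxa == 44:
        taxa, taxon_groups = _taxon_labels()
    else:
        taxa = [f"taxon_{i + 1:02d}" for i in range(cfg.n_taxa)]
        taxon_groups = pd.Series(["aquatic insect"] * cfg.n_taxa, index=taxa)

    # assign indicator taxa round-robin so every higher group contributes
    n_ind = min(cfg.indicators_per_group * cfg.n_groups, cfg.n_taxa)
    order = rng.permutation(cfg.n_taxa)
    indicator_taxa = {g: [] for g in range(1, cfg.n_groups + 1)}
    home = np.zeros(cfg.n_taxa, dtype=int)      # 0 = non-indicator
    for slot in range(n_ind):
        g = slot % cfg.n_groups + 1
        t = order[slot]
        home[t] = g
        indicator_taxa[g].append(taxa[t])

    # occurrence and mean-density model
    occ = np.empty((n, cfg.n_taxa))
    mu = np.empty((n, cfg.n_taxa))
    out_occ = cfg.fidelity * (1.0 - cfg.specificity)
    for t in range(cfg.n_taxa):
        if home[t] == 0:
            occ[:, t] = cfg.background_occupancy
            mu[:, t] = cfg.baseline_mean
        else:
            in_g = group_labels == home[t]
            occ[:, t] = np.where(in_g, cfg.fidelity, out_occ)
            mu[:, t] = np.where(in_g, cfg.baseline_mean * cfg.indicator_effect,
                                cfg.baseline_mean)
    present = rng.random((n, cfg.n_taxa)) < occ
    counts = _nbinom(rng, mu, cfg.dispersion)
    counts = np.where(present, np.maximum(counts, 1), 0)
    # density quantum: Petersen grabs of 0.0625 m² → multiples of 16
    abundance = pd.DataFrame(counts * 16.0, index=site_ids, columns=taxa)

    # environment: log-scale group shifts, pH on its own narrow scale
    env_vars = list(ENV_VARIABLES[:cfg.n_env])
    centered = np.linspace(-0.5, 0.5, cfg.n_groups)
    env = {}
    env_effects = {}
    for v, var in enumerate(env_vars):
        base = ENV_BASELINES.get(var, 1.0)
        if var in ENV_SHIFTED:
            shifts = centered[rng.permutation(cfg.n_groups)] * cfg.env_effect_size
        else:
            shifts = np.zeros(cfg.n_groups)
        env_effects[var] = shifts.tolist()
        per_site_shift = shifts[group_labels - 1]
        if var == "pH":
            vals = 8.5 + 0.1 * per_site_shift + rng.normal(0, 0.1, n)
            vals = np.clip(vals, 7.5, 9.2)
        else:
            vals = np.exp(np.log(base) + cfg.env_log_sd * per_site_shift
                          + rng.normal(0, cfg.env_log_sd, n))
        env[var] = vals
    env_df = pd.DataFrame(env, index=site_ids)

    # biomass: abundance-weighted individual-mass draws
    mass = np.array([MASS_BY_GROUP.get(taxon_groups[t], 0.01) for t in taxa])
    jitter = np.exp(rng.normal(0, 0.3, size=(n, cfg.n_taxa)))
    biomass = pd.Series((abundance.to_numpy() * mass * jitter).sum(axis=1) / 100.0,
                        index=site_ids, name="biomass_g_m2")

    community = CommunityMatrix(abundance=abundance, biomass=biomass,
                                meta=meta, taxon_groups=taxon_groups)
    environment = EnvMatrix(values=env_df)
    truth = SyntheticTruth(
        true_group=pd.Series(group_labels, index=site_ids, name="true_group"),
        indicator_taxa=indicator_taxa, env_effects=env_effects,
        seed=cfg.seed, config=cfg)
    return community, environment, truth


def export_fixture(dataset, path) -> dict:
    """Write community/environment/truth files; returns the file map."""
    community, environment, truth = dataset
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "community": out / "community.tsv",
        "environment": out / "environment.tsv",
        "truth": out / "truth.json",
    }
    write_community(community, files["community"])
    write_environment(environment, files["environment"])
    payload = {
        "seed": truth.seed,
        "config": asdict(truth.config) if truth.config else None,
        "true_group": {k: int(v) for k, v in truth.true_group.items()},
        "indicator_taxa": {str(k): v for k, v in truth.indicator_taxa.items()},
        "env_effects": truth.env_effects,
    }
    files["truth"].write_text(json.dumps(payload, indent=1))
    return files
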