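"""End-to-end orchestration of the community-classification analysis.

The full sequence mirrors how benthic biomonitoring studies combine the
pieces: ln(x+1)-transform the densities, train the SOM (grid chosen by the
5·sqrt(n) heuristic plus QE/TE rank among near-square candidates), cluster
the output neurons with K-means and pick the group number by SSI, compute
indicator species per group with permutation tests, summarise the five
diversity indices, PCA the (log, pH-exempt) environment, check the DCA
gradient length, and — only if the gradient is short enough for a linear
method — run a VIF-screened, forward-selected RDA with axis tests.
Kruskal–Wallis and BH-adjusted Spearman screens round out the battery.

Every stochastic stage derives its seed from the single run seed through a
stable hash, so stages are independently replayable; the run configuration
and all seeds land in the emitted summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, grouping, indval, ordination, som, stats
from .data import (CommunityMatrix, EnvMatrix, hellinger_transform,
                   log_environment, log_transform, standardize)
from .synthetic import GeneratorConfig, generate


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage-specific seed (< 2^31) from the run seed."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 0
    grid: tuple | str = "auto"            # (rows, cols) or "auto"
    max_grid_candidates: int = 5
    lattice: str = "hexagonal"
    epochs_rough: int = 100
    epochs_fine: int = 200
    k_range: tuple = (2, 10)
    kmeans_restarts: int = 100
    indval_n_perm: int = 999
    indval_threshold: float = 50.0
    alpha: float = 0.05
    vif_threshold: float = 10.0
    rda_n_perm: int = 999
    simulate: GeneratorConfig | None = None


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML mapping (keys = RunConfig fields;
    an optional ``simulate`` sub-mapping configures the generator)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        cfg.simulate = GeneratorConfig(**sim)
    if isinstance(cfg.grid, list):
        cfg.grid = tuple(cfg.grid)
    return cfg


def run_all(community: CommunityMatrix | None = None,
            env: EnvMatrix | None = None,
            config: RunConfig | None = None,
            outdir=None) -> dict:
    """Run the whole chain; returns a dict of tables plus a summary dict.

    Provide either ``community`` + ``env`` or a ``config.simulate`` block.
    If ``outdir`` is given, every table is written as TSV plus a
    ``summary.json`` of headline numbers.
    """
    cfg = config or RunConfig()
    results: dict = {}
    summary: dict = {"seed": cfg.seed}

    if community is None or env is None:
        sim_cfg = cfg.simulate or GeneratorConfig()
        community, env, truth = generate(sim_cfg,
                                         seed=stage_seed(cfg.seed, "simulate"))
        results["truth"] = truth
        summary["simulated"] = True

    # --- SOM classification ------------------------------------------
    x = log_transform(community.abundance, applied_to="abundance")
    som_seed = stage_seed(cfg.seed, "som")
    if cfg.grid == "auto":
        target = som.heuristic_neuron_count(community.n_sites)
        candidates = som.candidate_grids(target)[:cfg.max_grid_candidates]
        template = som.SOMConfig(grid_rows=candidates[0][0],
                                 grid_cols=candidates[0][1],
                                 lattice=cfg.lattice,
                                 epochs_rough=cfg.epochs_rough,
                                 epochs_fine=cfg.epochs_fine, seed=som_seed)
        model, grid_diag = som.select_grid(x, candidates, template=template,
                                           seed=som_seed)
        results["grid_diagnostics"] = grid_diag
        summary["neuron_target"] = target
    else:
        rows, cols = cfg.grid
        model = som.train_som(x, som.SOMConfig(
            grid_rows=rows, grid_cols=cols, lattice=cfg.lattice,
            epochs_rough=cfg.epochs_rough, epochs_fine=cfg.epochs_fine,
            seed=som_seed))
    results["som"] = model
    summary["grid"] = [model.config.grid_rows, model.config.grid_cols]
    summary["quantization_error"] = model.quantization_error
    summary["topographic_error"] = model.topographic_error

    # --- grouping -----------------------------------------------------
    lo, hi = cfg.k_range
    hi = min(hi, model.config.n_neurons - 1)
    partition = grouping.select_k(model, k_range=range(lo, hi + 1),
                                  restarts=cfg.kmeans_restarts,
                                  seed=stage_seed(cfg.seed, "kmeans"))
    results["partition"] = partition
    results["site_groups"] = pd.concat(
        [community.meta, partition.site_group], axis=1)
    results["ssi_curve"] = pd.DataFrame({
        "k": list(partition.ssi_by_k),
        "ssi": list(partition.ssi_by_k.values()),
        "inertia": [partition.inertia_by_k[k] for k in partition.ssi_by_k]})
    summary["selected_k"] = partition.k

    # --- indicator species ---------------------------------------------
    table = indval.indval_permutation_test(
        community, partition, n_perm=cfg.indval_n_perm,
        seed=stage_seed(cfg.seed, "indval"))
    indicators = indval.classify_indicators(table, threshold=cfg.indval_threshold,
                                            alpha=cfg.alpha)
    results["indval"] = table
    results["indicator_table"] = indicators
    summary["n_indicator_species"] = int(indicators["indicator_flag"].sum())
    summary["n_sub50_significant"] = int(indicators["sub50_flag"].sum())

    # --- diversity ------------------------------------------------------
    div = diversity.diversity_per_site(community)
    results["diversity"] = div
    results["diversity_by_lake"] = diversity.summarize_by(div, "lake", community.meta)
    results["diversity_by_season"] = diversity.summarize_by(div, "season", community.meta)
    results["diversity_by_group"] = diversity.summarize_by(div, partition.site_group)

    # --- environment: PCA ------------------------------------------------
    env_log = log_environment(env)
    env_z = standardize(env_log)
    pca_res = ordination.pca(env_log)
    results["pca"] = pca_res
    summary["pca_axis1_pct"] = float(pca_res.prop_explained[0] * 100)
    summary["pca_axis2_pct"] = float(pca_res.prop_explained[1] * 100)

    # --- DCA gate + RDA ---------------------------------------------------
    # the gradient-length check runs on the same ln(x+1) abundance that the
    # ordination models; raw counts would overstate turnover
    dca = ordination.dca_gradient_length(x)
    results["dca"] = dca
    summary["dca_gradient_length_sd"] = dca.gradient_length_sd
    summary["ordination_method"] = dca.recommendation
    if dca.recommendation == "linear":
        hel = hellinger_transform(community.abundance)
        vif_series = ordination.vif(env_z)
        keep = env_z.columns.tolist()
        while True:                       # iteratively drop the worst collinear
            v = ordination.vif(env_z[keep]) if len(keep) > 1 else None
            if v is None or v.max() <= cfg.vif_threshold:
                break
            keep.remove(v.idxmax())
        results["vif"] = vif_series
        fwd = ordination.forward_select(
            hel, env_z[keep], n_perm=cfg.rda_n_perm, alpha=cfg.alpha,
            seed=stage_seed(cfg.seed, "forward"))
        results["rda"] = fwd
        summary["rda_selected_vars"] = fwd.selected_vars
        summary["rda_constrained_pct"] = float((fwd.constrained_total or 0) * 100)
        if fwd.selected_vars:
            axis_p = ordination.test_axes(fwd, n_perm=cfg.rda_n_perm,
                                          seed=stage_seed(cfg.seed, "axes"))
            summary["rda_axis1_pct"] = float(fwd.prop_explained[0] * 100)
            summary["rda_axis_p"] = [float(v) for v in axis_p]
    else:
        summary["rda_selected_vars"] = None
        summary["note"] = ("first DCA gradient length >= 4 SD: a unimodal "
                           "method (CCA) is recommended; constrained step skipped")

    # --- group-wise stats --------------------------------------------------
    kw = stats.kruskal_by_variable(env.values, partition.site_group,
                                   alpha=cfg.alpha)
    results["kw_table"] = kw
    summary["kw_significant_vars"] = kw.loc[kw["p"] < cfg.alpha, "variable"].tolist()
    sp = stats.spearman_screen(div, env.values)
    results["spearman_grid"] = sp
    summary["spearman_significant_pairs"] = int(
        ((sp["p"] < cfg.alpha) & ~sp["undefined"]).sum())

    summary["stage_seeds"] = {s: stage_seed(cfg.seed, s) for s in
                              ("simulate", "som", "kmeans", "indval",
                               "forward", "axes")}
    results["summary"] = summary

    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "site_groups": results.get("site_groups"),
        "ssi_curve": results.get("ssi_curve"),
        "indicator_table": results.get("indicator_table"),
        "diversity": results.get("diversity"),
        "diversity_by_lake": results.get("diversity_by_lake"),
        "diversity_by_season": results.get("diversity_by_season"),
        "diversity_by_group": results.get("diversity_by_group"),
        "kw_table": results.get("kw_table"),
        "spearman_grid": results.get("spearman_grid"),
        "grid_diagnostics": results.get("grid_diagnostics"),
    }
    for name, df in tables.items():
        if df is not None:
            df.to_csv(outdir / f"{name}.tsv", sep="\t")
    pca_res = results.get("pca")
    if pca_res is not None:
        pd.DataFrame({"eigenvalue": pca_res.eigenvalues,
                      "prop_explained": pca_res.prop_explained}).to_csv(
            outdir / "pca_summary.tsv", sep="\t")
    fwd = results.get("rda")
    if fwd is not None and fwd.selection_steps is not None:
        fwd.selection_steps.to_csv(outdir / "rda_selection.tsv", sep="\t")
    (outdir / "summary.json").write_text(
        json.dumps(results["summary"], indent=1, default=str))
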