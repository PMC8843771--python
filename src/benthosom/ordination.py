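"""Unconstrained and constrained ordination: PCA, DCA gradient length, RDA.

The environmental battery follows standard practice in community ecology:

* PCA of the (log-transformed, pH exempt) environmental variables on the
  correlation matrix, so each axis' explained proportion is its eigenvalue
  divided by the number of variables;
* a DCA (detrended correspondence analysis) check of the community data's
  first gradient length in species-turnover SD units — below 4 SD species
  respond roughly linearly along the gradient and a linear method (RDA) is
  appropriate, above 4 a unimodal method (CCA) would be;
* RDA (redundancy analysis) of the Hellinger-transformed community on the
  environmental predictors: PCA of the fitted values of the multivariate
  regression Y ~ X, with VIF screening for collinearity, permutation-based
  forward selection of predictors, and per-axis permutation tests.

Forward selection adds, at each step, the candidate explaining the most
additional variance, and admits it only if its conditional pseudo-F beats
the permutation null built from the *maximum* pseudo-F over all remaining
candidates (residuals of the reduced model are permuted).  Using the
max-statistic null keeps the inclusion decision level-alpha even though the
best of many candidates is being tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ValidationError


@dataclass
class OrdinationResult:
    method: str
    eigenvalues: np.ndarray | None = None
    prop_explained: np.ndarray | None = None
    site_scores: pd.DataFrame | None = None
    species_scores: pd.DataFrame | None = None
    variable_scores: pd.DataFrame | None = None
    constrained_total: float | None = None
    selected_vars: list = field(default_factory=list)
    selection_steps: pd.DataFrame | None = None
    axis_p: np.ndarray | None = None
    gradient_length_sd: float | None = None
    recommendation: str | None = None
    vif: pd.Series | None = None
    # internals retained for permutation tests
    _X: np.ndarray | None = None
    _Y: np.ndarray | None = None


# ---------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------

def pca_proportions(eigenvalues, n_variables: int) -> np.ndarray:
    """Correlation-matrix PCA convention: proportion_k = eigenvalue_k / p."""
    return np.asarray(eigenvalues, dtype=float) / float(n_variables)


def pca(env: pd.DataFrame) -> OrdinationResult:
    """PCA on the correlation matrix of a site × variable table."""
    df = pd.DataFrame(env)
    sd = df.std(ddof=1)
    const = sd.index[(sd == 0) | sd.isna()].tolist()
    if const:
        raise ValidationError(f"constant variables: {const}")
    z = (df - df.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    axes = [f"PC{i + 1}" for i in range(len(vals))]
    # deterministic sign: largest-magnitude loading positive
    for a in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, a]))
        if vecs[j, a] < 0:
            vecs[:, a] = -vecs[:, a]
    scores = z.to_numpy() @ vecs
    return OrdinationResult(
        method="PCA",
        eigenvalues=vals,
        prop_explained=pca_proportions(vals, df.shape[1]),
        site_scores=pd.DataFrame(scores, index=df.index, columns=axes),
        variable_scores=pd.DataFrame(vecs, index=df.columns, columns=axes),
    )


# ---------------------------------------------------------------------
# DCA gradient length
# ---------------------------------------------------------------------

def dca_gradient_length(abundance: pd.DataFrame) -> OrdinationResult:
    """First-axis gradient length of the community in turnover-SD units.

    Correspondence analysis by reciprocal averaging gives the first axis;
    the axis is rescaled so the abundance-weighted mean within-site SD of
    species scores is one ("species turnover" unit), and the gradient
    length is the range of site scores on that rescaled axis.  Lengths
    below 4 SD recommend a linear ordination (RDA), above 4 a unimodal one.
    """
    df = pd.DataFrame(abundance)
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValidationError("gradient length needs at least 2 sites")
    if (arr < 0).any():
        raise ValidationError("negative abundances")
    if (arr.sum(axis=1) == 0).any():
        empty = df.index[arr.sum(axis=1) == 0].tolist()
        raise ValidationError(f"empty sites: {empty}")
    if (arr.sum(axis=0) == 0).any():
        empty = df.columns[arr.sum(axis=0) == 0].tolist()
        raise ValidationError(f"empty taxa: {empty}")

    p = arr / arr.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    lam = sv[0] ** 2
    x = u[:, 0] / np.sqrt(r)              # site standard scores, weighted var 1
    spec = (p.T @ x) / c                   # species scores: WA of site scores
    z = (p @ spec) / r                     # site centroids on the species axis
    # weighted RMS within-site SD of species scores = one turnover unit
    dev2 = ((spec[None, :] - z[:, None]) ** 2 * p / r[:, None]).sum(axis=1)
    alpha = np.sqrt(np.sum(r * dev2))
    if alpha <= 0:
        length = 0.0
    else:
        length = float((z.max() - z.min()) / alpha)
    rec = "linear" if length < 4 else "unimodal"
    return OrdinationResult(
        method="DCA",
        eigenvalues=np.array([lam]),
        gradient_length_sd=length,
        recommendation=rec,
        site_scores=pd.DataFrame({"DCA1": z}, index=df.index),
        species_scores=pd.DataFrame({"DCA1": spec}, index=df.columns),
    )


# ---------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------

def vif(env_subset: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1−R²) of each variable on the others."""
    df = pd.DataFrame(env_subset)
    if df.shape[1] < 2:
        raise ValidationError("VIF needs at least 2 variables")
    sd = df.std(ddof=1)
    const = sd.index[(sd == 0) | sd.isna()].tolist()
    if const:
        raise ValidationError(f"constant columns: {const}")
    x = df.to_numpy(dtype=float)
    n, p = x.shape
    out = {}
    for j, name in enumerate(df.columns):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        y = x[:, j]
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot
        if r2 > 1 - 1e-12:
            warnings.warn(f"{name} is exactly collinear with the others")
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------

def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def rda(y: pd.DataFrame, x: pd.DataFrame, standardize_x: bool = True) -> OrdinationResult:
    """Redundancy analysis: PCA of the fitted values of Y ~ X.

    ``y`` is the (Hellinger-transformed) site × species table, ``x`` the
    site × predictor table.  Species scores use correlation-biplot (type 2)
    scaling; variable scores are correlations of predictors with the
    constrained site scores.
    """
    ydf, xdf = pd.DataFrame(y), pd.DataFrame(x)
    if ydf.shape[0] != xdf.shape[0]:
        raise ValidationError("Y and X site counts differ")
    n = ydf.shape[0]
    if n <= xdf.shape[1]:
        raise ValidationError("need more sites than predictors")
    yc = _center(ydf.to_numpy(dtype=float))
    xm = xdf.to_numpy(dtype=float)
    if standardize_x:
        sd = xm.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(xdf.columns[sd == 0])
            raise ValidationError(f"constant predictors: {bad}")
        xc = (xm - xm.mean(axis=0)) / sd
    else:
        xc = _center(xm)
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        dep = []
        for j, name in enumerate(xdf.columns):
            others = np.delete(xc, j, axis=1)
            if np.linalg.matrix_rank(np.column_stack([others, xc[:, j]])) == \
                    np.linalg.matrix_rank(others):
                dep.append(name)
        raise ValidationError(f"rank-deficient predictors: {dep}")

    coef, _, _, _ = np.linalg.lstsq(xc, yc, rcond=None)
    yhat = xc @ coef
    u, sv, vt = np.linalg.svd(yhat, full_matrices=False)
    n_axes = int(min(rank, (sv > 1e-10 * max(sv[0], 1)).sum()))
    u, sv, vt = u[:, :n_axes], sv[:n_axes], vt[:n_axes]
    eig = sv ** 2 / (n - 1)
    total_var = float(np.sum(yc ** 2) / (n - 1))
    axes = [f"RDA{i + 1}" for i in range(n_axes)]

    site = u * sv                              # constrained (lc) site scores
    species = vt.T * (sv / np.sqrt(n - 1))
    with np.errstate(invalid="ignore"):
        var_scores = np.array([
            [np.corrcoef(xc[:, j], site[:, a])[0, 1] if site[:, a].std() > 0 else 0.0
             for a in range(n_axes)]
            for j in range(xc.shape[1])])
    return OrdinationResult(
        method="RDA",
        eigenvalues=eig,
        prop_explained=eig / total_var,
        constrained_total=float(eig.sum() / total_var),
        site_scores=pd.DataFrame(site, index=ydf.index, columns=axes),
        species_scores=pd.DataFrame(species, index=ydf.columns, columns=axes),
        variable_scores=pd.DataFrame(var_scores, index=xdf.columns, columns=axes),
        _X=xc, _Y=yc,
    )


def test_axes(result: OrdinationResult, n_perm: int = 999, seed: int = 0) -> np.ndarray:
    """Marginal permutation p per constrained axis (rows of Y permuted)."""
    if result._X is None or result._Y is None:
        raise ValueError("result lacks stored X/Y; rerun rda()")
    xc, yc = result._X, result._Y
    n = yc.shape[0]
    hat = xc @ np.linalg.pinv(xc)
    obs = result.eigenvalues
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs))
    for _ in range(n_perm):
        yp = yc[rng.permutation(n)]
        sv = np.linalg.svd(hat @ yp, compute_uv=False)[:len(obs)]
        lam = np.zeros(len(obs))
        lam[:len(sv)] = sv ** 2 / (n - 1)
        exceed += lam >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    result.axis_p = p
    return p


# ---------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------

def forward_select(y: pd.DataFrame, x_full: pd.DataFrame, n_perm: int = 999,
                   alpha: float = 0.05, seed: int = 0,
                   max_vars: int | None = None) -> OrdinationResult:
    """Greedy forward selection of RDA predictors with permutation tests.

    At each step the candidate adding the most constrained variance is
    tested: residuals of the reduced model are permuted ``n_perm`` times
    and the candidate enters only if its conditional pseudo-F exceeds the
    permuted max-over-candidates pseudo-F sufficiently rarely
    (p < ``alpha``).  May select zero variables.  The returned result is
    the RDA on the selected predictors (empty selection → no axes).
    """
    ydf, xdf = pd.DataFrame(y), pd.DataFrame(x_full)
    yc = _center(ydf.to_numpy(dtype=float))
    xz = xdf.to_numpy(dtype=float)
    sd = xz.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError(f"constant predictors: {list(xdf.columns[sd == 0])}")
    xz = (xz - xz.mean(axis=0)) / sd
    n = yc.shape[0]
    total_ss = float(np.sum(yc ** 2))
    rng = np.random.default_rng(seed)

    names = list(xdf.columns)
    remaining = list(range(len(names)))
    selected: list[int] = []
    q_basis = np.zeros((n, 0))
    e = yc.copy()
    rss = total_ss
    steps = []
    limit = max_vars if max_vars is not None else len(names)

    while remaining and len(selected) < limit and len(selected) < n - 2:
        # residualize candidates against the selected basis
        cand_dirs, cand_idx = [], []
        for j in remaining:
            v = xz[:, j] - q_basis @ (q_basis.T @ xz[:, j])
            v = v - v.mean()
            norm = np.linalg.norm(v)
            if norm > 1e-8:
                cand_dirs.append(v / norm)
                cand_idx.append(j)
        if not cand_dirs:
            break
        u = np.column_stack(cand_dirs)          # n × n_cand
        ss_add = np.sum((u.T @ e) ** 2, axis=1)
        df_resid = n - 1 - (len(selected) + 1)
        if df_resid <= 0:
            break
        with np.errstate(divide="ignore"):
            f_obs = ss_add / np.maximum(rss - ss_add, 1e-300) * df_resid
        best = int(np.argmax(ss_add))
        f_best = f_obs[best]

        exceed = 0
        for _ in range(n_perm):
            ep = e[rng.permutation(n)]
            ss_p = np.sum((u.T @ ep) ** 2, axis=1)
            with np.errstate(divide="ignore"):
                f_p = ss_p / np.maximum(rss - ss_p, 1e-300) * df_resid
            exceed += f_p.max() >= f_best - 1e-12
        p = (1.0 + exceed) / (1.0 + n_perm)
        if p >= alpha:
            break
        j = cand_idx[best]
        selected.append(j)
        remaining.remove(j)
        d = u[:, best][:, None]
        q_basis = np.column_stack([q_basis, d])
        e = e - d @ (d.T @ e)
        new_rss = float(np.sum(e ** 2))
        steps.append({"variable": names[j],
                      "added_r2": (rss - new_rss) / total_ss,
                      "cum_r2": (total_ss - new_rss) / total_ss,
                      "pseudo_f": f_best, "p": p})
        rss = new_rss

    step_df = pd.DataFrame(steps, columns=["variable", "added_r2", "cum_r2",
                                           "pseudo_f", "p"])
    if selected:
        result = rda(ydf, xdf.iloc[:, selected])
    else:
        result = OrdinationResult(method="RDA", eigenvalues=np.array([]),
                                  prop_explained=np.array([]),
                                  constrained_total=0.0)
    result.selected_vars = [names[j] for j in selected]
    result.selection_steps = step_df
    return result
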