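"""Batch Kohonen self-organizing map for community ordination/classification.

A SOM projects the site × taxon abundance matrix onto a small 2-D lattice of
"neurons", each carrying a codebook vector in taxon space.  Training is the
deterministic batch algorithm: every epoch each site is assigned to its
best-matching unit (BMU, the nearest codebook vector) and each codebook
vector is replaced by the neighbourhood-kernel-weighted mean of the sites,
with a Gaussian kernel over lattice distance whose radius decays linearly
during a rough phase and stays at its floor during a fine phase.

Map fit is summarised by two errors:

* quantization error (QE) — mean Euclidean distance from sites to their BMU;
* topographic error (TE) — fraction of sites whose first and second BMUs are
  not lattice-adjacent.

The output-layer size follows the common heuristic of about 5·sqrt(n)
neurons for n sites, with the final grid chosen among near-square candidate
factorizations by the smallest combined rank of QE and TE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata


@dataclass
class SOMConfig:
    grid_rows: int
    grid_cols: int
    lattice: str = "hexagonal"
    epochs_rough: int = 100
    epochs_fine: int = 200
    sigma_start: float | None = None   # default max(rows, cols) / 2
    sigma_end: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 2:
            raise ValueError("SOM needs at least 2 neurons")
        if self.lattice not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.sigma_start is None:
            self.sigma_start = max(self.grid_rows, self.grid_cols) / 2.0
        if not (self.sigma_start >= self.sigma_end > 0):
            raise ValueError("need sigma_start >= sigma_end > 0")

    @property
    def n_neurons(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class SOMModel:
    codebook: np.ndarray          # neurons × features
    config: SOMConfig
    bmu: np.ndarray               # site → neuron index
    quantization_error: float
    topographic_error: float
    site_ids: list = field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        return lattice_coords(self.config.grid_rows, self.config.grid_cols,
                              self.config.lattice)


def heuristic_neuron_count(n_sites: int) -> int:
    """Output-layer sizing heuristic: round(5 * sqrt(n_sites))."""
    if n_sites < 1:
        raise ValueError("need at least one site")
    return int(round(5.0 * np.sqrt(n_sites)))


def candidate_grids(target: int) -> list[tuple[int, int]]:
    """Near-square (rows, cols) factorizations with rows*cols near target.

    Products are restricted to [0.8*target, 1.3*target], rows >= cols, and
    aspect ratio at most 2 (relaxed if that leaves nothing); sorted by
    |rows*cols - target|, then smaller product, then fewer rows.
    """
    if target < 2:
        raise ValueError("target must be >= 2")
    lo = int(np.ceil(0.8 * target))
    hi = int(np.floor(1.3 * target))
    pairs = []
    for p in range(max(lo, 2), hi + 1):
        for cols in range(1, int(np.sqrt(p)) + 1):
            if p % cols == 0:
                rows = p // cols
                pairs.append((rows, cols))
    square = [(r, c) for r, c in pairs if r <= 2 * c]
    if square:
        pairs = square
    pairs.sort(key=lambda rc: (abs(rc[0] * rc[1] - target), rc[0] * rc[1], rc[0]))
    return pairs


def lattice_coords(rows: int, cols: int, lattice: str = "hexagonal") -> np.ndarray:
    """Planar coordinates of the neurons; nearest neighbours sit at distance 1."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r = r.ravel().astype(float)
    c = c.ravel().astype(float)
    if lattice == "hexagonal":
        x = c + 0.5 * (r % 2)
        y = r * (np.sqrt(3) / 2.0)
    else:
        x, y = c, r
    return np.column_stack([x, y])


def _as_array(x):
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index)
    arr = np.asarray(x, dtype=float)
    return arr, list(range(arr.shape[0]))


def train_som(x, config: SOMConfig) -> SOMModel:
    """Train a batch SOM; deterministic given ``config.seed``.

    The codebook is initialized on the seeded random span of the first two
    principal components of the data, which stabilizes training on small
    site sets.
    """
    arr, site_ids = _as_array(x)
    if arr.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite input values")
    n, d = arr.shape
    k = config.n_neurons
    if k > n:
        warnings.warn(f"more neurons ({k}) than sites ({n})")

    rng = np.random.default_rng(config.seed)
    mean = arr.mean(axis=0)
    xc = arr - mean
    # principal axes of the data; degenerate directions fall back to noise
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_pc = min(2, vt.shape[0])
    sd = s[:n_pc] / np.sqrt(max(n - 1, 1))
    coeff = rng.uniform(-1.0, 1.0, size=(k, n_pc))
    codebook = mean + (coeff * sd) @ vt[:n_pc]
    codebook = codebook + 1e-9 * rng.standard_normal(codebook.shape)

    coords = lattice_coords(config.grid_rows, config.grid_cols, config.lattice)
    lat_d2 = cdist(coords, coords, "sqeuclidean")

    total = config.epochs_rough + config.epochs_fine
    for t in range(total):
        if t < config.epochs_rough and config.epochs_rough > 1:
            frac = t / max(config.epochs_rough - 1, 1)
            sigma = config.sigma_start + frac * (config.sigma_end - config.sigma_start)
        else:
            sigma = config.sigma_end
        dist = cdist(arr, codebook)
        bmu = dist.argmin(axis=1)
        h = np.exp(-lat_d2 / (2.0 * sigma * sigma))   # neurons × neurons
        w = h[:, bmu]                                  # neurons × sites
        denom = w.sum(axis=1)
        ok = denom > 1e-300
        updated = (w @ arr) / np.where(ok, denom, 1.0)[:, None]
        codebook = np.where(ok[:, None], updated, codebook)

    model = SOMModel(codebook=codebook, config=config,
                     bmu=cdist(arr, codebook).argmin(axis=1),
                     quantization_error=0.0, topographic_error=0.0,
                     site_ids=site_ids)
    model.quantization_error = quantization_error(model, arr)
    model.topographic_error = topographic_error(model, arr)
    return model


def quantization_error(model: SOMModel, x) -> float:
    """Mean Euclidean distance from each input to its best-matching unit."""
    arr, _ = _as_array(x)
    dist = cdist(arr, model.codebook)
    return float(dist.min(axis=1).mean())


def topographic_error(model: SOMModel, x) -> float:
    """Fraction of inputs whose two best neurons are not lattice-adjacent."""
    if model.config.n_neurons < 2:
        raise ValueError("topographic error needs at least 2 neurons")
    arr, _ = _as_array(x)
    dist = cdist(arr, model.codebook)
    order = np.argsort(dist, axis=1)
    first, second = order[:, 0], order[:, 1]
    coords = model.coords
    gap = np.linalg.norm(coords[first] - coords[second], axis=1)
    return float(np.mean(gap > 1.001))


def select_grid(x, candidates: list[tuple[int, int]],
                template: SOMConfig | None = None, seed: int = 0) -> tuple[SOMModel, pd.DataFrame]:
    """Train one SOM per candidate grid and pick the best by rank(QE)+rank(TE).

    All candidates share the same seed policy.  Ties break toward the
    smaller grid.  Returns the winning model plus the per-candidate
    diagnostics table (rows, cols, QE, TE).
    """
    if not candidates:
        raise ValueError("no candidate grids")
    models, rows = [], []
    for r, c in candidates:
        if template is None:
            cfg = SOMConfig(grid_rows=r, grid_cols=c, seed=seed)
        else:
            cfg = replace(template, grid_rows=r, grid_cols=c,
                          sigma_start=None, seed=seed)
        m = train_som(x, cfg)
        models.append(m)
        rows.append({"rows": r, "cols": c, "neurons": r * c,
                     "qe": m.quantization_error, "te": m.topographic_error})
    diag = pd.DataFrame(rows)
    ranksum = rankdata(diag["qe"]) + rankdata(diag["te"])
    diag["rank_sum"] = ranksum
    order = sorted(range(len(models)),
                   key=lambda i: (ranksum[i], diag["neurons"][i], diag["rows"][i]))
    return models[order[0]], diag
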