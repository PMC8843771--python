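"""K-means on SOM output neurons and SSI-based choice of group number.

The trained SOM has no explicit class boundaries, so the codebook neurons
are clustered with K-means and the resulting neuron clusters are pulled
back to sites through the BMU map (sites are never re-clustered).  The
number of groups k is chosen by the Simple Structure Index (SSI), a
cluster-validity score that combines, feature by feature, (1) the contrast
between the extreme cluster centers, (2) the sizes of those two contrasting
clusters, and (3) how far cluster-mean levels deviate from the overall
mean; larger SSI means a better-structured partition.

The SSI variant implemented here is the weighted form ("ssiw") used by the
cascade K-means cluster-validity tooling common in community ecology.  For
centers ``c`` (k clusters × p features) and cluster sizes ``n``:

    span_v   = max_g c[g,v] - min_g c[g,v]
    dev_v    = | mean_g c[g,v] - mean(c) |
    w_v      = sqrt(n[argmax_g c[g,v]] * n[argmin_g c[g,v]])
    SSI      = sum_v span_v * exp(-dev_v) * w_v
               / ( p * max_sizes * exp(-min_v dev_v) )

where ``max_sizes`` is the largest cluster size appearing among the
contrasting clusters.  SSI is 0 when all centers coincide and grows with
between-cluster feature contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .som import SOMModel


@dataclass
class GroupPartition:
    """Site and neuron group labels plus the SSI-vs-k selection record."""

    k: int
    neuron_cluster: np.ndarray            # neuron → group label (1..k)
    site_group: pd.Series                 # site → group label (1..k)
    ssi_by_k: dict = field(default_factory=dict)
    inertia_by_k: dict = field(default_factory=dict)


def kmeans(points, k: int, restarts: int = 100, seed: int = 0):
    """Best-of-restarts Lloyd's K-means with k-means++ seeding.

    Returns ``(labels, centers, inertia)`` of the minimum-inertia solution.
    """
    arr = np.asarray(points, dtype=float)
    n_distinct = np.unique(arr, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                init="k-means++", algorithm="lloyd").fit(arr)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def simple_structure_index(points, labels, centers, weights=None) -> float:
    """SSI of a partition (see module docstring for the pinned definition).

    ``weights`` optionally gives each point a mass (e.g. the number of
    sampling events a SOM neuron represents); cluster sizes are then sums
    of masses instead of point counts.
    """
    centers = np.asarray(centers, dtype=float)
    labels = np.asarray(labels)
    k, p = centers.shape
    if k < 2:
        raise ValueError("SSI needs at least 2 clusters")
    uniq = np.unique(labels)
    if len(uniq) != k:
        raise ValueError("every cluster must be non-empty")
    if weights is None:
        clsize = np.array([(labels == u).sum() for u in uniq], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        clsize = np.array([w[labels == u].sum() for u in uniq])
        if (clsize <= 0).any():
            raise ValueError("every cluster needs positive total weight")

    cmaxi = centers.argmax(axis=0)
    cmini = centers.argmin(axis=0)
    span = centers.max(axis=0) - centers.min(axis=0)
    meanmean = centers.mean()
    absmdif = np.abs(centers.mean(axis=0) - meanmean)
    csizemax = clsize[cmaxi]
    csizemin = clsize[cmini]
    hiestw = p * max(csizemax.max(), csizemin.max()) * np.exp(-absmdif.min())
    if hiestw == 0:
        return 0.0
    ssiw = float(np.sum(span * np.exp(-absmdif) * np.sqrt(csizemax * csizemin)) / hiestw)
    return ssiw


def select_k(model: SOMModel, k_range=range(2, 11), restarts: int = 100,
             seed: int = 0) -> GroupPartition:
    """Scan k over ``k_range``, pick the SSI-maximising K-means partition.

    K-means runs on the occupied codebook neurons (those that are BMU of at
    least one site): unoccupied neurons interpolate between data regions
    and represent no sampling events, so they carry no weight in either the
    clustering or the SSI, whose cluster sizes count mapped sites.
    Unoccupied neurons are afterwards attached to their nearest cluster
    center so every neuron has a label.  Ties in SSI break toward the
    smaller k (parsimony).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    n_neurons = model.codebook.shape[0]
    if ks[0] < 2 or ks[-1] > n_neurons - 1:
        raise ValueError(f"k range must lie within [2, {n_neurons - 1}]")

    occupied = np.unique(model.bmu)
    points = model.codebook[occupied]
    site_counts = np.bincount(model.bmu, minlength=n_neurons)[occupied]

    ssi_by_k, inertia_by_k, partitions = {}, {}, {}
    for k in ks:
        if k > np.unique(points, axis=0).shape[0]:
            continue
        labels, centers, inertia = kmeans(points, k, restarts=restarts,
                                          seed=seed)
        ssi_by_k[k] = simple_structure_index(points, labels, centers,
                                             weights=site_counts)
        inertia_by_k[k] = inertia
        partitions[k] = (labels, centers)
    if not ssi_by_k:
        raise ValueError("no feasible k in range")
    best_k = max(ssi_by_k, key=lambda k: (ssi_by_k[k], -k))

    raw, centers = partitions[best_k]
    # every neuron gets the label of its nearest selected-center
    full = np.empty(n_neurons, dtype=int)
    full[occupied] = raw
    rest = np.setdiff1d(np.arange(n_neurons), occupied)
    if rest.size:
        d = np.linalg.norm(model.codebook[rest, None, :] - centers[None], axis=2)
        full[rest] = d.argmin(axis=1)
    # relabel clusters 1..k in order of first appearance along the lattice
    order = {old: new + 1 for new, old in
             enumerate(dict.fromkeys(full.tolist()))}
    neuron_cluster = np.array([order[v] for v in full])
    site_group = pd.Series(neuron_cluster[model.bmu], index=model.site_ids,
                           name="group")
    return GroupPartition(k=best_k, neuron_cluster=neuron_cluster,
                          site_group=site_group, ssi_by_k=ssi_by_k,
                          inertia_by_k=inertia_by_k)
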