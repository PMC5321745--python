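"""Clustering patches into semi-independent networks and network-level
structural summaries.

Patches are grouped by agglomerative clustering on a connectivity-style
similarity ``s_ij = (A_i*A_j)^b * exp(-alpha*d_ij)``: nearby pairs of large
patches are similar, so clusters correspond to regions a dispersing
butterfly can traverse within a generation while between-cluster movement
is rare.  Cluster-cluster similarity is the geometric mean of all
cross-pair similarities, damped by ``min(n1,n2)^(1-q)`` so that ``q > 1``
discourages absorbing large clusters; ``q = 1`` is the pure geometric
mean (the linkage is exact average linkage on log-similarities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capacity import kernel, metapop_capacity
from .landscape import Landscape, OccupancyHistory


@dataclass(frozen=True)
class ClusterParams:
    """Clustering controls: kernel parameter ``alpha`` (1/km), area
    exponent ``b`` of the pairwise similarity, linkage damping ``q``, and
    the stopping rule ``cut`` — either a similarity threshold (float) or a
    target cluster count (``("k", int)``)."""

    alpha: float = 1.0
    b: float = 0.5
    q: float = 1.5
    cut: float | tuple = 0.01

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.q < 1:
            raise ValueError("q must be >= 1")


@dataclass(frozen=True)
class NetworkAssignment:
    """Network id (contiguous, 0-based) per patch."""

    network_id: np.ndarray
    n_networks: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.network_id)
        if ids.size and (ids.min() < 0 or ids.max() >= self.n_networks):
            raise ValueError("network ids must be contiguous in [0, n_networks)")

    def members(self, n: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.network_id) == n)


def _relabel_contiguous(labels: np.ndarray) -> NetworkAssignment:
    """Relabel so networks are numbered by their lowest patch index."""
    order: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return NetworkAssignment(network_id=out, n_networks=len(order))


def cluster_patches(landscape: Landscape, params: ClusterParams) -> NetworkAssignment:
    """Agglomerative geometric-average-linkage clustering on connectivity.

    Merging is greedy on the damped cross-similarity and stops when the
    best similarity falls below ``cut`` (threshold mode) or when the target
    number of clusters is reached (``cut=("k", K)``).  Ties are broken by
    the lowest patch index so the result is order-deterministic.
    """
    n = landscape.n_patches
    if n == 0:
        raise ValueError("empty landscape")
    target_k = None
    if isinstance(params.cut, tuple):
        kind, val = params.cut
        if kind != "k":
            raise ValueError("tuple cut must be ('k', target_count)")
        target_k = int(val)
        if target_k < 1 or target_k > n:
            raise ValueError(f"target cluster count {target_k} unreachable for {n} patches")
    if n == 1:
        return NetworkAssignment(network_id=np.zeros(1, dtype=int), n_networks=1)

    logA = np.log(landscape.areas)
    # mean log-similarity between clusters; singletons start with pair values
    ml = (params.b * (logA[:, None] + logA[None, :])
          - params.alpha * landscape.distance_matrix).astype(float)
    np.fill_diagonal(ml, -np.inf)
    size = np.ones(n, dtype=int)
    active = np.ones(n, dtype=bool)
    labels = np.arange(n)
    rep = np.arange(n)  # lowest member index per cluster, for tie-breaks
    n_clusters = n

    while n_clusters > 1:
        # damped similarity on the active block
        act = np.flatnonzero(active)
        sub = ml[np.ix_(act, act)].copy()
        damp = np.minimum.outer(size[act], size[act]).astype(float)
        sub = sub + (1.0 - params.q) * np.log(damp)
        best = np.nanmax(sub)
        if target_k is None and best < np.log(params.cut):
            break
        # deterministic arg-max: among maxima pick lexicographically
        # smallest (rep_i, rep_j)
        ii, jj = np.where(sub >= best - 1e-12)
        cand = sorted(
            (min(rep[act[a]], rep[act[b]]), max(rep[act[a]], rep[act[b]]), a, b)
            for a, b in zip(ii, jj) if a < b
        )
        _, _, a, b = cand[0]
        i, j = act[a], act[b]
        # average-linkage update of mean log cross-similarity
        tot = size[i] + size[j]
        ml[i, :] = (size[i] * ml[i, :] + size[j] * ml[j, :]) / tot
        ml[:, i] = ml[i, :]
        ml[i, i] = -np.inf
        active[j] = False
        labels[labels == labels[j]] = labels[i]
        rep[i] = min(rep[i], rep[j])
        size[i] = tot
        n_clusters -= 1
        if target_k is not None and n_clusters == target_k:
            break
    return _relabel_contiguous(labels)


def load_assignment(path, landscape: Landscape) -> NetworkAssignment:
    """Read ``networks.csv`` (patch_id, network_id); bypasses clustering."""
    df = pd.read_csv(path)
    idx = landscape.index_of(df["patch_id"].to_numpy())
    labels = np.full(landscape.n_patches, -1, dtype=object)
    labels[idx] = df["network_id"].to_numpy()
    if np.any(labels == -1):
        raise ValueError("assignment file does not cover every patch")
    # map arbitrary labels to contiguous ints by first appearance
    return _relabel_contiguous(pd.factorize(pd.Series(labels))[0])


def save_assignment(assignment: NetworkAssignment, landscape: Landscape, path) -> None:
    pd.DataFrame({"patch_id": landscape.ids,
                  "network_id": assignment.network_id}).to_csv(path, index=False)


def network_centroids(assignment: NetworkAssignment, landscape: Landscape,
                      area_weighted: bool = False) -> np.ndarray:
    """(x, y) centre point of each network (unweighted mean by default)."""
    xy = landscape.coords
    cents = np.empty((assignment.n_networks, 2))
    for k in range(assignment.n_networks):
        m = assignment.members(k)
        if area_weighted:
            w = landscape.areas[m]
            cents[k] = (xy[m] * w[:, None]).sum(axis=0) / w.sum()
        else:
            cents[k] = xy[m].mean(axis=0)
    return cents


def network_connectivity(
    assignment: NetworkAssignment,
    landscape: Landscape,
    mean_pop: np.ndarray,
    alpha: float = 1.0,
) -> np.ndarray:
    """Between-network connectivity S_n = sum over outside patches of
    ``N_j * exp(-alpha * d_nj)`` with d_nj the distance from patch j to the
    network's centre point and N_j the patch's average population size
    (larval groups)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    N = np.asarray(mean_pop, dtype=float)
    cents = network_centroids(assignment, landscape)
    xy = landscape.coords
    S = np.empty(assignment.n_networks)
    for k in range(assignment.n_networks):
        d = np.hypot(*(xy - cents[k]).T)
        outside = np.asarray(assignment.network_id) != k
        S[k] = float(np.sum(N[outside] * kernel(d[outside], alpha)))
    return S


@dataclass(frozen=True)
class NetworkTable:
    """Per-network summary table: the unit of the headline regressions."""

    table: pd.DataFrame = field(repr=False)

    def __getitem__(self, col):
        return self.table[col]


def network_summaries(
    assignment: NetworkAssignment,
    landscape: Landscape,
    history: OccupancyHistory | None = None,
    M: np.ndarray | None = None,
    mean_pop: np.ndarray | None = None,
    alpha: float = 1.0,
) -> NetworkTable:
    """One row per network: size, pooled area, extent, external
    connectivity, metapopulation capacity (from the per-network submatrix
    of ``M`` if given) and observed occupancy summaries (if a history is
    given).

    ``mean_fraction_occupied`` and ``mean_p_lambda`` average over observed
    patch-years only.
    """
    ids = np.asarray(assignment.network_id)
    if len(ids) != landscape.n_patches:
        raise ValueError("assignment does not match landscape size")
    xy = landscape.coords
    if mean_pop is None and history is not None and history.n_groups is not None:
        with np.errstate(invalid="ignore"):
            mean_pop = np.nan_to_num(np.nanmean(history.n_groups, axis=1))
    rows = []
    from .capacity import p_lambda_series  # local import to avoid cycle at module load

    for k in range(assignment.n_networks):
        m = assignment.members(k)
        row = {
            "network_id": k,
            "n_patches": len(m),
            "pooled_area_ha": float(landscape.areas[m].sum()),
            "centroid_x_km": float(xy[m, 0].mean()),
            "centroid_y_km": float(xy[m, 1].mean()),
            "extent_km2": float(np.ptp(xy[m, 0]) * np.ptp(xy[m, 1])) if len(m) > 1 else 0.0,
        }
        if M is not None:
            sub = metapop_capacity(M[np.ix_(m, m)])
            row["lambda_M"] = sub.lambda_M
        if history is not None:
            occ = history.occupied[m]
            n_obs = np.sum(~np.isnan(occ), axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(n_obs > 0,
                                np.nansum(occ, axis=0) / np.maximum(n_obs, 1), np.nan)
            row["mean_fraction_occupied"] = (float(np.mean(frac[n_obs > 0]))
                                             if (n_obs > 0).any() else np.nan)
            if M is not None:
                sub_hist = OccupancyHistory(years=history.years, occupied=occ)
                pl = p_lambda_series(sub_hist, sub.weights)
                row["mean_p_lambda"] = float(np.nanmean(pl))
        rows.append(row)
    table = pd.DataFrame(rows)
    if mean_pop is not None:
        table["ext_connectivity"] = network_connectivity(assignment, landscape,
                                                         mean_pop, alpha)
    return NetworkTable(table=table)
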