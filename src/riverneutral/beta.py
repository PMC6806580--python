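"""Beta diversity and spatial statistics: Bray-Curtis, geographic distances,
Mantel / partial Mantel, ANOSIM, PCoA and distance-decay regression.

Distances between sites come in two flavours reflecting how organisms can
actually move through a river basin: straight-line great-circle kilometres,
and "dendritic" kilometres along the branching watercourse (shortest path on
the undirected river tree).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
import skbio
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .otu import OtuTable, OtuTableError

EARTH_RADIUS_KM = 6371.0088  # WGS84 mean radius


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance (or similarity) matrix with sample labels."""

    values: np.ndarray
    labels: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper off-diagonal triangle as a flat vector (n(n-1)/2 pairs)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().rename_axis("sample").to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def read(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index), metric)


def _check_labels(*dms: DistanceMatrix) -> None:
    first = dms[0].labels
    for dm in dms[1:]:
        if dm.labels != first:
            raise ValueError("distance matrices have mismatched labels")


@dataclass
class RiverNetwork:
    """Dendritic river network: nodes with coordinates, directed edges.

    ``edges`` are (upstream, downstream, length_km) triples; ignoring
    direction the network must be a tree (connected and acyclic).
    """

    nodes: pd.DataFrame  # index = node id, columns longitude / latitude
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for u, v, w in self.edges:
            if w <= 0:
                raise ValueError(f"edge {u}->{v} has non-positive length {w}")
            for node in (u, v):
                if node not in self.nodes.index:
                    raise ValueError(f"edge endpoint {node!r} has no coordinates")
        g = self.undirected_graph()
        if len(g) and not nx.is_connected(g):
            raise ValueError("river network must be connected")
        if len(self.edges) != len(g) - 1:
            raise ValueError("river network must be a tree (dendritic)")

    def undirected_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index)
        for u, v, w in self.edges:
            g.add_edge(u, v, length=w)
        return g

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes.index)
        for u, v, w in self.edges:
            g.add_edge(u, v, length=w)
        return g

    def sources(self) -> list[str]:
        g = self.directed_graph()
        return [n for n in g.nodes if g.in_degree(n) == 0]

    def write(self, edge_path, node_path) -> None:
        pd.DataFrame(self.edges, columns=["from", "to", "length_km"]).to_csv(
            edge_path, sep="\t", index=False, lineterminator="\n"
        )
        self.nodes.rename_axis("node").to_csv(node_path, sep="\t", lineterminator="\n")

    @classmethod
    def read(cls, edge_path, node_path) -> "RiverNetwork":
        edges_df = pd.read_csv(edge_path, sep="\t")
        nodes = pd.read_csv(node_path, sep="\t", index_col=0)
        edges = [
            (str(r["from"]), str(r["to"]), float(r["length_km"]))
            for _, r in edges_df.iterrows()
        ]
        return cls(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable, as_similarity: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y); similarity = 1 - d."""
    sums = table.sample_sums()
    if (sums == 0).any():
        raise OtuTableError(f"all-zero samples: {sums.index[sums == 0].tolist()}")
    d = squareform(pdist(table.counts.to_numpy(dtype=float), metric="braycurtis"))
    if as_similarity:
        return DistanceMatrix(1.0 - d, table.sample_ids, "bray-curtis-sim")
    return DistanceMatrix(d, table.sample_ids, "bray-curtis-dissim")


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km between two lon/lat points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geo_distances(
    meta: pd.DataFrame, network: RiverNetwork | None = None
) -> DistanceMatrix:
    """Pairwise site distances in km.

    Without a network: great-circle (haversine) distance from longitude and
    latitude columns.  With a network: cumulative dendritic distance, the
    shortest path along the undirected river tree.
    """
    ids = list(meta.index)
    n = len(ids)
    out = np.zeros((n, n))
    if network is None:
        lon = meta["longitude"].to_numpy(dtype=float)
        lat = meta["latitude"].to_numpy(dtype=float)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = haversine_km(lon[i], lat[i], lon[j], lat[j])
        return DistanceMatrix(out, ids, "euclid-km")
    missing = [s for s in ids if s not in network.nodes.index]
    if missing:
        raise ValueError(f"sites not on the river network: {missing}")
    g = network.undirected_graph()
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = lengths[ids[i]][ids[j]]
    return DistanceMatrix(out, ids, "dendritic-km")


def env_distances(env: pd.DataFrame, sqrt_transform: bool = True) -> DistanceMatrix:
    """Euclidean distance on standardised environmental variables.

    By convention all variables except pH are square-root transformed before
    standardisation (``sqrt_transform=True``); negative values are shifted
    to zero first so the root is defined.
    """
    x = transform_env(env) if sqrt_transform else env.astype(float)
    z = (x - x.mean()) / x.std(ddof=1).replace(0, 1.0)
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, list(env.index), "env-euclid")


def transform_env(env: pd.DataFrame) -> pd.DataFrame:
    """Square-root transform every environmental variable except pH."""
    out = env.astype(float).copy()
    for col in out.columns:
        if col.lower() == "ph":
            continue
        v = out[col]
        shifted = v - min(v.min(), 0.0)
        out[col] = np.sqrt(shifted)
    return out


# ---------------------------------------------------------------------------
# Mantel statistics
# ---------------------------------------------------------------------------

def _mantel_vectors(dm: DistanceMatrix, method: str) -> np.ndarray:
    v = dm.condensed()
    if method == "spearman":
        return rankdata(v)  # average ranks for ties
    if method == "pearson":
        return v.astype(float)
    raise ValueError(f"unknown method {method!r}")


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def _permuted_condensed(values: np.ndarray, n: int, perm: np.ndarray) -> np.ndarray:
    full = squareform(values)
    return squareform(full[np.ix_(perm, perm)], checks=False)


def mantel_test(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> dict:
    """Mantel correlation between two distance matrices.

    r is the (Spearman or Pearson) correlation of the condensed upper
    triangles; the p-value comes from simultaneous row/column permutation of
    the second matrix, one-tailed for positive association by default
    (``alternative="two-sided"`` doubles the smaller tail).
    p = (1 + #{permuted r >= observed}) / (1 + permutations).
    """
    _check_labels(dm1, dm2)
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    n = dm1.n
    a = _mantel_vectors(dm1, method)
    v2 = dm2.condensed()
    b = _mantel_vectors(dm2, method)
    r_obs = _corr(a, b)
    rng = np.random.default_rng(seed)
    count_ge = 0
    count_le = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        bp = _permuted_condensed(v2, n, perm)
        if method == "spearman":
            bp = rankdata(bp)
        r_perm = _corr(a, bp)
        if r_perm >= r_obs:
            count_ge += 1
        if r_perm <= r_obs:
            count_le += 1
    p_greater = (1 + count_ge) / (1 + permutations)
    p_less = (1 + count_le) / (1 + permutations)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return {"r": r_obs, "p": p, "permutations": permutations, "method": method}


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def partial_mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    dm3: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> dict:
    """Mantel correlation of dm1 and dm2 with dm3 linearly removed.

    Both (rank-transformed, for Spearman) condensed triangles are
    residualised on dm3's, the residuals correlated, and significance
    obtained by permuting the residualised dm2 rows/columns.  Degenerate
    inputs (a residual with no variance, e.g. dm1 = dm2 = dm3) report r = 0
    with p = 1 and a warning.
    """
    _check_labels(dm1, dm2, dm3)
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    n = dm1.n
    a = _mantel_vectors(dm1, method)
    b = _mantel_vectors(dm2, method)
    c = _mantel_vectors(dm3, method)
    ra = _residualize(a, c)
    rb = _residualize(b, c)
    if np.allclose(ra, 0) or np.allclose(rb, 0):
        warnings.warn("degenerate partial Mantel (residuals vanish)", stacklevel=2)
        return {"r": 0.0, "p": 1.0, "permutations": permutations, "method": method,
                "degenerate": True}
    r_obs = _corr(ra, rb)
    rng = np.random.default_rng(seed)
    count_ge = 0
    count_le = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        rb_perm = _permuted_condensed(rb, n, perm)
        r_perm = _corr(ra, rb_perm)
        if r_perm >= r_obs:
            count_ge += 1
        if r_perm <= r_obs:
            count_le += 1
    p_greater = (1 + count_ge) / (1 + permutations)
    p_less = (1 + count_le) / (1 + permutations)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return {"r": r_obs, "p": p, "permutations": permutations, "method": method,
            "degenerate": False}


# ---------------------------------------------------------------------------
# ANOSIM / PCoA / distance-decay
# ---------------------------------------------------------------------------

def anosim(
    dm: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Global ANOSIM R and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/4) with
    M = n(n-1)/2; R near 0 means no separation, 1 complete separation.
    """
    groups = pd.Series(np.asarray(groups, dtype=object), index=dm.labels)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (sizes < 2).any():
        raise ValueError(f"singleton groups: {sizes.index[sizes < 2].tolist()}")
    sk_dm = skbio.DistanceMatrix(dm.values, ids=dm.labels)
    res = _skbio_anosim(
        sk_dm, groups.to_numpy(), permutations=permutations, seed=seed
    )
    return {
        "R": float(res["test statistic"]),
        "p": float(res["p-value"]),
        "permutations": permutations,
    }


def pcoa(dm: DistanceMatrix) -> dict:
    """Principal coordinate analysis (Gower double-centering + eigh).

    Returns sample coordinates, eigenvalues (negatives reported, not
    corrected) and the proportion of variance per axis, sorted by
    eigenvalue.
    """
    if dm.n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    sk_dm = skbio.DistanceMatrix(dm.values, ids=dm.labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(sk_dm, method="eigh", warn_neg_eigval=False)
    return {
        "coordinates": res.samples,
        "eigenvalues": res.eigvals.to_numpy(),
        "proportion_explained": res.proportion_explained.to_numpy(),
    }


def distance_decay(
    sim: DistanceMatrix,
    dist: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Distance-decay of community similarity with geographic distance.

    Ordinary least squares of pairwise similarity on pairwise distance over
    the n(n-1)/2 unordered pairs gives slope and intercept; the correlation
    and its significance come from a Mantel test (pairs are not independent,
    so a naive regression p-value would be anticonservative).  A negative
    association (decay) is the tested alternative.
    """
    _check_labels(sim, dist)
    s = sim.condensed()
    d = dist.condensed()
    slope, intercept = np.polyfit(d, s, 1)
    mt = mantel_test(
        sim, dist, method=method, permutations=permutations, seed=seed,
        alternative="less",
    )
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r": mt["r"],
        "p": mt["p"],
        "n_pairs": len(s),
        "method": method,
    }
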