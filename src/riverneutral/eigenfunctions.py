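"""Spatial eigenfunction bases: PCNM and directional AEM.

PCNM (principal coordinates of neighbour matrices) models symmetric spatial
structure: the geographic distance matrix is truncated (distances beyond a
threshold replaced by four times the threshold), principal coordinates are
extracted, and the positive-eigenvalue axes become spatial predictors.

AEM (asymmetric eigenvector maps) models directional structure on a river
network: a binary site-by-edge matrix records which directed edges lie
upstream of each site, edges are down-weighted by
``w = 1 - (d / d_max)^2`` (d = network distance of the linked pair), and the
left singular vectors of the centred weighted matrix form the basis.  Unlike
PCNM, AEM vectors change when flow direction is reversed — directionality is
the point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .beta import DistanceMatrix, RiverNetwork

_EIG_TOL = 1e-8


@dataclass
class SpatialEigenbasis:
    """Centered, mutually orthogonal spatial predictor columns."""

    vectors: pd.DataFrame  # index = site ids, one column per eigenfunction
    eigenvalues: np.ndarray
    kind: str  # "pcnm" | "aem"
    params: dict

    def __post_init__(self) -> None:
        v = self.vectors.to_numpy()
        if v.size:
            if np.max(np.abs(v.mean(axis=0))) > 1e-8:
                raise ValueError("eigenfunction columns must be centered")
            gram = v.T @ v
            off = gram - np.diag(np.diag(gram))
            if np.max(np.abs(off)) > 1e-6 * max(np.max(np.abs(gram)), 1.0):
                raise ValueError("eigenfunction columns must be orthogonal")

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def write(self, tsv_path, json_path=None) -> None:
        import json as _json

        self.vectors.rename_axis("site").to_csv(tsv_path, sep="\t", lineterminator="\n")
        if json_path is not None:
            with open(json_path, "w") as fh:
                _json.dump(
                    {
                        "kind": self.kind,
                        "eigenvalues": self.eigenvalues.tolist(),
                        "params": self.params,
                    },
                    fh,
                    indent=1,
                )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # reproducible sign convention: largest-|loading| entry positive
    for j in range(vectors.shape[1]):
        i = int(np.argmax(np.abs(vectors[:, j])))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return vectors


def pcnm_vectors(
    dist: DistanceMatrix, truncation: float | None = None
) -> SpatialEigenbasis:
    """PCNM eigenfunctions of a geographic distance matrix.

    ``truncation=None`` uses the longest edge of the minimum spanning tree
    (the smallest threshold keeping all sites connected).  Distances above
    the threshold are replaced by 4x the threshold, the truncated matrix is
    double-centered (Gower), and eigenvectors with positive eigenvalues are
    retained, scaled to unit norm.
    """
    n = dist.n
    if n < 4:
        raise ValueError("PCNM needs at least 4 sites")
    d = dist.values.copy()
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    if truncation <= 0:
        raise ValueError("truncation must be positive")
    d_trunc = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(d_trunc, 0.0)

    a = -0.5 * d_trunc**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > _EIG_TOL * max(abs(eigval).max(), 1.0)
    vectors = _fix_signs(eigvec[:, keep].copy())
    return SpatialEigenbasis(
        vectors=pd.DataFrame(
            vectors,
            index=dist.labels,
            columns=[f"PCNM{j + 1}" for j in range(int(keep.sum()))],
        ),
        eigenvalues=eigval[keep],
        kind="pcnm",
        params={"truncation_km": truncation},
    )


def build_site_by_edge(
    network: RiverNetwork, sites: list[str] | None = None
) -> pd.DataFrame:
    """Binary matrix marking which directed edges lie upstream of each site.

    Entry (s, e) = 1 iff edge e is on the directed path from a network
    origin (source node) down to site s.  Requires a dendritic (acyclic)
    directed network; a cycle raises.
    """
    g = network.directed_graph()
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("river network contains a directed cycle")
    if sites is None:
        sites = list(network.nodes.index)
    edge_ids = [f"{u}->{v}" for u, v, _ in network.edges]
    edge_index = {eid: k for k, eid in enumerate(edge_ids)}
    mat = np.zeros((len(sites), len(network.edges)), dtype=int)
    rev = g.reverse()
    for i, s in enumerate(sites):
        if s not in g:
            raise ValueError(f"site {s!r} is not on the network")
        # all edges whose head is an ancestor-or-self of s
        upstream_nodes = nx.descendants(rev, s) | {s}
        for u, v, _ in network.edges:
            if v in upstream_nodes:
                mat[i, edge_index[f"{u}->{v}"]] = 1
    return pd.DataFrame(mat, index=sites, columns=edge_ids)


def aem_vectors(
    site_by_edge: pd.DataFrame, edge_lengths: np.ndarray | list[float],
    weight: str = "parabolic",
) -> SpatialEigenbasis:
    """AEM eigenfunctions from a site-by-edge matrix and edge lengths.

    Each edge column is scaled by ``w = 1 - (d / d_max)^2`` (d_max = maximum
    edge length among the linked pairs; the longest link gets weight 0),
    columns are centered, and the left singular vectors with positive
    singular values form the basis.  ``weight="none"`` skips the weighting.
    """
    e = site_by_edge.to_numpy(dtype=float)
    d = np.asarray(edge_lengths, dtype=float)
    if d.shape[0] != e.shape[1]:
        raise ValueError("edge_lengths must align with site_by_edge columns")
    if np.any(d <= 0):
        raise ValueError("edge lengths must be positive")
    if weight == "parabolic":
        d_max = d.max()
        w = 1.0 - (d / d_max) ** 2
        if np.max(w) == 0.0:
            # every edge sits at d_max (all lengths equal): the parabolic
            # down-weighting carries no information, so fall back to unit
            # weights rather than annihilating the basis
            warnings.warn(
                "all edges share the maximum length; parabolic weights are "
                "degenerate, using unit weights",
                stacklevel=2,
            )
            w = np.ones_like(d)
    elif weight == "none":
        w = np.ones_like(d)
    else:
        raise ValueError(f"unknown weighting {weight!r}")
    weighted = e * w[None, :]
    centered = weighted - weighted.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        warnings.warn("no spatial structure (all site rows equal)", stacklevel=2)
        return SpatialEigenbasis(
            vectors=pd.DataFrame(index=site_by_edge.index),
            eigenvalues=np.empty(0),
            kind="aem",
            params={"weight": weight, "d_max": float(d.max())},
        )
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    keep = s > _EIG_TOL * s.max()
    vectors = _fix_signs(u[:, keep].copy())
    return SpatialEigenbasis(
        vectors=pd.DataFrame(
            vectors,
            index=site_by_edge.index,
            columns=[f"AEM{j + 1}" for j in range(int(keep.sum()))],
        ),
        eigenvalues=(s[keep] ** 2),
        kind="aem",
        params={"weight": weight, "d_max": float(d.max())},
    )


def aem_from_network(network: RiverNetwork, sites: list[str] | None = None) -> SpatialEigenbasis:
    """Convenience: site-by-edge construction + parabolic weighting + SVD."""
    sbe = build_site_by_edge(network, sites)
    lengths = [w for _, _, w in network.edges]
    return aem_vectors(sbe, lengths)
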