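"""Synthetic metacommunities, river networks and niche-structured communities.

Everything the pipeline consumes can be generated here with known ground
truth:

* neutral local communities — a lognormal metacommunity sampled through
  Sloan's immigration model.  The stationary distribution of the underlying
  birth-death-immigration process is Dirichlet with concentration
  ``Nm * metacommunity proportions``; local compositions are drawn from it
  and then sequenced as a multinomial of N reads.  This is exact for the
  occupancy-abundance relationship the model fit uses, and far faster than
  simulating the Markov chain (a slow explicit-chain sampler is kept for
  cross-checks, see :func:`simulate_neutral_chain`);
* dendritic (tree-shaped) river networks with site coordinates laid out so
  that straight-line distance never exceeds along-network distance;
* niche-structured communities whose expected abundances follow Gaussian
  responses to an environmental gradient, blurred by spatially
  autocorrelated lognormal noise on the network.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .beta import RiverNetwork
from .otu import OtuTable

#: default desk-scale shape mirroring the study design: 30 sites along the
#: river, rarefied depth 10^4 reads, 2000-taxon species pool
DEFAULT_N_SITES = 30
DEFAULT_DEPTH = 10_000
DEFAULT_S = 2000


@dataclass
class NeutralSimConfig:
    """Parameters of a neutral metacommunity simulation."""

    S: int = DEFAULT_S
    Nm: float = 1000.0
    N: int = DEFAULT_DEPTH
    n_sites: int = DEFAULT_N_SITES
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Nm <= 0:
            raise ValueError("Nm must be positive")
        if min(self.S, self.N, self.n_sites) <= 0:
            raise ValueError("S, N and n_sites must be positive")


@dataclass
class NicheSimConfig:
    """Parameters of a niche-structured (deterministic-assembly) simulation."""

    S: int = 200
    N: int = DEFAULT_DEPTH
    niche_strength: float = 1.0  # 0 switches the gradient response off
    niche_width: float = 0.25  # as a fraction of the gradient range
    autocorr_range_km: float = 10.0  # 0 switches spatial noise correlation off
    noise_sigma: float = 0.5  # lognormal dispersion of the site noise
    n_env_noise: int = 23  # uninformative environment columns emitted
    seed: int = 0


def _metacommunity(cfg: NeutralSimConfig, rng: np.random.Generator) -> np.ndarray:
    ab = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, size=cfg.S)
    return ab / ab.sum()


def simulate_neutral_samples(
    cfg: NeutralSimConfig, metacommunity: np.ndarray | None = None
) -> OtuTable:
    """Sample local communities under Sloan's immigration model.

    Per site, local relative abundances are Dirichlet(Nm * p) and N reads
    are drawn multinomially.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if metacommunity is None:
        p = _metacommunity(cfg, rng)
    else:
        p = np.asarray(metacommunity, dtype=float)
        p = p / p.sum()
        if len(p) != cfg.S:
            raise ValueError("metacommunity length must equal cfg.S")
    counts = np.empty((cfg.n_sites, cfg.S), dtype=np.int64)
    alpha = cfg.Nm * p
    for i in range(cfg.n_sites):
        # gamma-normalisation form of the Dirichlet; tiny shapes may underflow
        # to exact zeros, which is the correct absent-taxon limit
        g = rng.gamma(shape=alpha, scale=1.0)
        tot = g.sum()
        local = g / tot if tot > 0 else p
        counts[i] = rng.multinomial(cfg.N, local)
    table = pd.DataFrame(
        counts,
        index=[f"site{i + 1:02d}" for i in range(cfg.n_sites)],
        columns=[f"OTU{j + 1:05d}" for j in range(cfg.S)],
    )
    return OtuTable(table)


def simulate_neutral_chain(
    metacommunity: np.ndarray,
    Nm: float,
    community_size: int = 500,
    generations: int = 2000,
    n_sites: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Explicit birth-death-immigration Markov chain (slow oracle).

    Individuals die one per step; the replacement is an immigrant drawn from
    the metacommunity with probability m = Nm / community_size, else the
    offspring of a random local survivor.  Returns per-site relative
    abundances after ``generations`` community turnovers.  Only intended for
    tiny cross-checks of the Dirichlet stationary approximation.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(metacommunity, dtype=float)
    p = p / p.sum()
    S = len(p)
    m = min(Nm / community_size, 1.0)
    out = np.empty((n_sites, S))
    for s in range(n_sites):
        comm = rng.multinomial(community_size, p)
        for _ in range(generations * community_size):
            dead = rng.choice(S, p=comm / community_size)
            comm[dead] -= 1
            if rng.random() < m:
                born = rng.choice(S, p=p)
            else:
                born = rng.choice(S, p=comm / (community_size - 1))
            comm[born] += 1
        out[s] = comm / community_size
    return out


def simulate_river_network(
    n_sites: int,
    branching: float = 0.35,
    mean_edge_km: float = 3.0,
    sinuosity: float = 1.3,
    seed: int = 0,
    origin_lon: float = 116.5,
    origin_lat: float = 25.2,
) -> RiverNetwork:
    """Random dendritic river network with site coordinates.

    A random tree grows from a single source; each new site attaches to an
    existing one (preferring recent, chain-like growth unless ``branching``
    triggers a fork).  Edge length = straight-line distance × ``sinuosity``
    (>= 1), so the along-network distance between any two sites is at least
    their straight-line separation.  Flow is directed away from the source
    (node 0 is the headwater origin; edges point downstream).
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    if sinuosity < 1.0:
        raise ValueError("sinuosity must be >= 1")
    rng = np.random.default_rng(seed)
    # planar layout in km relative to the origin
    xy = np.zeros((n_sites, 2))
    parent = np.full(n_sites, -1)
    heading = {0: rng.uniform(0, 2 * math.pi)}
    tips = [0]
    for v in range(1, n_sites):
        if rng.random() < branching or not tips:
            u = int(rng.integers(0, v))  # fork off any existing node
            ang = heading[u] + rng.uniform(-1.2, 1.2)
        else:
            u = tips.pop(rng.integers(0, len(tips)))  # extend a tip
            ang = heading[u] + rng.uniform(-0.5, 0.5)
        straight = rng.gamma(4.0, mean_edge_km / sinuosity / 4.0) + 0.1
        cand = xy[u] + straight * np.array([math.cos(ang), math.sin(ang)])
        # reject placements that would fold the tree back on itself
        for _ in range(40):
            d_new = np.linalg.norm(xy[:v] - cand, axis=1)
            if np.all(d_new > 0.25 * straight):
                break
            ang = heading[u] + rng.uniform(-math.pi, math.pi)
            cand = xy[u] + straight * np.array([math.cos(ang), math.sin(ang)])
        xy[v] = cand
        parent[v] = u
        heading[v] = ang
        tips.append(v)
    # km offsets -> lon/lat (local tangent plane approximation)
    km_per_deg_lat = 111.19
    lat = origin_lat + xy[:, 1] / km_per_deg_lat
    lon = origin_lon + xy[:, 0] / (km_per_deg_lat * math.cos(math.radians(origin_lat)))
    nodes = pd.DataFrame(
        {"longitude": lon, "latitude": lat},
        index=[f"site{i + 1:02d}" for i in range(n_sites)],
    )
    edges = []
    for v in range(1, n_sites):
        u = parent[v]
        straight = float(np.linalg.norm(xy[v] - xy[u]))
        edges.append((nodes.index[u], nodes.index[v], straight * sinuosity))
    return RiverNetwork(nodes=nodes, edges=edges)


def _network_distance_matrix(network: RiverNetwork) -> np.ndarray:
    g = network.undirected_graph()
    ids = list(network.nodes.index)
    n = len(ids)
    out = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            out[i, j] = lengths[a][b]
    return out


def simulate_niche_communities(
    cfg: NicheSimConfig, network: RiverNetwork
) -> tuple[OtuTable, pd.DataFrame]:
    """Niche-structured communities tracking a gradient along the network.

    The primary gradient is the along-network distance from the source
    (plus noise); each taxon has a Gaussian response to it with optimum
    spread over the gradient range.  Expected abundances are multiplied by
    lognormal noise whose log has an exponential spatial correlation on the
    network (range ``autocorr_range_km``), then sequenced as a multinomial.

    Returns the count table and an environment table whose first column
    (``gradient``) is the informative variable, followed by a few correlates
    and ``n_env_noise`` pure-noise columns (24 columns by default, the width
    of a typical river physicochemistry panel).
    """
    rng = np.random.default_rng(cfg.seed)
    ids = list(network.nodes.index)
    n = len(ids)
    netd = _network_distance_matrix(network)
    gradient = netd[0]  # distance downstream from the source
    grange = max(gradient.max() - gradient.min(), 1e-9)
    z = (gradient - gradient.min()) / grange  # gradient scaled to [0, 1]

    optima = rng.uniform(-0.1, 1.1, size=cfg.S)
    widths = np.maximum(cfg.niche_width * (0.5 + rng.random(cfg.S)), 1e-3)
    base = np.exp(rng.normal(0, 1.0, size=cfg.S))
    response = np.exp(
        -cfg.niche_strength * ((z[:, None] - optima[None, :]) / widths[None, :]) ** 2
    )
    expected = base[None, :] * response

    if cfg.autocorr_range_km > 0:
        cov = cfg.noise_sigma**2 * np.exp(-netd / cfg.autocorr_range_km)
    else:
        cov = cfg.noise_sigma**2 * np.eye(n)
    cov = cov + 1e-10 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    noise = np.exp(chol @ rng.normal(size=(n, cfg.S)))
    expected = expected * noise
    probs = expected / expected.sum(axis=1, keepdims=True)

    counts = np.vstack([rng.multinomial(cfg.N, probs[i]) for i in range(n)])
    meta = network.nodes.copy()
    meta["site"] = ids
    table = OtuTable(
        pd.DataFrame(
            counts, index=ids, columns=[f"OTU{j + 1:05d}" for j in range(cfg.S)]
        ),
        sample_meta=meta,
    )

    env = {"gradient": gradient}
    env["gradient_sq"] = gradient**2
    for k in range(cfg.n_env_noise):
        env[f"env_noise{k + 1:02d}"] = rng.normal(size=n)
    env_table = pd.DataFrame(env, index=ids)
    return table, env_table


def simulate_two_seasons(
    wet_cfg: NeutralSimConfig,
    dry_cfg: NeutralSimConfig,
    seed: int = 0,
) -> tuple[OtuTable, OtuTable]:
    """Wet/dry season pair drawn from one shared metacommunity.

    Both tables use the same lognormal metacommunity (drawn from ``seed``);
    the seasons differ only in Nm (and any other per-season config fields).
    Emulates the contrast of a high-dispersal wet season versus a more
    dispersal-limited dry season.
    """
    if wet_cfg.S != dry_cfg.S:
        raise ValueError("seasons must share the species pool size")
    rng = np.random.default_rng(seed)
    shared_cfg = replace(wet_cfg, seed=seed)
    p = _metacommunity(shared_cfg, rng)
    sub = np.random.SeedSequence(seed).spawn(2)
    wet = simulate_neutral_samples(
        replace(wet_cfg, seed=int(sub[0].generate_state(1)[0] % (2**31))), metacommunity=p
    )
    dry = simulate_neutral_samples(
        replace(dry_cfg, seed=int(sub[1].generate_state(1)[0] % (2**31))), metacommunity=p
    )
    wet.counts.index = [f"wet{i + 1:02d}" for i in range(wet.n_samples)]
    dry.counts.index = [f"dry{i + 1:02d}" for i in range(dry.n_samples)]
    return OtuTable(wet.counts), OtuTable(dry.counts)
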