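import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from riverneutral import (
    NeutralSimConfig,
    NicheSimConfig,
    OtuTable,
    bray_curtis,
    env_distances,
    fit_ncm,
    geo_distances,
    mantel_test,
    ncm_input_from_table,
    simulate_neutral_samples,
    simulate_niche_communities,
    simulate_river_network,
    simulate_two_seasons,
)
from riverneutral.simulate import simulate_neutral_chain


class TestNeutralSimulator:
    def test_determinism(self):
        cfg = NeutralSimConfig(S=100, Nm=500, N=2000, n_sites=6, seed=9)
        a = simulate_neutral_samples(cfg)
        b = simulate_neutral_samples(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_output_is_valid_table(self):
        cfg = NeutralSimConfig(S=150, Nm=200, N=1500, n_sites=8, seed=2)
        tab = simulate_neutral_samples(cfg)
        tab.validate()
        assert (tab.sample_sums() == cfg.N).all()
        assert tab.n_samples == 8 and tab.n_otus == 150

    def test_occupancy_tracks_metacommunity_abundance(self):
        cfg = NeutralSimConfig(S=500, Nm=300, N=5000, n_sites=20, seed=4)
        rng = np.random.default_rng(cfg.seed)
        p = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, size=cfg.S)
        p = p / p.sum()
        tab = simulate_neutral_samples(cfg, metacommunity=p)
        occupancy = (tab.counts.to_numpy() > 0).mean(axis=0)
        rho, _ = spearmanr(p, occupancy)
        assert rho > 0.9

    def test_large_nm_converges_to_metacommunity(self):
        p = np.array([0.5, 0.3, 0.15, 0.05])
        tight = simulate_neutral_samples(
            NeutralSimConfig(S=4, Nm=1e7, N=100_000, n_sites=5, seed=1),
            metacommunity=p,
        )
        rel = tight.counts.div(tight.counts.sum(axis=1), axis=0).to_numpy()
        assert np.max(np.abs(rel - p[None, :])) < 0.01
        loose = simulate_neutral_samples(
            NeutralSimConfig(S=4, Nm=10.0, N=100_000, n_sites=5, seed=1),
            metacommunity=p,
        )
        rel_l = loose.counts.div(loose.counts.sum(axis=1), axis=0).to_numpy()
        assert np.max(np.abs(rel_l - p[None, :])) > np.max(np.abs(rel - p[None, :]))

    def test_invalid_nm_rejected(self):
        with pytest.raises(ValueError):
            NeutralSimConfig(Nm=-5.0)

    def test_dirichlet_matches_explicit_chain_variance(self):
        """The Dirichlet stationary shortcut against the explicit
        birth-death-immigration chain: across-site variance of local
        relative abundance should match p(1-p)/(Nm+1) for both."""
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.full(8, 5.0))
        Nm, size = 20.0, 400
        chain = simulate_neutral_chain(
            p, Nm, community_size=size, generations=40, n_sites=15, seed=3
        )
        theo_var = p * (1 - p) / (Nm + 1)
        ratio = chain.var(axis=0, ddof=1) / theo_var
        assert 0.5 < ratio.mean() < 1.7


class TestRiverNetworkSimulator:
    def test_tree_and_determinism(self):
        net = simulate_river_network(15, seed=6)
        g = net.undirected_graph()
        import networkx as nx

        assert nx.is_connected(g)
        assert len(net.edges) == len(net.nodes) - 1
        net2 = simulate_river_network(15, seed=6)
        assert net.edges == net2.edges
        pd.testing.assert_frame_equal(net.nodes, net2.nodes)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_dendritic_at_least_straight_line(self, seed):
        net = simulate_river_network(12, seed=seed)
        dend = geo_distances(net.nodes, network=net).values
        eucl = geo_distances(net.nodes).values
        assert np.all(dend - eucl >= -1e-6)

    def test_flow_from_single_source(self):
        net = simulate_river_network(10, seed=5)
        assert len(net.sources()) == 1


class TestNicheSimulator:
    def test_null_config_unstructured(self):
        """No niche response, no spatial autocorrelation: community distance
        correlates with neither environment nor geography."""
        net = simulate_river_network(14, seed=7)
        cfg = NicheSimConfig(S=150, N=3000, niche_strength=0.0,
                             autocorr_range_km=0.0, n_env_noise=4, seed=7)
        tab, env = simulate_niche_communities(cfg, net)
        dm = bray_curtis(tab)
        r_env = mantel_test(dm, env_distances(env), permutations=99, seed=0)
        r_geo = mantel_test(dm, geo_distances(net.nodes), permutations=99, seed=0)
        assert abs(r_env["r"]) < 0.3
        assert abs(r_geo["r"]) < 0.3

    def test_strong_gradient_mantel_power(self):
        hits = 0
        for seed in range(6):
            net = simulate_river_network(14, seed=seed)
            cfg = NicheSimConfig(S=150, N=3000, niche_strength=3.0,
                                 noise_sigma=0.2, n_env_noise=4, seed=seed)
            tab, env = simulate_niche_communities(cfg, net)
            dm = bray_curtis(tab)
            res = mantel_test(dm, env_distances(env[["gradient"]]),
                              permutations=99, seed=seed)
            hits += res["r"] > 0 and res["p"] <= 0.05
        assert hits >= 5

    def test_env_table_shape(self):
        net = simulate_river_network(10, seed=1)
        cfg = NicheSimConfig(S=50, N=1000, n_env_noise=22, seed=1)
        tab, env = simulate_niche_communities(cfg, net)
        assert env.shape == (10, 24)  # gradient + gradient_sq + 22 noise
        assert list(env.index) == tab.sample_ids

    def test_niche_taxa_enriched_off_neutral_curve(self):
        """Mixing neutral with strongly niche-structured taxa: the latter are
        over-represented outside the fitted neutral envelope."""
        net = simulate_river_network(25, seed=11)
        depth = 8000
        neutral = simulate_neutral_samples(
            NeutralSimConfig(S=800, Nm=1000, N=depth, n_sites=25, seed=11)
        )
        niche_cfg = NicheSimConfig(S=200, N=depth, niche_strength=4.0,
                                   niche_width=0.08, noise_sigma=0.1, seed=11)
        niche_tab, _ = simulate_niche_communities(niche_cfg, net)
        counts = pd.concat(
            [
                neutral.counts.set_index(niche_tab.counts.index),
                niche_tab.counts.add_prefix("niche_"),
            ],
            axis=1,
        )
        mixed = OtuTable(counts)
        inp = ncm_input_from_table(mixed)
        fit = fit_ncm(inp)
        is_niche = np.array([o.startswith("niche_") for o in inp.otu_ids])
        off = fit.partition != "neutral"
        frac_niche_off = off[is_niche].mean()
        frac_neutral_off = off[~is_niche].mean()
        assert frac_niche_off > 1.5 * frac_neutral_off


class TestTwoSeasons:
    def test_shared_metacommunity_and_determinism(self):
        wet_cfg = NeutralSimConfig(S=300, Nm=2000, N=4000, n_sites=10)
        dry_cfg = NeutralSimConfig(S=300, Nm=1000, N=4000, n_sites=10)
        w1, d1 = simulate_two_seasons(wet_cfg, dry_cfg, seed=3)
        w2, d2 = simulate_two_seasons(wet_cfg, dry_cfg, seed=3)
        pd.testing.assert_frame_equal(w1.counts, w2.counts)
        pd.testing.assert_frame_equal(d1.counts, d2.counts)
        assert w1.sample_ids[0].startswith("wet")
        assert d1.sample_ids[0].startswith("dry")

    def test_seasons_share_pool_but_differ(self):
        wet_cfg = NeutralSimConfig(S=300, Nm=2000, N=4000, n_sites=10)
        dry_cfg = NeutralSimConfig(S=300, Nm=100, N=4000, n_sites=10)
        wet, dry = simulate_two_seasons(wet_cfg, dry_cfg, seed=4)
        assert wet.otu_ids == dry.otu_ids
        # the low-Nm season tracks the shared pool more loosely
        m_w = fit_ncm(ncm_input_from_table(wet)).m
        m_d = fit_ncm(ncm_input_from_table(dry)).m
        assert m_w > m_d

    def test_mismatched_pools_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            simulate_two_seasons(
                NeutralSimConfig(S=100), NeutralSimConfig(S=200), seed=0
            )
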