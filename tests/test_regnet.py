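"""Coherence network construction, RD, and the degree-preserving null."""

import numpy as np
import pytest

import coldmir as cm
from conftest import star_network
from oracles import enumerate_bipartite_graphs, rd_of_edge_set


class TestBuildAndClassify:
    def test_empty_target_map_gives_isolated_nodes(self):
        net = cm.build_network({"m1": "up"}, {"g1": "down"}, [])
        assert net.n_edges == 0
        iso_m, iso_g = net.isolated_nodes()
        assert iso_m == ["m1"] and iso_g == ["g1"]

    def test_full_bipartite_construction(self):
        net = cm.build_network(
            {"m1": "up", "m2": "down"},
            {"g1": "up", "g2": "down", "g3": "up"},
            [(m, g) for m in ("m1", "m2") for g in ("g1", "g2", "g3")],
        )
        assert net.n_edges == 6
        dm, dg = net.degrees()
        assert list(dm) == [3, 3] and list(dg) == [2, 2, 2]

    def test_pairs_outside_node_sets_ignored(self):
        net = cm.build_network({"m1": "up"}, {"g1": "down"}, [("m1", "g1"), ("m9", "g1"), ("m1", "g9")])
        assert net.n_edges == 1

    def test_id_collision_rejected(self):
        with pytest.raises(ValueError, match="both namespaces"):
            cm.build_network({"x": "up"}, {"x": "down"}, [])

    @pytest.mark.parametrize(
        "mdir,gdir,label",
        [("up", "down", "coherent"), ("down", "up", "coherent"),
         ("up", "up", "incoherent"), ("down", "down", "incoherent")],
    )
    def test_coherence_definition(self, mdir, gdir, label):
        net = cm.build_network({"m1": mdir}, {"g1": gdir}, [("m1", "g1")])
        assert cm.classify_edges(net)[0]["label"] == label

    def test_global_direction_flip_preserves_labels_and_rd(self):
        net = star_network(5, 3)
        flipped = cm.build_network(
            {"m1": "down"},
            {g: ("up" if g.startswith("gc") else "down") for g in net.gene_ids},
            [("m1", g) for g in net.gene_ids],
        )
        assert list(net.edge_coherent()) == list(flipped.edge_coherent())
        assert cm.regulatory_density(net) == cm.regulatory_density(flipped)


class TestRegulatoryDensity:
    def test_97_edge_network_value(self):
        assert cm.regulatory_density(star_network(54, 43)) == pytest.approx(11 / 97)
        assert round(cm.regulatory_density(star_network(54, 43)), 4) == 0.1134

    def test_203_edge_network_value(self):
        assert round(cm.regulatory_density(star_network(103, 100)), 4) == 0.0148

    def test_extremes_and_balance(self):
        assert cm.regulatory_density(star_network(7, 0)) == 1.0
        assert cm.regulatory_density(star_network(0, 7)) == -1.0
        assert cm.regulatory_density(star_network(4, 4)) == 0.0

    def test_zero_edge_network_errors(self):
        net = cm.build_network({"m1": "up"}, {"g1": "down"}, [])
        with pytest.raises(ValueError):
            cm.regulatory_density(net)

    def test_rd_lies_on_lattice(self, rng):
        """RD of any network with E edges is (2c-E)/E for integer c."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            genes = {f"g{i}": ("up" if r.random() < 0.5 else "down") for i in range(30)}
            mirnas = {f"m{i}": ("up" if r.random() < 0.5 else "down") for i in range(5)}
            pairs = [(m, g) for m in mirnas for g in genes if r.random() < 0.3]
            if not pairs:
                continue
            net = cm.build_network(mirnas, genes, pairs)
            rd = cm.regulatory_density(net)
            e = net.n_edges
            lattice = {(2 * c - e) / e for c in range(e + 1)}
            assert any(abs(rd - v) < 1e-12 for v in lattice)


def random_net(seed, n_mirnas=6, n_genes=15, p=0.4):
    r = np.random.default_rng(seed)
    mirnas = {f"m{i}": ("up" if r.random() < 0.5 else "down") for i in range(n_mirnas)}
    genes = {f"g{i}": ("up" if r.random() < 0.5 else "down") for i in range(n_genes)}
    pairs = [(m, g) for m in mirnas for g in genes if r.random() < p]
    return cm.build_network(mirnas, genes, pairs)


class TestShuffle:
    def test_degree_sequence_always_preserved(self):
        net = random_net(3)
        for seed in range(20):
            sh = cm.shuffle_degree_preserving(net, seed)
            assert np.array_equal(sh.degrees()[0], net.degrees()[0])
            assert np.array_equal(sh.degrees()[1], net.degrees()[1])
            # no duplicate edges
            assert len({(m, g) for m, g in zip(sh.edge_mirna, sh.edge_gene)}) == sh.n_edges

    def test_complete_bipartite_2x2_is_rigid(self):
        net = cm.build_network(
            {"m1": "up", "m2": "down"},
            {"g1": "up", "g2": "down"},
            [("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2")],
        )
        with pytest.warns(UserWarning, match="no valid"):
            sh = cm.shuffle_degree_preserving(net, 0)
        assert cm.regulatory_density(sh) == cm.regulatory_density(net)

    def test_directions_untouched_by_shuffle(self):
        net = random_net(5)
        sh = cm.shuffle_degree_preserving(net, 1)
        assert np.array_equal(sh.mirna_dir, net.mirna_dir)
        assert np.array_equal(sh.gene_dir, net.gene_dir)

    def test_chain_samples_uniformly_over_degree_class(self):
        """Shuffle RD frequencies match exhaustive enumeration of all
        bipartite graphs with the same degree sequence (3x4, 6 edges)."""
        mirnas = {"m0": "up", "m1": "down", "m2": "up"}
        genes = {"g0": "down", "g1": "up", "g2": "down", "g3": "up"}
        pairs = [("m0", "g0"), ("m0", "g1"), ("m0", "g2"),
                 ("m1", "g0"), ("m1", "g3"), ("m2", "g1")]
        net = cm.build_network(mirnas, genes, pairs)
        row_deg, col_deg = net.degrees()
        graphs = enumerate_bipartite_graphs(list(row_deg), list(col_deg))
        row_dir = {i: d for i, d in enumerate(net.mirna_dir)}
        col_dir = {j: d for j, d in enumerate(net.gene_dir)}
        exact = {}
        for gset in graphs:
            rd = round(rd_of_edge_set(gset, row_dir, col_dir), 9)
            exact[rd] = exact.get(rd, 0) + 1
        total = sum(exact.values())
        n_rep = 3000
        observed = {}
        for seed in range(n_rep):
            sh = cm.shuffle_degree_preserving(net, seed)
            rd = round(cm.regulatory_density(sh), 9)
            observed[rd] = observed.get(rd, 0) + 1
        assert set(observed) <= set(exact)
        for rd, cnt in exact.items():
            expected = cnt / total
            got = observed.get(rd, 0) / n_rep
            sd = (expected * (1 - expected) / n_rep) ** 0.5
            assert abs(got - expected) < 5 * sd + 0.01, (rd, got, expected)


class TestRDNullTest:
    def test_empirical_p_formula_and_quantile_order(self):
        net = random_net(7)
        res = cm.rd_null_test(net, n=99, seed=3)
        k = int((res.null_rds >= res.observed_rd).sum())
        assert res.empirical_p == pytest.approx((1 + k) / 100)
        assert res.q95 <= res.q99
        assert 0 < res.empirical_p <= 1

    def test_observed_above_all_null_gives_minimal_p(self):
        # strongly coherent network of private star components
        mirnas = {f"m{i}": "up" for i in range(3)}
        mirnas.update({f"m{i}": "down" for i in range(3, 6)})
        genes = {}
        pairs = []
        gi = 0
        for m, d in mirnas.items():
            for _ in range(8):
                genes[f"g{gi}"] = "down" if d == "up" else "up"
                pairs.append((m, f"g{gi}"))
                gi += 1
        net = cm.build_network(mirnas, genes, pairs)
        assert cm.regulatory_density(net) == 1.0
        res = cm.rd_null_test(net, n=200, seed=11)
        if (res.null_rds < 1.0).all():
            assert res.empirical_p == pytest.approx(1 / 201)

    def test_fixed_seed_reproduces_null_distribution(self):
        net = random_net(9)
        a = cm.rd_null_test(net, n=50, seed=4)
        b = cm.rd_null_test(net, n=50, seed=4)
        assert np.array_equal(a.null_rds, b.null_rds)
        c = cm.rd_null_test(net, n=50, seed=5)
        assert not np.array_equal(a.null_rds, c.null_rds)

    def test_zero_or_one_edge_network_errors(self):
        net = cm.build_network({"m1": "up"}, {"g1": "down"}, [("m1", "g1")])
        with pytest.raises(ValueError):
            cm.rd_null_test(net, n=10, seed=0)
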