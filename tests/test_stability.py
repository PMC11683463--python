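import math

import networkx as nx
import numpy as np
import pytest
from cohesion_oracle import brute_force_cohesion
from conftest import make_network

from phodnet.core_io import OtuTable, SignedNetwork
from phodnet.errors import ValidationError
from phodnet.stability import (
    cohesion,
    global_efficiency,
    natural_connectivity,
    robustness_curve,
    vulnerability,
)


def random_signed_network(n, p, seed, require_connected=False):
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        if not require_connected or nx.is_connected(g):
            break
    return SignedNetwork(
        [str(v) for v in g.nodes],
        [(str(a), str(b), 0.9, 1) for a, b in g.edges],
    )


class TestNaturalConnectivity:
    def test_edgeless_graph_is_zero(self):
        net = SignedNetwork(["a", "b", "c", "d"], [])
        assert natural_connectivity(net) == 0.0

    def test_k3(self, k3):
        expected = math.log((math.exp(2) + 2 * math.exp(-1)) / 3)
        assert natural_connectivity(k3) == pytest.approx(expected, abs=1e-10)

    def test_k2(self):
        net = make_network([("a", "b")])
        assert natural_connectivity(net) == pytest.approx(math.log(math.cosh(1)), abs=1e-10)

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValidationError):
            natural_connectivity(SignedNetwork([], []))

    def test_non_increasing_under_edge_deletion(self):
        rng = np.random.default_rng(7)
        for i in range(100):
            net = random_signed_network(12, 0.3, seed=1000 + i)
            if net.n_edges == 0:
                continue
            base = natural_connectivity(net)
            drop = int(rng.integers(net.n_edges))
            reduced = SignedNetwork(
                list(net.node_ids),
                [e for k, e in enumerate(net.edges) if k != drop],
            )
            assert natural_connectivity(reduced) <= base + 1e-12


class TestRobustnessCurve:
    def test_fraction_zero_matches_intact_network(self, k4):
        c = robustness_curve(k4, fractions=[0.0, 0.25], n_reps=20, seed=1)
        assert c.mean_connectivity[0] == pytest.approx(natural_connectivity(k4))
        assert c.sd_connectivity[0] == 0.0

    def test_k4_single_removal_is_deterministic_by_symmetry(self, k4, k3):
        c = robustness_curve(k4, fractions=[0.25], n_reps=50, seed=3)
        assert c.mean_connectivity[0] == pytest.approx(
            natural_connectivity(k3), abs=1e-10
        )
        assert c.sd_connectivity[0] == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical(self, two_triangles):
        a = robustness_curve(two_triangles, n_reps=30, seed=9)
        b = robustness_curve(two_triangles, n_reps=30, seed=9)
        assert a.mean_connectivity == b.mean_connectivity
        assert a.sd_connectivity == b.sd_connectivity

    def test_auc_of_flat_curve(self, k3):
        c = robustness_curve(k3, fractions=[0.0, 0.1, 0.2], n_reps=5, seed=0)
        # no node removed at any of these fractions (floor(f*3) = 0)
        assert c.auc == pytest.approx(0.2 * natural_connectivity(k3))

    @pytest.mark.parametrize(
        "kwargs", [dict(fractions=[0.5, 0.2]), dict(fractions=[-0.1]), dict(n_reps=0)]
    )
    def test_invalid_arguments(self, k3, kwargs):
        with pytest.raises(ValidationError):
            robustness_curve(k3, **kwargs)


class TestGlobalEfficiency:
    def test_complete_graph(self, k3):
        assert global_efficiency(k3) == pytest.approx(1.0)

    def test_path(self, p3):
        assert global_efficiency(p3) == pytest.approx(5 / 6)

    def test_disconnected_pair(self):
        net = SignedNetwork(["a", "b"], [])
        assert global_efficiency(net) == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValidationError):
            global_efficiency(SignedNetwork(["a"], []))


class TestVulnerability:
    def test_k3_all_zero(self, k3):
        res = vulnerability(k3)
        assert res.network_vulnerability == pytest.approx(0.0, abs=1e-12)
        assert all(abs(v) < 1e-12 for v in res.per_node.values())

    def test_p3_cut_vertex(self, p3):
        res = vulnerability(p3)
        assert res.per_node["b"] == pytest.approx(1.0)
        assert res.per_node["a"] == pytest.approx(-0.2)
        assert res.network_vulnerability == pytest.approx(1.0)

    def test_star_hub_removal(self, s4):
        res = vulnerability(s4)
        assert res.network_vulnerability == pytest.approx(1.0)
        assert max(res.per_node, key=res.per_node.get) == "h"

    def test_bounded_by_one(self):
        for seed in range(20):
            net = random_signed_network(10, 0.3, seed, require_connected=True)
            res = vulnerability(net)
            assert res.network_vulnerability <= 1.0 + 1e-12

    def test_zero_efficiency_rejected(self):
        with pytest.raises(ValidationError):
            vulnerability(SignedNetwork(["a", "b", "c"], []))


class TestCohesion:
    def test_matches_brute_force_oracle(self, cohesion_fixture):
        res = cohesion(cohesion_fixture, n_null=100, seed=7)
        conn_pos, conn_neg, c_pos, c_neg, npc = brute_force_cohesion(
            cohesion_fixture.counts, n_null=100, seed=7
        )
        np.testing.assert_allclose(
            list(res.connectedness_pos.values()), conn_pos, atol=1e-10
        )
        np.testing.assert_allclose(
            list(res.connectedness_neg.values()), conn_neg, atol=1e-10
        )
        np.testing.assert_allclose(list(res.cohesion_pos.values()), c_pos, atol=1e-10)
        np.testing.assert_allclose(list(res.cohesion_neg.values()), c_neg, atol=1e-10)
        np.testing.assert_allclose(list(res.npc.values()), npc, atol=1e-10)

    def test_all_positive_corrected_correlations_give_zero_negative_cohesion(self):
        # closure makes a fully positively correlated relative-abundance table
        # impossible (each taxon's covariances with the rest sum to -var), so
        # the contract is checked on the corrected-correlation -> cohesion step
        from phodnet.stability import cohesion_from_corrected

        rng = np.random.default_rng(4)
        n_taxa, n_samples = 5, 9
        corrected = rng.uniform(0.1, 0.9, (n_taxa, n_taxa))
        corrected = (corrected + corrected.T) / 2
        rel = rng.dirichlet(np.ones(n_taxa), size=n_samples).T
        _, conn_neg, c_pos, c_neg, npc = cohesion_from_corrected(corrected, rel)
        assert np.all(conn_neg == 0.0)
        assert np.all(c_neg == 0.0)
        assert np.all(npc == 0.0)
        assert np.all(c_pos > 0)

    def test_single_taxon_table_flagged(self):
        t = OtuTable(["t"], [f"s{i}" for i in range(6)], np.ones((1, 6)))
        res = cohesion(t, n_null=20, seed=0)
        assert all(v == 0.0 for v in res.cohesion_pos.values())
        assert all(math.isnan(v) for v in res.npc.values())

    def test_sign_contracts_on_random_tables(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            counts = rng.integers(0, 50, size=(8, 10)).astype(float)
            counts[:, counts.sum(axis=0) == 0] = 1.0
            t = OtuTable(
                [f"t{i}" for i in range(8)], [f"s{j}" for j in range(10)], counts
            )
            res = cohesion(t, n_null=20, seed=seed)
            assert all(v >= 0 for v in res.cohesion_pos.values())
            assert all(v <= 0 for v in res.cohesion_neg.values())
            assert all(
                math.isnan(v) or v >= 0 for v in res.npc.values()
            )

    def test_determinism(self, cohesion_fixture):
        a = cohesion(cohesion_fixture, n_null=30, seed=5)
        b = cohesion(cohesion_fixture, n_null=30, seed=5)
        assert a.npc == b.npc and a.cohesion_pos == b.cohesion_pos

    def test_too_few_samples_rejected(self):
        t = OtuTable(["a", "b"], [f"s{i}" for i in range(4)], np.ones((2, 4)))
        with pytest.raises(ValidationError):
            cohesion(t, n_null=20, seed=0)

    def test_small_n_null_warns(self, cohesion_fixture):
        with pytest.warns(UserWarning):
            cohesion(cohesion_fixture, n_null=5, seed=0)
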