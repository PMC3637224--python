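"""Statistical-parsimony network construction, cores, and mutation counting."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.integrate import quad

from clupeagen.coalsim import simulate_scenario
from clupeagen.network import (
    build_network,
    count_group_mutations,
    identify_cores,
    parsimony_connection_limit,
    parsimony_probability,
    watterson_theta,
)
from clupeagen.popgen_stats import segregating_sites
from clupeagen.seq_io import collapse_haplotypes

from conftest import haplotype_table


def parsimony_probability_oracle(j, L, theta):
    """Direct quadrature of the defining integrals (independent numerics)."""

    def u_same(t):
        return 0.25 + 0.75 * np.exp(-4 * theta * t / 3)

    def u_diff(t):
        return 0.75 * (1 - np.exp(-4 * theta * t / 3))

    def u_one(t):
        return theta * t * np.exp(-theta * t)

    num = quad(
        lambda t: np.exp(-t) * u_one(t) ** j * u_same(t) ** (L - j), 0, np.inf, limit=400
    )[0]
    den = quad(
        lambda t: np.exp(-t) * u_diff(t) ** j * u_same(t) ** (L - j), 0, np.inf, limit=400
    )[0]
    return num / den


class TestConnectionLimit:
    def test_single_step_connections_always_admissible(self):
        assert parsimony_connection_limit(10, 0.99, theta_site=0.5) >= 1

    @pytest.mark.parametrize("j", [1, 2, 5, 10])
    def test_parsimony_probability_matches_quadrature_oracle(self, j):
        L, theta = 1612, 0.01
        assert parsimony_probability(j, L, theta) == pytest.approx(
            parsimony_probability_oracle(j, L, theta), rel=1e-5
        )

    def test_limit_consistent_with_oracle_scan(self):
        L, conf, theta = 1612, 0.99, 0.005
        limit = parsimony_connection_limit(L, conf, theta)
        assert parsimony_probability_oracle(limit, L, theta) >= conf
        assert parsimony_probability_oracle(limit + 1, L, theta) < conf

    def test_lower_confidence_admits_longer_connections(self):
        theta = 0.01
        assert parsimony_connection_limit(1612, 0.95, theta) >= parsimony_connection_limit(
            1612, 0.99, theta
        )

    def test_watterson_estimator(self):
        # S=10, n=5: a = 1 + 1/2 + 1/3 + 1/4
        assert watterson_theta(10, 5) == pytest.approx(10 / (1 + 0.5 + 1 / 3 + 0.25))


class TestBuildNetwork:
    def test_single_haplotype_network(self):
        table = haplotype_table([("AAAA", {"P1": 3})], ["P1"])
        net = build_network(table, confidence=0.95)
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_star_of_single_step_satellites(self):
        table = haplotype_table(
            [
                ("AAAAAAAAAA", {"P1": 10}),
                ("AAAAAAAAAT", {"P1": 1}),
                ("AAAAAAAATA", {"P1": 1}),
                ("AAAAAAATAA", {"P1": 1}),
            ],
            ["P1"],
        )
        net = build_network(table, confidence=0.95)
        core = "H001"
        assert net.graph.degree[core] == 3
        assert all(d["steps"] == 1 for _, _, d in net.graph.edges(data=True))

    def test_direct_edges_carry_observed_difference_counts(self, rng):
        seqs = []
        base = rng.choice(list("ACGT"), size=40)
        for i in range(6):
            s = base.copy()
            for site in rng.choice(40, size=i, replace=False):
                s[site] = rng.choice([c for c in "ACGT" if c != base[site]])
            seqs.append("".join(s))
        table = haplotype_table([(s, {"P1": 1}) for s in seqs], ["P1"])
        net = build_network(table, confidence=0.95)
        for u, v, data in net.graph.edges(data=True):
            observed = sum(
                x != y for x, y in zip(table.sequences[u], table.sequences[v])
            )
            assert data["steps"] == observed

    def test_spanning_steps_not_above_minimum_spanning_tree_oracle(self, rng):
        seqs = []
        base = rng.choice(list("ACGT"), size=30)
        for i in range(7):
            s = base.copy()
            for site in rng.choice(30, size=int(rng.integers(0, 5)), replace=False):
                s[site] = rng.choice([c for c in "ACGT" if c != base[site]])
            seqs.append("".join(s))
        seqs = list(dict.fromkeys(seqs))
        table = haplotype_table([(s, {"P1": 1}) for s in seqs], ["P1"])
        net = build_network(table, confidence=0.95)
        if nx.is_connected(net.graph):
            complete = nx.Graph()
            for (i, a), (j, b) in itertools.combinations(enumerate(seqs), 2):
                complete.add_edge(i, j, weight=sum(x != y for x, y in zip(a, b)))
            mst_weight = sum(
                d["weight"]
                for _, _, d in nx.minimum_spanning_tree(complete).edges(data=True)
            )
            resolution = net.minimum_spanning_resolution()
            net_weight = sum(d["steps"] for _, _, d in resolution.edges(data=True))
            assert net_weight == mst_weight

    def test_infinite_sites_simulation_gives_tree_with_steps_equal_to_s(self):
        # without homoplasy and within the connection limit, the minimum
        # spanning resolution is a tree whose total steps equal the number
        # of segregating sites
        ds = simulate_scenario(
            {
                "n_anc": 2_000,
                "split_time_years": None,
                "n_per_deme": [15],
            },
            seed=11,
        )
        haps = collapse_haplotypes(ds.alignment, ds.popmap)
        net = build_network(haps, confidence=0.95)
        resolution = net.minimum_spanning_resolution()
        if nx.is_connected(net.graph):
            total_steps = sum(d["steps"] for _, _, d in resolution.edges(data=True))
            assert total_steps == segregating_sites(ds.alignment.sequences)

    def test_network_isomorphic_under_input_reordering(self, rng):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "TAAAAAAAAA"]
        t1 = haplotype_table([(s, {"P1": 1}) for s in seqs], ["P1"])
        t2 = haplotype_table([(s, {"P1": 1}) for s in reversed(seqs)], ["P1"])
        n1 = build_network(t1, confidence=0.95)
        n2 = build_network(t2, confidence=0.95)
        e1 = {
            frozenset((t1.sequences[u], t1.sequences[v]))
            for u, v in n1.graph.edges
        }
        e2 = {
            frozenset((t2.sequences[u], t2.sequences[v]))
            for u, v in n2.graph.edges
        }
        assert e1 == e2

    def test_graphml_export_round_trips_node_and_edge_counts(self, tmp_path):
        table = haplotype_table(
            [("AAAAAAAAAA", {"P1": 4}), ("AAAAAAAAAT", {"P1": 1})], ["P1"]
        )
        net = build_network(table, confidence=0.95)
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 2
        assert back.number_of_edges() == 1

    def test_per_partition_steps_sum_to_edge_length(self, rng):
        ds = simulate_scenario("transarctic_bottleneck", seed=2)
        haps = collapse_haplotypes(ds.alignment, ds.popmap)
        net = build_network(haps, confidence=0.99)
        for _, _, data in net.graph.edges(data=True):
            assert sum(data["steps_by_partition"].values()) == data["steps"]


class TestIdentifyCores:
    def test_single_haplotype_is_the_core(self):
        table = haplotype_table([("AAAA", {"P1": 5})], ["P1"])
        net = build_network(table, confidence=0.95)
        cores, _ = identify_cores(net, 0.25)
        assert cores == {"H001"}

    def test_threshold_selects_exactly_one_core(self):
        table = haplotype_table(
            [
                ("AAAAAAAAAA", {"P1": 50}),
                ("AAAAAAAAAT", {"P1": 3}),
                ("AAAAAAAATA", {"P1": 2}),
                ("AAAAAAATAA", {"P1": 1}),
            ],
            ["P1"],
        )
        net = build_network(table, confidence=0.95)
        cores, satellites = identify_cores(net, 0.25)
        assert cores == {"H001"}
        assert set(satellites) == {"H002", "H003", "H004"}
        assert set(satellites.values()) == {"H001"}

    def test_founder_expansion_yields_one_core_with_tight_satellites(self):
        # severe-bottleneck replicates where the truth genealogy shows a
        # single founder lineage (bottleneck-deme MRCA younger than the
        # split): one dominant core, satellite cloud hugging it
        def mrca_time_of_deme(ds, deme):
            gen = ds.genealogy
            members = {i for i in range(gen.n_leaves) if gen.leaf_demes[i] == deme}
            best = None
            for node in gen.children:
                if members <= set(gen.leaves_under(node)):
                    if best is None or gen.times[node] < gen.times[best]:
                        best = node
            return gen.times[best]

        total_satellites = within_two = 0
        checked = 0
        for seed in range(40):
            ds = simulate_scenario("balsfjord_serial", seed=seed)
            if mrca_time_of_deme(ds, 1) >= ds.truth.split_time_generations:
                continue  # several founder lineages survived: not a pure star
            haps = collapse_haplotypes(ds.alignment, ds.popmap)
            bls = haps.subset_populations(["BLS"])
            net = build_network(bls, confidence=0.99)
            cores, satellites = identify_cores(net, 0.25)
            assert len(cores) == 1
            core = next(iter(cores))
            for sat in satellites:
                dist = nx.shortest_path_length(net.graph, sat, core, weight="steps")
                total_satellites += 1
                within_two += dist <= 2
            checked += 1
            if checked >= 10:
                break
        assert checked >= 5
        assert within_two / total_satellites >= 0.9

    def test_no_core_above_threshold_warns_and_returns_empty(self):
        table = haplotype_table(
            [("AAAA", {"P1": 1}), ("AAAT", {"P1": 1}), ("AATT", {"P1": 1})], ["P1"]
        )
        net = build_network(table, confidence=0.95)
        cores, satellites = identify_cores(net, 0.5)
        assert cores == set()


class TestCountGroupMutations:
    def test_shared_only_haplotype_counts_zero(self):
        table = haplotype_table([("AAAA", {"P1": 10, "P2": 5})], ["P1", "P2"])
        net = build_network(table, confidence=0.95)
        assert count_group_mutations(net, table, ["P2"]) == 0

    def test_three_exclusive_satellites_count_three(self):
        table = haplotype_table(
            [
                ("AAAAAAAAAA", {"P1": 10, "P2": 5}),
                ("AAAAAAAAAT", {"P2": 3}),
                ("AAAAAAAATA", {"P2": 2}),
                ("AAAAAAATAA", {"P2": 1}),
            ],
            ["P1", "P2"],
        )
        net = build_network(table, confidence=0.95)
        assert count_group_mutations(net, table, ["P2"]) == 3

    def test_unknown_population_is_an_error(self):
        table = haplotype_table([("AAAA", {"P1": 2})], ["P1"])
        net = build_network(table, confidence=0.95)
        with pytest.raises(ValueError, match="not in haplotype table"):
            count_group_mutations(net, table, ["NOPE"])

    def test_count_tracks_simulated_truth_within_ten_percent(self):
        # founder-expansion replicates with recorded post-split mutations
        est_total = true_total = 0
        for s in range(50):
            ds = simulate_scenario("balsfjord_serial", seed=3000 + s)
            haps = collapse_haplotypes(ds.alignment, ds.popmap)
            net = build_network(haps, confidence=0.99)
            est_total += count_group_mutations(net, haps, ["BLS"])
            true_total += sum(ds.truth.exclusive_mutations["BLS"].values())
        assert true_total > 0
        assert abs(est_total - true_total) / true_total <= 0.10

    def test_per_partition_counts_sum_to_total(self):
        ds = simulate_scenario("transarctic_bottleneck", seed=5)
        haps = collapse_haplotypes(ds.alignment, ds.popmap)
        net = build_network(haps, confidence=0.99)
        per_part = count_group_mutations(net, haps, ["EUR"], per_partition=True)
        total = count_group_mutations(net, haps, ["EUR"])
        assert sum(per_part.values()) == total
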