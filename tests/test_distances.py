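"""Observed and model-corrected distances, NJ/UPGMA trees, group distances."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average_linkage
from scipy.spatial.distance import squareform

from clupeagen.distances import (
    DistanceMatrix,
    SubstitutionModel,
    basal_distance,
    discrete_gamma_rates,
    distance_matrix,
    gtr_ig_distance,
    jc69,
    neighbor_joining,
    net_between_group_distance,
    p_distance,
    upgma,
)


def jc69_closed_form(p):
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def make_pair(p, length=1000):
    """Two sequences differing at a fraction p of sites (A->C changes)."""
    n_diff = int(round(p * length))
    a = "A" * length
    b = "C" * n_diff + "A" * (length - n_diff)
    return a, b


class TestPDistance:
    def test_identical_sequences(self):
        assert p_distance("A" * 100, "A" * 100) == 0.0

    def test_one_quarter(self):
        assert p_distance("AAAA", "AAAT") == 0.25

    def test_missing_sites_are_skipped_pairwise(self):
        assert p_distance("AAN-", "AACT") == 0.0
        assert p_distance("ACN", "AAN") == 0.5

    def test_no_comparable_sites_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("NN", "AC")


class TestGtrIgDistance:
    def test_identical_sequences_give_zero(self):
        m = jc69()
        assert gtr_ig_distance("ACGT" * 25, "ACGT" * 25, m) == 0.0

    @pytest.mark.parametrize("p", [0.02, 0.05, 0.10, 0.20])
    def test_reduces_to_jc69_closed_form_in_equal_rates_limit(self, p):
        a, b = make_pair(p, length=10_000)
        d = gtr_ig_distance(a, b, jc69())
        assert d == pytest.approx(jc69_closed_form(p), abs=1e-6)

    def test_estimates_unbiased_against_simulated_branch_lengths(self, rng):
        # forward-simulate pairs at a known branch length under the model,
        # then check the mean ML estimate against the truth
        model = SubstitutionModel(alpha=1.0, p_inv=0.0, n_categories=1)
        t_true = 0.08
        length = 2000
        P = model.transition_matrix(t_true)
        freqs = np.asarray(model.freqs)
        estimates = []
        for _ in range(200):
            anc = rng.choice(4, size=length, p=freqs)
            der = np.array([rng.choice(4, p=P[x]) for x in anc])
            seq_a = "".join("ACGT"[x] for x in anc)
            seq_b = "".join("ACGT"[x] for x in der)
            estimates.append(gtr_ig_distance(seq_a, seq_b, model))
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - t_true) < 3 * se + 1e-4

    def test_never_below_p_distance(self, rng):
        model = SubstitutionModel(alpha=0.5, p_inv=0.2)
        for _ in range(10):
            length = 500
            a = "".join(rng.choice(list("ACGT"), size=length))
            b = list(a)
            for site in rng.choice(length, size=30, replace=False):
                b[site] = rng.choice([c for c in "ACGT" if c != a[site]])
            b = "".join(b)
            assert gtr_ig_distance(a, b, model) >= p_distance(a, b) - 1e-9

    def test_gamma_category_means_average_to_one(self):
        for alpha in (0.1, 0.5, 2.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0)
            assert np.all(np.diff(rates) > 0)


class TestDistanceMatrix:
    def test_identical_haplotypes_give_zero_matrix(self):
        dm = distance_matrix([("h1", "AAAA"), ("h2", "AAAA")])
        assert np.allclose(dm.values, 0.0)

    def test_matches_elementwise_oracle(self, rng):
        haps = []
        for i in range(6):
            seq = "".join(rng.choice(list("ACGT"), size=100))
            haps.append((f"h{i}", seq))
        dm = distance_matrix(haps, method="p")
        for (la, sa), (lb, sb) in itertools.combinations(haps, 2):
            assert dm[la, lb] == pytest.approx(p_distance(sa, sb))

    def test_gtr_matrix_equals_pairwise_loop(self, rng):
        model = jc69()
        haps = []
        base = rng.choice(list("ACGT"), size=300)
        for i in range(5):
            seq = base.copy()
            for site in rng.choice(300, size=10 + 5 * i, replace=False):
                seq[site] = rng.choice([c for c in "ACGT" if c != base[site]])
            haps.append((f"h{i}", "".join(seq)))
        dm = distance_matrix(haps, method="gtr_ig", model=model)
        for (la, sa), (lb, sb) in itertools.combinations(haps, 2):
            assert dm[la, lb] == pytest.approx(gtr_ig_distance(sa, sb, model))

    def test_invariant_under_reordering(self, rng):
        haps = [
            (f"h{i}", "".join(rng.choice(list("ACGT"), size=50))) for i in range(5)
        ]
        dm1 = distance_matrix(haps)
        dm2 = distance_matrix(list(reversed(haps)))
        for a, b in itertools.combinations([h for h, _ in haps], 2):
            assert dm1[a, b] == pytest.approx(dm2[a, b])


def tree_path_distances(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                out[i, j] = out[j, i] = pdm.distance(taxa[a], taxa[b])
    return out


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree_exactly(self):
        source = "((A:1,B:2):1,(C:3,D:1):0);"
        labels = ["A", "B", "C", "D"]
        dm = DistanceMatrix(labels, tree_path_distances(source, labels))
        tree = neighbor_joining(dm)
        recovered = tree_path_distances(tree.as_string(schema="newick"), labels)
        assert np.allclose(recovered, dm.values, atol=1e-9)

    def test_three_taxa_solve_the_three_point_equations(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.0]]))
        tree = neighbor_joining(dm)
        recovered = tree_path_distances(tree.as_string(schema="newick"), ["A", "B", "C"])
        assert np.allclose(recovered, dm.values, atol=1e-9)

    def test_fewer_than_three_taxa_is_an_error(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_zero_rf_distance_on_random_additive_matrices(self, rng):
        # random topologies with random branch lengths are perfectly additive,
        # so NJ must recover them (path-distance equality implies same splits)
        for rep in range(5):
            n = 7
            taxa = [f"t{i}" for i in range(n)]
            sim = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0,
                death_rate=0.0,
                num_extant_tips=n,
                rng=__import__("random").Random(rep),
            )
            for i, leaf in enumerate(sim.leaf_node_iter()):
                leaf.taxon.label = taxa[i]
            for edge in sim.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = max(edge.length, 0.05)
            source = sim.as_string(schema="newick")
            dm = DistanceMatrix(taxa, tree_path_distances(source, taxa))
            tree = neighbor_joining(dm)
            recovered = tree_path_distances(tree.as_string(schema="newick"), taxa)
            assert np.allclose(recovered, dm.values, atol=1e-8)


class TestUpgma:
    def test_two_taxa_root_height_is_half_the_distance(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0.0]]))
        tree = upgma(dm)
        root = tree.seed_node
        lengths = [child.edge.length for child in root.child_nodes()]
        assert lengths == pytest.approx([0.05, 0.05])

    def test_matches_scipy_average_linkage_heights(self, rng):
        for _ in range(5):
            n = 6
            coords = rng.random((n, 2))
            d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
            dm = DistanceMatrix([f"t{i}" for i in range(n)], d)
            tree = upgma(dm)
            Z = scipy_average_linkage(squareform(d))
            tree.calc_node_ages(ultrametricity_precision=1e-6)
            root_age = tree.seed_node.age
            assert root_age == pytest.approx(Z[-1, 2] / 2.0, abs=1e-9)

    def test_identical_taxa_give_star_at_height_zero(self):
        dm = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        tree = upgma(dm)
        assert all(
            leaf.distance_from_root() == pytest.approx(0.0)
            for leaf in tree.leaf_node_iter()
        )

    def test_nj_and_upgma_agree_on_ultrametric_matrices(self, rng):
        # build a random ultrametric matrix via single-linkage-style heights
        for rep in range(3):
            n = 6
            Z_input = rng.random((n, n))
            d = np.maximum(Z_input, Z_input.T)
            np.fill_diagonal(d, 0)
            # force ultrametricity: cophenetic distances of an average-linkage tree
            from scipy.cluster.hierarchy import cophenet

            Z = scipy_average_linkage(squareform(d))
            d_ultra = squareform(cophenet(Z))
            labels = [f"t{i}" for i in range(n)]
            dm = DistanceMatrix(labels, d_ultra)
            nj_tree = neighbor_joining(dm)
            up_tree = upgma(dm)
            nj_splits = unrooted_splits(nj_tree, labels)
            up_splits = unrooted_splits(up_tree, labels)
            assert nj_splits == up_splits


def unrooted_splits(tree, labels):
    taxa = set(labels)
    splits = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is None or head.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in head.leaf_iter())
        if 1 < len(side) < len(taxa) - 1:
            splits.add(min(side, frozenset(taxa - side), key=sorted))
    return splits


class TestGroupDistances:
    def test_constant_between_distances(self):
        d = np.array(
            [[0, 0, 0.1, 0.1], [0, 0, 0.1, 0.1], [0.1, 0.1, 0, 0], [0.1, 0.1, 0, 0.0]]
        )
        dm = DistanceMatrix(["a1", "a2", "b1", "b2"], d)
        assert basal_distance(dm, ["a1", "a2"], ["b1", "b2"]) == pytest.approx(0.1)

    def test_two_by_two_block_mean(self):
        d = np.zeros((4, 4))
        d[0, 2], d[0, 3], d[1, 2], d[1, 3] = 0.1, 0.2, 0.3, 0.4
        d = d + d.T
        dm = DistanceMatrix(["a1", "a2", "b1", "b2"], d)
        assert basal_distance(dm, ["a1", "a2"], ["b1", "b2"]) == pytest.approx(0.25)

    def test_overlapping_groups_rejected(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError, match="overlap"):
            basal_distance(dm, ["a", "b"], ["b", "c"])

    def test_net_distance_zero_for_identical_groups(self):
        d = np.full((4, 4), 0.2)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(["a1", "a2", "b1", "b2"], d)
        assert net_between_group_distance(dm, ["a1", "a2"], ["b1", "b2"]) == pytest.approx(0.0)

    def test_net_distance_formula(self):
        # between-mean 0.5, within-means 0.2 and 0.4 -> 0.5 - 0.3 = 0.2
        d = np.zeros((4, 4))
        d[0, 1] = 0.2  # within group a
        d[2, 3] = 0.4  # within group b
        d[0, 2] = d[0, 3] = d[1, 2] = d[1, 3] = 0.5
        d = d + d.T
        dm = DistanceMatrix(["a1", "a2", "b1", "b2"], d)
        assert net_between_group_distance(dm, ["a1", "a2"], ["b1", "b2"]) == pytest.approx(0.2)

    def test_net_distance_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            n = 7
            m = rng.random((n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            labels = [f"x{i}" for i in range(n)]
            dm = DistanceMatrix(labels, d)
            ga, gb = labels[:3], labels[3:]
            between = np.mean([d[i, j] for i in range(3) for j in range(3, n)])
            wa = np.mean([d[i, j] for i in range(3) for j in range(3) if i < j])
            wb = np.mean([d[i, j] for i in range(3, n) for j in range(3, n) if i < j])
            expected = between - 0.5 * (wa + wb)
            assert net_between_group_distance(dm, ga, gb) == pytest.approx(expected)
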