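"""Statistical-parsimony haplotype networks.

Builds TCS-style haplotype networks: haplotypes are joined in order of
increasing pairwise difference, up to a connection limit chosen so that
connections are non-homoplasious ("parsimonious") with a stated confidence
(95% or 99%). Edges are annotated with total mutational steps and with
per-partition step counts (e.g. coding-gene vs control-region changes).
Core (high-frequency) haplotypes and their satellite clouds are identified,
and the mutations inferred to have arisen within a population group since
its founding are counted from the network.

Parsimony probability. For two sequences of length m differing at j sites,
the probability that every observed difference arose by exactly one
substitution is evaluated under a neutral coalescent: the pair's
coalescence time is exponential (coalescent units), mutations at a site are
Poisson along the two lineages, and a 4-state symmetric (Jukes-Cantor)
site model gives the probability that k hits at a site leave an observable
difference. Writing theta for the per-site scaled mutation rate (Watterson
estimate from the sample), the parsimony probability is the ratio of two
one-dimensional integrals over the coalescence time; the connection limit
is the largest j whose parsimony probability still reaches the confidence
level (single-step connections are always admitted).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .seq_io import MISSING, HaplotypeTable, Partition

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parsimony probability / connection limit
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.laguerre.laggauss(96)


def watterson_theta(n_segregating: int, n_samples: int) -> float:
    """Watterson's estimator theta_W = S / a_{n-1} (per gene)."""
    if n_samples < 2:
        raise ValueError("Watterson's estimator needs n >= 2")
    a = sum(1.0 / i for i in range(1, n_samples))
    return n_segregating / a


def parsimony_probability(j: int, L: int, theta_site: float) -> float:
    """P(all j observed differences are single hits | j differences, L sites).

    Evaluated with Gauss-Laguerre quadrature over the exponential
    coalescence-time density. ``theta_site`` is the per-site scaled
    mutation rate (2*N*mu for haploid mtDNA).
    """
    if j == 0:
        return 1.0
    if L <= 0:
        raise ValueError("sequence length must be positive")
    th = max(theta_site, 1e-12)
    t = _GL_NODES

    # per-site terms given coalescence time t (JC site model, Poisson hits)
    u_same = 0.25 + 0.75 * np.exp(-4.0 * th * t / 3.0)  # identical site
    u_diff = 0.75 * (1.0 - np.exp(-4.0 * th * t / 3.0))  # differing site
    u_one = th * t * np.exp(-th * t)  # exactly one hit

    log_same = np.log(u_same)
    with np.errstate(divide="ignore"):
        log_diff = np.log(np.maximum(u_diff, 1e-300))
        log_one = np.log(np.maximum(u_one, 1e-300))
    rest = (L - j) * log_same
    log_num = np.log(_GL_WEIGHTS) + j * log_one + rest
    log_den = np.log(_GL_WEIGHTS) + j * log_diff + rest

    def logsumexp(v: np.ndarray) -> float:
        m = v.max()
        return m + math.log(np.exp(v - m).sum())

    return float(math.exp(logsumexp(log_num) - logsumexp(log_den)))


def parsimony_connection_limit(
    L: int, confidence: float = 0.95, theta_site: float = 0.01, max_steps: int = 200
) -> int:
    """Largest step count j with parsimony probability >= confidence.

    Single-step connections are always admissible (one observed difference
    between two sequences cannot be homoplasious within the pair), so the
    limit is at least 1.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    limit = 1
    for j in range(2, max_steps + 1):
        if parsimony_probability(j, L, theta_site) >= confidence:
            limit = j
        else:
            break
    return limit


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def _partitioned_differences(
    a: str, b: str, partitions: Sequence[Partition]
) -> tuple[int, dict[str, int]]:
    """Total and per-partition difference counts (missing skipped pairwise)."""
    per_part: dict[str, int] = {p.name: 0 for p in partitions}
    total = 0
    for p in partitions:
        for x, y in zip(a[p.start : p.end], b[p.start : p.end]):
            if x in MISSING or y in MISSING:
                continue
            if x != y:
                per_part[p.name] += 1
                total += 1
    return total, per_part


@dataclass
class HaplotypeNetwork:
    """Statistical-parsimony network over sampled haplotypes.

    ``graph`` is a networkx Graph whose nodes are haplotype ids (node
    attributes: ``frequency``, per-population ``counts``) and whose edges
    carry ``steps`` (total mutational steps) and ``steps_by_partition``.
    Alternative equal-length connections are retained, so the graph may
    contain loops; ``n_loop_edges`` records how many edges close loops.
    Components beyond the connection limit stay disconnected.
    """

    graph: nx.Graph
    connection_limit: int
    confidence: float
    theta_site: float
    partitions: list[Partition] = field(default_factory=list)
    n_loop_edges: int = 0

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def subnetworks(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def minimum_spanning_resolution(self) -> nx.Graph:
        """Minimum-step spanning forest used for mutation counting.

        When loops (alternative connections) exist, the minimum spanning
        tree of each component gives the minimum-step resolution.
        """
        return nx.minimum_spanning_tree(self.graph, weight="steps")

    def expanded_graph(self) -> nx.Graph:
        """Graph with unsampled intermediate nodes on multi-step edges."""
        g = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, inferred=False, **data)
        med = 0
        for u, v, data in self.graph.edges(data=True):
            steps = data["steps"]
            if steps == 1:
                g.add_edge(u, v, steps=1)
                continue
            prev = u
            for _ in range(steps - 1):
                med += 1
                mid = f"median{med}"
                g.add_node(mid, inferred=True, frequency=0)
                g.add_edge(prev, mid, steps=1)
                prev = mid
            g.add_edge(prev, v, steps=1)
        return g

    def to_graphml(self, path) -> None:
        """GraphML export with per-partition step counts flattened to attributes."""
        g = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, frequency=data.get("frequency", 0))
        for u, v, data in self.graph.edges(data=True):
            attrs = {"steps": data["steps"]}
            for name, cnt in data["steps_by_partition"].items():
                attrs[f"steps_{name}"] = cnt
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)

    def edge_table(self) -> list[dict]:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            row = {"hap_a": u, "hap_b": v, "steps": data["steps"]}
            for name, cnt in data["steps_by_partition"].items():
                row[f"steps_{name}"] = cnt
            rows.append(row)
        return rows


def build_network(
    haps: HaplotypeTable,
    confidence: float = 0.99,
    theta_site: float | None = None,
) -> HaplotypeNetwork:
    """TCS-style agglomerative network construction.

    Haplotype pairs are processed in order of increasing difference count;
    at each difference level every pair that joined two previously separate
    components is connected (so alternative equal-length connections are
    all retained, possibly closing loops). Connections longer than the
    parsimony limit are omitted, which can leave separate sub-networks.

    ``theta_site`` defaults to the Watterson estimate from the expanded
    sample divided by the sequence length.
    """
    ids = haps.haplotype_ids
    if not ids:
        raise ValueError("empty haplotype table")
    partitions = haps.partitions or [
        Partition("all", 0, len(next(iter(haps.sequences.values()))))
    ]
    L = partitions[-1].end

    if theta_site is None:
        from .popgen_stats import segregating_sites

        seqs = haps.expand()
        theta_site = (
            watterson_theta(segregating_sites(seqs), len(seqs)) / L
            if len(seqs) >= 2
            else 0.01
        )

    limit = parsimony_connection_limit(L, confidence, theta_site)

    graph = nx.Graph()
    freq = {h: haps.frequency(h) for h in ids}
    for h in ids:
        graph.add_node(h, frequency=freq[h], counts=haps.counts.loc[h].to_dict())

    # pairwise differences, sorted by (steps, frequency criterion, index)
    order = {h: i for i, h in enumerate(ids)}
    pairs = []
    for a, b in itertools.combinations(ids, 2):
        steps, per_part = _partitioned_differences(
            haps.sequences[a], haps.sequences[b], partitions
        )
        pairs.append((steps, -(freq[a] + freq[b]), order[a], order[b], a, b, per_part))
    pairs.sort()

    n_loops = 0
    for steps, group_pairs in itertools.groupby(pairs, key=lambda p: p[0]):
        if steps == 0 or steps > limit:
            continue
        components_at_level = {
            h: ci for ci, comp in enumerate(nx.connected_components(graph)) for h in comp
        }
        merged: set[frozenset[int]] = set()
        for _, _, _, _, a, b, per_part in group_pairs:
            ca, cb = components_at_level[a], components_at_level[b]
            if ca == cb:
                continue
            key = frozenset((ca, cb))
            if key in merged:
                n_loops += 1  # alternative equal-length connection: keep, log
            merged.add(key)
            graph.add_edge(a, b, steps=steps, steps_by_partition=per_part)

    if n_loops:
        logger.info("network contains %d loop-closing alternative edges", n_loops)
    return HaplotypeNetwork(
        graph=graph,
        connection_limit=limit,
        confidence=confidence,
        theta_site=theta_site,
        partitions=list(partitions),
        n_loop_edges=n_loops,
    )


# ---------------------------------------------------------------------------
# cores, satellites, group-exclusive mutation counting
# ---------------------------------------------------------------------------


def identify_cores(
    network: HaplotypeNetwork, min_freq_fraction: float = 0.05
) -> tuple[set[str], dict[str, str]]:
    """Flag core haplotypes and assign satellites to their nearest core.

    Cores are haplotypes whose total frequency is at least
    ``min_freq_fraction`` of the sample size. Satellites are assigned to
    the graph-nearest core (steps as edge weight); ties go to the more
    frequent core. Satellites in components without a core are left
    unassigned.
    """
    if not 0 < min_freq_fraction < 1:
        raise ValueError("min_freq_fraction must lie in (0, 1)")
    freq = nx.get_node_attributes(network.graph, "frequency")
    total = sum(freq.values())
    cores = {h for h, f in freq.items() if f >= min_freq_fraction * total}
    if not cores:
        logger.warning("no haplotype reaches the core frequency threshold")
        return set(), {}
    assignment: dict[str, str] = {}
    for h in network.graph.nodes:
        if h in cores:
            continue
        best: tuple[float, int, str] | None = None
        for core in cores:
            try:
                dist = nx.shortest_path_length(
                    network.graph, h, core, weight="steps"
                )
            except nx.NetworkXNoPath:
                continue
            cand = (dist, -freq[core], core)
            if best is None or cand < best:
                best = cand
        if best is not None:
            assignment[h] = best[2]
    return cores, assignment


def count_group_mutations(
    network: HaplotypeNetwork,
    haps: HaplotypeTable,
    group: Iterable[str],
    per_partition: bool = False,
    core_fraction: float = 0.25,
):
    """Mutational steps leading to haplotypes exclusive to a population group.

    A haplotype is group-exclusive when all its observations come from the
    group's populations. On the minimum-step spanning resolution of each
    sub-network, an edge is counted when the side of the tree it leads to
    contains only group-exclusive haplotypes: those are the mutations
    inferred to have arisen within the group since founding. Each edge is
    counted once.

    One refinement mirrors the core/satellite reading of founder
    expansions: when an exclusive subtree contains a dominant haplotype
    (frequency >= ``core_fraction`` of the group sample), that haplotype is
    taken to be the founding state itself, so the stem path connecting it
    to the shared part of the network records pre-founding lineage history
    and is excluded from the count. Satellites hanging off the core (or
    off a shared core) are counted as usual. In a fully exclusive
    sub-network the count is taken over all edges away from its core.

    Returns the total step count, or a dict of per-partition counts when
    ``per_partition`` is set.
    """
    group_pops = list(group)
    unknown = [p for p in group_pops if p not in haps.populations]
    if unknown:
        raise ValueError(f"populations not in haplotype table: {unknown}")
    in_group = haps.counts[group_pops].sum(axis=1)
    total_counts = haps.counts.sum(axis=1)
    exclusive = {
        h
        for h in haps.haplotype_ids
        if in_group[h] > 0 and in_group[h] == total_counts[h]
    }
    group_n = int(in_group.sum())
    freq = nx.get_node_attributes(network.graph, "frequency")

    forest = network.minimum_spanning_resolution()
    totals: dict[str, int] = {p.name: 0 for p in network.partitions}
    grand_total = 0

    def add_edge(u: str, v: str) -> None:
        nonlocal grand_total
        data = forest.edges[u, v]
        grand_total += data["steps"]
        for name, cnt in data["steps_by_partition"].items():
            totals[name] += cnt

    for component in nx.connected_components(forest):
        tree = forest.subgraph(component)
        shared = [h for h in component if h not in exclusive]
        if not shared:
            # entirely group-exclusive sub-network: count all edges; no stem
            for u, v, _ in tree.edges(data=True):
                add_edge(u, v)
            continue
        # root at the most frequent shared haplotype
        root = max(shared, key=lambda h: (freq[h], h))
        parent = {root: None}
        order = [root]
        for u, v in nx.bfs_edges(tree, root):
            parent[v] = u
            order.append(v)
        # post-order: is the subtree below each node entirely exclusive?
        subtree_all_exclusive = {h: h in exclusive for h in component}
        for node in reversed(order):
            for child in tree.neighbors(node):
                if parent.get(child) == node and not subtree_all_exclusive[child]:
                    subtree_all_exclusive[node] = False
        # maximal exclusive subtrees hang below nodes whose parent subtree
        # is not all-exclusive
        for top in order:
            par = parent[top]
            if par is None or not subtree_all_exclusive[top] or subtree_all_exclusive[par]:
                continue  # not the root of a maximal exclusive subtree
            members = [
                n for n in order if _is_descendant_or_self(n, top, parent)
            ]
            core = max(members, key=lambda h: (freq[h], h))
            excluded_path: set[tuple[str, str]] = set()
            # a founding core is a dominant haplotype with its own satellite
            # cloud; a lone exclusive haplotype is a satellite, not a core
            if len(members) >= 2 and freq[core] >= core_fraction * group_n:
                # stem path parent -> top -> ... -> core is pre-founding
                node = core
                while node != top:
                    excluded_path.add(_edge_key(parent[node], node))
                    node = parent[node]
                excluded_path.add(_edge_key(par, top))
            # count the stem unless excluded (low-frequency satellite clouds
            # keep their stem: those steps arose in-group)
            if _edge_key(par, top) not in excluded_path:
                add_edge(par, top)
            for n in members:
                if n == top:
                    continue
                if _edge_key(parent[n], n) not in excluded_path:
                    add_edge(parent[n], n)
    return totals if per_partition else grand_total


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _is_descendant_or_self(node: str, ancestor: str, parent: dict[str, str | None]) -> bool:
    while node is not None:
        if node == ancestor:
            return True
        node = parent[node]
    return False
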