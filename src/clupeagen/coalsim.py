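"""Coalescent simulator for the split–bottleneck–expansion demography.

Generates ground-truthed synthetic datasets for the full analysis chain:
an ancestral population splits at a known time into two descendant demes of
unequal founding fractions, each descendant grows exponentially from its
founder size toward a carrying size, lineages may migrate asymmetrically,
and mutations fall on two partitions (a coding gene and a faster-evolving
control region) at unequal rates.

The simulation runs backward in time as a structured coalescent for a
single non-recombining haploid locus (mtDNA, maternally inherited, so all
sizes are effective female numbers). Within each deme the pairwise
coalescence rate is 1/N_d(tau) where N_d is the deterministic size
trajectory; waiting times are drawn exactly by piecewise-analytic inversion
of the integrated hazard (no time discretisation). At the split time the
descendant demes merge into the constant-size ancestor.

Size trajectory: looking backward from the present, a descendant deme has
size N_d(tau) = min(carrying_size, founder_size * exp(g * (T - tau))) for
tau < T — i.e. forward in time the deme grows exponentially at rate g from
its founder size until it reaches the carrying size, then stays constant.

The truth record keeps the genealogy (Newick, branch lengths in
generations), the true split time, per-branch mutation counts per
partition, and the per-deme counts of post-split "exclusive" mutations —
mutations younger than the split on branches subtending samples of a
single deme, i.e. exactly the quantity the direct-count dating estimator
tries to recover from a haplotype network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .dating import RateCalibration, cytb_calibration, cr_calibration
from .seq_io import Partition, PartitionedAlignment, PopulationMap

COALESCENCE_CAP = 1e9  # generations; safeguard against non-coalescence

BASES = "ACGT"


# ---------------------------------------------------------------------------
# demographic model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicModel:
    """Two-deme isolation-with-migration demography (or single panmictic deme).

    Parameters
    ----------
    n_anc:
        Ancestral effective (female) population size, haploid lineage count.
    split_time:
        Generations before present at which the descendants merge into the
        ancestor (backward); ``None`` for a single panmictic deme.
    founder_fractions:
        Founding size of each descendant deme as a fraction of ``n_anc``.
    growth_rates:
        Post-split exponential growth rate per generation in each deme.
    carrying_sizes:
        Present-day size ceiling per deme; defaults to ``n_anc``.
    migration:
        ``(m12, m21)`` backward per-lineage per-generation migration rates
        (a lineage sampled in deme 1 traces its ancestry into deme 2 at
        rate ``m12``).
    """

    n_anc: float
    split_time: float | None = None
    founder_fractions: tuple[float, float] = (0.99, 0.01)
    growth_rates: tuple[float, float] = (0.05, 0.05)
    carrying_sizes: tuple[float, float] | None = None
    migration: tuple[float, float] = (0.0, 0.0)
    generation_years: float = 4.0
    deme_names: tuple[str, ...] = ("D1", "D2")

    def __post_init__(self) -> None:
        if self.n_anc < 1:
            raise ValueError("ancestral size must be >= 1")
        if self.split_time is not None:
            if self.split_time <= 0:
                raise ValueError("split time must be positive")
            for s in self.founder_fractions:
                if not 0 < s <= 1:
                    raise ValueError("founder fractions must lie in (0, 1]")
            if any(f * self.n_anc < 1 for f in self.founder_fractions):
                raise ValueError("founder size below one individual")

    @classmethod
    def panmictic(cls, n: float, generation_years: float = 4.0) -> "DemographicModel":
        return cls(
            n_anc=n,
            split_time=None,
            generation_years=generation_years,
            deme_names=("D1",),
        )

    @property
    def n_demes(self) -> int:
        return 1 if self.split_time is None else 2

    def founder_size(self, deme: int) -> float:
        return self.founder_fractions[deme] * self.n_anc

    def carrying_size(self, deme: int) -> float:
        if self.carrying_sizes is not None:
            return self.carrying_sizes[deme]
        return self.n_anc

    def size_at(self, deme: int, tau: float) -> float:
        """Deme size at backward time tau (generations before present)."""
        if self.split_time is None:
            return self.n_anc
        if tau >= self.split_time:
            return self.n_anc
        g = self.growth_rates[deme]
        f = self.founder_size(deme)
        if g <= 0:
            return f
        return min(self.carrying_size(deme), f * math.exp(g * (self.split_time - tau)))

    @property
    def split_time_years(self) -> float | None:
        if self.split_time is None:
            return None
        return self.split_time * self.generation_years


# ---------------------------------------------------------------------------
# genealogy container
# ---------------------------------------------------------------------------


@dataclass
class Genealogy:
    """Binary coalescent tree: leaves 0..n-1, internal nodes above.

    ``times`` are node ages in generations (0 for leaves); ``children``
    maps internal node ids to their two children; ``leaf_demes`` records
    the sampling deme index per leaf.
    """

    n_leaves: int
    times: list[float]
    children: dict[int, tuple[int, int]]
    leaf_ids: list[str]
    leaf_demes: list[int]
    coalescence_demes: dict[int, int] = field(default_factory=dict)

    @property
    def root(self) -> int:
        return len(self.times) - 1

    @property
    def tmrca(self) -> float:
        return self.times[self.root]

    def parent_map(self) -> dict[int, int]:
        return {c: p for p, (a, b) in self.children.items() for c in (a, b)}

    def branches(self) -> list[tuple[int, int, float, float, float]]:
        """(node, parent, length, t_lower, t_upper) for every non-root node."""
        parents = self.parent_map()
        out = []
        for node, parent in parents.items():
            t0, t1 = self.times[node], self.times[parent]
            out.append((node, parent, t1 - t0, t0, t1))
        return out

    def leaves_under(self, node: int) -> list[int]:
        stack, leaves = [node], []
        while stack:
            cur = stack.pop()
            if cur < self.n_leaves:
                leaves.append(cur)
            else:
                stack.extend(self.children[cur])
        return sorted(leaves)

    def total_branch_length(self) -> float:
        return sum(br[2] for br in self.branches())

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if node < self.n_leaves:
                return self.leaf_ids[node]
            a, b = self.children[node]
            la = self.times[node] - self.times[a]
            lb = self.times[node] - self.times[b]
            return f"({render(a)}:{la:.6f},{render(b)}:{lb:.6f})"

        return render(self.root) + ";"


# ---------------------------------------------------------------------------
# backward simulation
# ---------------------------------------------------------------------------


def _next_coalescence(
    model: DemographicModel, deme: int, k: int, tau0: float, tau_end: float, e: float
) -> float | None:
    """Invert the integrated pairwise-coalescence hazard within [tau0, tau_end).

    ``e`` is an Exp(1) draw; returns the event time, or None if the hazard
    accumulated before ``tau_end`` is insufficient.
    """
    if k < 2:
        return None
    c = k * (k - 1) / 2.0
    if model.split_time is None or tau0 >= (model.split_time or 0):
        # constant ancestral size
        n = model.n_anc
        t = tau0 + e * n / c
        return t if t < tau_end else None

    # descendant deme: constant carrying phase then exponential shrink phase
    T = model.split_time
    g = model.growth_rates[deme]
    f = model.founder_size(deme)
    cap = model.carrying_size(deme)
    if g <= 0 or f >= cap:
        tau_star = 0.0  # no constant phase distinct from exponential, size==f or cap
    else:
        tau_star = T - math.log(cap / f) / g
    tau = tau0
    remaining = e
    # phase 1: constant size (cap) while tau < tau_star
    if tau < tau_star:
        n = cap
        span = min(tau_star, tau_end) - tau
        lam = c / n
        if remaining < lam * span:
            return tau + remaining / lam
        remaining -= lam * span
        tau = min(tau_star, tau_end)
        if tau >= tau_end:
            return None
    # phase 2: exponential shrink toward founder size as tau -> T
    if g <= 0:
        n = f if f < cap else cap
        span = tau_end - tau
        lam = c / n
        if remaining < lam * span:
            return tau + remaining / lam
        return None
    # N(tau) = f * exp(g (T - tau)); hazard integral has closed form
    b = min(tau_end, T)
    if tau >= b:
        return None
    # Lambda(tau, x) = (c / (f g)) * (exp(g(x-T)) - exp(g(tau-T)))
    base = math.exp(g * (tau - T))
    lam_total = (c / (f * g)) * (math.exp(g * (b - T)) - base)
    if remaining >= lam_total:
        return None
    x = T + math.log(base + remaining * f * g / c) / g
    return x


def simulate_genealogy(
    model: DemographicModel, n_per_deme: Sequence[int], seed: int | None = None
) -> Genealogy:
    """Simulate one structured-coalescent genealogy over all samples.

    ``n_per_deme`` gives the sample size per deme (one entry for a
    panmictic model). Times are in generations; the result is reproducible
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_demes = model.n_demes
    if len(n_per_deme) != n_demes:
        raise ValueError(f"expected {n_demes} sample sizes, got {len(n_per_deme)}")
    if any(n < 1 for n in n_per_deme):
        raise ValueError("need at least one sample per deme")

    leaf_ids = []
    leaf_demes = []
    for d in range(n_demes):
        for i in range(n_per_deme[d]):
            leaf_ids.append(f"{model.deme_names[d]}_{i + 1:03d}")
            leaf_demes.append(d)
    n = len(leaf_ids)

    times = [0.0] * n
    children: dict[int, tuple[int, int]] = {}
    coalescence_demes: dict[int, int] = {}
    lineages: list[tuple[int, int]] = [(i, leaf_demes[i]) for i in range(n)]
    tau = 0.0
    next_id = n
    merged = model.split_time is None

    while len(lineages) > 1:
        if tau > COALESCENCE_CAP:
            raise RuntimeError(f"no full coalescence within {COALESCENCE_CAP:.0e} generations")
        epoch_end = math.inf if merged else model.split_time
        demes_present = sorted({d for _, d in lineages})
        candidates: list[tuple[float, str, int]] = []
        for d in demes_present:
            k = sum(1 for _, dd in lineages if dd == d)
            t = _next_coalescence(model, 0 if merged else d, k, tau, epoch_end, rng.exponential())
            if t is not None:
                candidates.append((t, "coal", d))
        if not merged:
            for d, rate in ((0, model.migration[0]), (1, model.migration[1])):
                k = sum(1 for _, dd in lineages if dd == d)
                if k > 0 and rate > 0:
                    t = tau + rng.exponential() / (k * rate)
                    if t < epoch_end:
                        candidates.append((t, "mig", d))

        if not candidates:
            if merged:
                raise RuntimeError("no feasible events in merged phase")  # pragma: no cover
            tau = model.split_time
            merged = True
            lineages = [(lid, 0) for lid, _ in lineages]
            continue

        t_event, kind, d = min(candidates)
        tau = t_event
        members = [i for i, (_, dd) in enumerate(lineages) if dd == d]
        if kind == "coal":
            ia, ib = rng.choice(len(members), size=2, replace=False)
            a, b = lineages[members[ia]][0], lineages[members[ib]][0]
            times.append(tau)
            children[next_id] = (a, b)
            coalescence_demes[next_id] = d if not merged else -1
            lineages = [
                lin for idx, lin in enumerate(lineages) if idx not in (members[ia], members[ib])
            ]
            lineages.append((next_id, d))
            next_id += 1
        else:
            mover = members[int(rng.integers(len(members)))]
            lid, _ = lineages[mover]
            lineages[mover] = (lid, 1 - d)

    return Genealogy(
        n_leaves=n,
        times=times,
        children=children,
        leaf_ids=leaf_ids,
        leaf_demes=leaf_demes,
        coalescence_demes=coalescence_demes,
    )


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationPartition:
    """Per-partition mutation process: length and per-site per-generation rate."""

    name: str
    length: int
    rate_per_site_per_generation: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("partition length must be positive")
        if self.rate_per_site_per_generation < 0:
            raise ValueError("rate must be >= 0")


def default_partitions(
    cytb: RateCalibration | None = None, cr: RateCalibration | None = None
) -> list[MutationPartition]:
    """Two-partition default: coding gene plus 3.6x-faster control region."""
    cytb = cytb or cytb_calibration()
    cr = cr or cr_calibration()
    return [
        MutationPartition("cytb", cytb.gene_length, cytb.mu_site_per_generation),
        MutationPartition("cr", cr.gene_length, cr.mu_site_per_generation),
    ]


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated dataset."""

    newick: str
    split_time_generations: float | None
    split_time_years: float | None
    per_branch_mutations: dict[int, dict[str, int]]
    exclusive_mutations: dict[str, dict[str, int]]
    total_mutations: dict[str, int]
    segregating_sites: dict[str, int]
    seed: int | None
    model: dict

    def to_json(self, path=None) -> str:
        payload = {
            "newick": self.newick,
            "split_time_generations": self.split_time_generations,
            "split_time_years": self.split_time_years,
            "per_branch_mutations": {
                str(k): v for k, v in self.per_branch_mutations.items()
            },
            "exclusive_mutations": self.exclusive_mutations,
            "total_mutations": self.total_mutations,
            "segregating_sites": self.segregating_sites,
            "seed": self.seed,
            "model": self.model,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class SimulatedDataset:
    alignment: PartitionedAlignment
    popmap: PopulationMap
    truth: TruthRecord
    genealogy: Genealogy


def drop_mutations(
    genealogy: Genealogy,
    partitions: Sequence[MutationPartition],
    seed: int | None = None,
    infinite_sites: bool = True,
    subst_model=None,
    model: DemographicModel | None = None,
    deme_names: Sequence[str] | None = None,
) -> SimulatedDataset:
    """Drop Poisson mutations on the genealogy and build the alignment.

    In infinite-sites mode every mutation hits a fresh site (exact truth
    accounting: segregating sites == mutations placed); in finite-sites
    mode sites are drawn uniformly per partition and bases evolve by the
    jump chain of the supplied substitution model (Jukes-Cantor when none
    is given), so homoplasy can occur.
    """
    rng = np.random.default_rng(seed)
    split_time = model.split_time if model is not None else None
    names = list(
        deme_names
        if deme_names is not None
        else (model.deme_names if model is not None else [])
    )
    parents = genealogy.parent_map()

    # mutation placement: (branch node, partition, time, site)
    per_branch: dict[int, dict[str, int]] = {}
    mutations: list[tuple[int, str, float, int]] = []
    for part in partitions:
        taken_sites: set[int] = set()
        for node, parent, length, t0, t1 in genealogy.branches():
            lam = part.rate_per_site_per_generation * part.length * length
            count = int(rng.poisson(lam)) if lam > 0 else 0
            if count == 0:
                continue
            per_branch.setdefault(node, {})[part.name] = (
                per_branch.get(node, {}).get(part.name, 0) + count
            )
            times_m = rng.uniform(t0, t1, size=count)
            for t_m in times_m:
                if infinite_sites:
                    if len(taken_sites) >= part.length:
                        raise RuntimeError(
                            f"infinite-sites overflow: more mutations than sites in "
                            f"partition '{part.name}'"
                        )
                    while True:
                        site = int(rng.integers(part.length))
                        if site not in taken_sites:
                            break
                    taken_sites.add(site)
                else:
                    site = int(rng.integers(part.length))
                mutations.append((node, part.name, float(t_m), site))

    # sequences: root draw, then apply branch mutations root-to-tip
    freqs = (
        np.asarray(subst_model.freqs) if subst_model is not None else np.full(4, 0.25)
    )
    part_offsets = {}
    pos = 0
    for part in partitions:
        part_offsets[part.name] = pos
        pos += part.length
    total_len = pos

    root_seq = rng.choice(4, size=total_len, p=freqs)
    muts_by_branch: dict[int, list[tuple[float, str, int]]] = {}
    for node, pname, t_m, site in mutations:
        muts_by_branch.setdefault(node, []).append((t_m, pname, site))

    def mutate_base(current: int) -> int:
        if subst_model is None:
            choices = [b for b in range(4) if b != current]
            return int(rng.choice(choices))
        q_row = _jump_probs(subst_model, current)
        return int(rng.choice(4, p=q_row))

    seqs: dict[int, np.ndarray] = {genealogy.root: root_seq}
    order = [genealogy.root]
    stack = [genealogy.root]
    while stack:
        cur = stack.pop()
        if cur >= genealogy.n_leaves:
            for child in genealogy.children[cur]:
                order.append(child)
                stack.append(child)
    for node in order:
        if node == genealogy.root:
            continue
        seq = seqs[parents[node]].copy()
        # apply this branch's mutations oldest-first (descending time)
        for t_m, pname, site in sorted(muts_by_branch.get(node, []), reverse=True):
            idx = part_offsets[pname] + site
            seq[idx] = mutate_base(int(seq[idx]))
        seqs[node] = seq

    sequences = [
        "".join(BASES[b] for b in seqs[i]) for i in range(genealogy.n_leaves)
    ]
    aln_partitions = [
        Partition(p.name, part_offsets[p.name], part_offsets[p.name] + p.length)
        for p in partitions
    ]
    alignment = PartitionedAlignment(
        sample_ids=list(genealogy.leaf_ids),
        sequences=sequences,
        partitions=aln_partitions,
    )

    if not names:
        names = [f"D{d + 1}" for d in range(max(genealogy.leaf_demes) + 1)]
    popmap = PopulationMap(
        {
            sid: (names[d], names[d])
            for sid, d in zip(genealogy.leaf_ids, genealogy.leaf_demes)
        }
    )

    # truth: per-deme post-split exclusive mutations
    exclusive: dict[str, dict[str, int]] = {
        nm: {p.name: 0 for p in partitions} for nm in names
    }
    if split_time is not None:
        deme_of_leaf = genealogy.leaf_demes
        branch_deme: dict[int, int | None] = {}
        for node in parents:
            leaf_demes_under = {deme_of_leaf[l] for l in genealogy.leaves_under(node)}
            branch_deme[node] = (
                leaf_demes_under.pop() if len(leaf_demes_under) == 1 else None
            )
        for node, pname, t_m, _ in mutations:
            d = branch_deme.get(node)
            if d is not None and t_m < split_time:
                exclusive[names[d]][pname] += 1

    total_mut = {p.name: 0 for p in partitions}
    for node, pname, _, _ in mutations:
        total_mut[pname] += 1

    from .popgen_stats import segregating_sites as count_S

    seg = {}
    for part in aln_partitions:
        seg[part.name] = count_S([s[part.start : part.end] for s in sequences])

    truth = TruthRecord(
        newick=genealogy.to_newick(),
        split_time_generations=split_time,
        split_time_years=(
            split_time * model.generation_years if split_time is not None else None
        ),
        per_branch_mutations=per_branch,
        exclusive_mutations=exclusive,
        total_mutations=total_mut,
        segregating_sites=seg,
        seed=seed,
        model=asdict(model) if model is not None else {},
    )
    return SimulatedDataset(alignment=alignment, popmap=popmap, truth=truth, genealogy=genealogy)


def _jump_probs(subst_model, current: int) -> np.ndarray:
    """Normalised off-diagonal GTR jump probabilities from a base."""
    vals, vecs, sqrt_f = subst_model._eig
    Q = (vecs @ np.diag(vals) @ vecs.T / sqrt_f[:, None]) * sqrt_f[None, :]
    row = np.clip(Q[current], 0.0, None)
    row[current] = 0.0
    return row / row.sum()


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

SCENARIO_PRESETS: dict[str, dict] = {
    # single panmictic pool, e.g. for null Phi_ST checks
    "panmictic": {
        "n_anc": 50_000,
        "split_time_years": None,
        "n_per_deme": [40],
    },
    # symmetric two-deme split with gene flow
    "two_deme_island": {
        "n_anc": 50_000,
        "split_time_years": 200_000,
        "founder_fractions": (0.5, 0.5),
        "growth_rates": (0.0, 0.0),
        "carrying_sizes": (25_000, 25_000),
        "migration": (1e-4, 1e-4),
        "n_per_deme": [25, 25],
        "deme_names": ("D1", "D2"),
    },
    # Pacific-like ancestral deme plus one bottlenecked, star-expanding
    # European-like descendant (founders ~1% of the ancestral size; slow
    # recovery keeps the founder effect visible in haplotype diversity,
    # the large carrying size keeps the post-split genealogy star-like)
    "transarctic_bottleneck": {
        "n_anc": 150_000,
        "split_time_years": 10_000,
        "founder_fractions": (0.99, 0.01),
        "growth_rates": (0.05, 0.005),
        "carrying_sizes": (150_000, 500_000),
        "migration": (0.0, 0.0),
        "n_per_deme": [50, 50],
        "deme_names": ("PAC", "EUR"),
    },
    # serial colonisation end point: extreme founder event (0.05%)
    "balsfjord_serial": {
        "n_anc": 150_000,
        "split_time_years": 10_000,
        "founder_fractions": (0.99, 0.0005),
        "growth_rates": (0.05, 0.005),
        "carrying_sizes": (150_000, 500_000),
        "migration": (0.0, 0.0),
        "n_per_deme": [50, 39],
        "deme_names": ("PAC", "BLS"),
    },
}


def scenario_model(config: dict) -> tuple[DemographicModel, list[int]]:
    """Build a :class:`DemographicModel` from a scenario config dict."""
    generation_years = config.get("generation_years", 4.0)
    split_years = config.get("split_time_years")
    model = DemographicModel(
        n_anc=config["n_anc"],
        split_time=(None if split_years is None else split_years / generation_years),
        founder_fractions=tuple(config.get("founder_fractions", (0.99, 0.01))),
        growth_rates=tuple(config.get("growth_rates", (0.05, 0.05))),
        carrying_sizes=(
            tuple(config["carrying_sizes"]) if config.get("carrying_sizes") else None
        ),
        migration=tuple(config.get("migration", (0.0, 0.0))),
        generation_years=generation_years,
        deme_names=tuple(
            config.get("deme_names", ("D1",) if split_years is None else ("D1", "D2"))
        ),
    )
    return model, list(config["n_per_deme"])


def simulate_scenario(
    config: str | dict,
    seed: int | None = None,
    infinite_sites: bool = True,
    partitions: Sequence[MutationPartition] | None = None,
) -> SimulatedDataset:
    """Simulate a named preset or explicit config end to end."""
    if isinstance(config, str):
        if config not in SCENARIO_PRESETS:
            raise KeyError(
                f"unknown preset '{config}'; options: {sorted(SCENARIO_PRESETS)}"
            )
        config = SCENARIO_PRESETS[config]
    model, n_per_deme = scenario_model(config)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    genealogy = simulate_genealogy(model, n_per_deme, seed=seeds[0])
    return drop_mutations(
        genealogy,
        partitions if partitions is not None else default_partitions(),
        seed=seeds[1],
        infinite_sites=infinite_sites,
        model=model,
    )


def simulate_transarctic_scenario(
    seed: int | None = None, config: dict | None = None, **kwargs
) -> SimulatedDataset:
    """Convenience wrapper for the founder-bottleneck invasion scenario."""
    merged = dict(SCENARIO_PRESETS["transarctic_bottleneck"])
    if config:
        merged.update(config)
    return simulate_scenario(merged, seed=seed, **kwargs)
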