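"""Sequence and population-map I/O, partition handling, haplotype collapsing.

The analyses downstream operate on aligned mitochondrial sequences carrying
two named partitions (a protein-coding gene, e.g. cytochrome b, and a
control-region fragment), a sample-to-population map, and a table of
distinct haplotypes with per-population counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = set("ACGTN-")

#: characters treated as missing/unresolved when comparing sites pairwise
MISSING = set("N-")


class FormatError(ValueError):
    """Malformed input file or inconsistent record set."""


@dataclass(frozen=True)
class Partition:
    """Half-open 0-based interval [start, end) with a name."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid partition bounds {self.start}:{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PartitionedAlignment:
    """Aligned nucleotide sequences with named, contiguous partitions.

    Invariants enforced on construction: all sequences share one length L,
    sample ids are unique, and the partitions tile [0, L) in order without
    gaps or overlap.
    """

    sample_ids: list[str]
    sequences: list[str]
    partitions: list[Partition]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("sample_ids and sequences length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise FormatError(f"duplicate sample ids: {dupes}")
        length = self.length
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != length:
                raise FormatError(
                    f"record '{sid}' has length {len(seq)}, expected {length}"
                )
            bad = set(seq.upper()) - VALID_CHARS
            if bad:
                raise FormatError(f"record '{sid}' contains invalid characters {bad}")
        pos = 0
        for part in self.partitions:
            if part.start != pos:
                raise ValueError(
                    f"partitions must be contiguous; '{part.name}' starts at "
                    f"{part.start}, expected {pos}"
                )
            pos = part.end
        if pos != length:
            raise ValueError(f"partitions cover [0, {pos}) but alignment length is {length}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else sum(p.length for p in self.partitions)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def partition_names(self) -> list[str]:
        return [p.name for p in self.partitions]

    def get_partition(self, name: str) -> "PartitionedAlignment":
        """Sub-alignment restricted to one partition (re-indexed to 0)."""
        for part in self.partitions:
            if part.name == name:
                return PartitionedAlignment(
                    sample_ids=list(self.sample_ids),
                    sequences=[s[part.start : part.end] for s in self.sequences],
                    partitions=[Partition(name, 0, part.length)],
                )
        raise KeyError(f"no partition named '{name}'")

    def sequence_of(self, sample_id: str) -> str:
        return self.sequences[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Iterable[str]) -> "PartitionedAlignment":
        wanted = list(sample_ids)
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        return PartitionedAlignment(
            sample_ids=wanted,
            sequences=[self.sequences[index[s]] for s in wanted],
            partitions=list(self.partitions),
        )


def read_fasta(path: str | Path, partition_spec: Sequence[tuple[str, int, int]]) -> PartitionedAlignment:
    """Read an aligned multi-FASTA into a :class:`PartitionedAlignment`.

    ``partition_spec`` is an ordered list of ``(name, start, end)`` half-open
    0-based intervals whose lengths must sum to the record length. Input
    order of records is preserved.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {path}")
    partitions = [Partition(n, s, e) for n, s, e in partition_spec]
    total = partitions[-1].end
    for rec in records:
        if len(rec.seq) != total:
            raise FormatError(
                f"record '{rec.id}' has length {len(rec.seq)}, expected {total} "
                f"from partition spec"
            )
    return PartitionedAlignment(
        sample_ids=[rec.id for rec in records],
        sequences=[str(rec.seq) for rec in records],
        partitions=partitions,
    )


def write_fasta(aln: PartitionedAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate(aln_a: PartitionedAlignment, aln_b: PartitionedAlignment) -> PartitionedAlignment:
    """Join two alignments sample-wise; partitions of both are preserved.

    Sample order follows ``aln_a``. The sample-id sets must be identical.
    """
    if not aln_b.sample_ids and not aln_b.partitions:
        return aln_a
    set_a, set_b = set(aln_a.sample_ids), set(aln_b.sample_ids)
    if set_a != set_b:
        diff = sorted(set_a.symmetric_difference(set_b))
        raise FormatError(f"sample sets differ; symmetric difference: {diff}")
    offset = aln_a.length
    new_parts = list(aln_a.partitions) + [
        Partition(p.name, p.start + offset, p.end + offset) for p in aln_b.partitions
    ]
    index_b = {sid: i for i, sid in enumerate(aln_b.sample_ids)}
    seqs = [
        seq_a + aln_b.sequences[index_b[sid]]
        for sid, seq_a in zip(aln_a.sample_ids, aln_a.sequences)
    ]
    return PartitionedAlignment(list(aln_a.sample_ids), seqs, new_parts)


@dataclass
class PopulationMap:
    """Sample → (population, group) assignment plus population order.

    ``group`` may be ``None``; groups model regional pools such as the
    European population groups or ocean-basin groupings.
    """

    assignments: dict[str, tuple[str, str | None]]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop, _ in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, grp in self.assignments.values():
            if grp is not None:
                seen.setdefault(grp)
        return list(seen)

    def population_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][0]

    def group_of(self, sample_id: str) -> str | None:
        return self.assignments[sample_id][1]

    def samples_in(self, population: str) -> list[str]:
        return [s for s, (p, _) in self.assignments.items() if p == population]

    def populations_in_group(self, group: str) -> list[str]:
        seen: dict[str, None] = {}
        for pop, grp in self.assignments.values():
            if grp == group:
                seen.setdefault(pop)
        return list(seen)

    def group_to_populations(self) -> dict[str, list[str]]:
        return {g: self.populations_in_group(g) for g in self.groups}

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for pop, _ in self.assignments.values():
            out[pop] = out.get(pop, 0) + 1
        return out


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a TSV with header ``sample_id<TAB>population[<TAB>group]``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise FormatError(
            f"popmap {path} must have columns sample_id, population[, group]; "
            f"found {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"duplicate sample ids in popmap: {dupes}")
    has_group = "group" in df.columns
    assignments = {}
    for _, row in df.iterrows():
        grp = row["group"] if has_group and pd.notna(row["group"]) else None
        assignments[row["sample_id"]] = (row["population"], grp)
    return PopulationMap(assignments)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "population": pop, "group": grp if grp is not None else ""}
        for sid, (pop, grp) in popmap.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with a haplotype × population count matrix.

    Haplotype ids are assigned in order of first appearance in the input
    alignment (``H001``, ``H002``, ...), which makes collapsing
    deterministic for a fixed input file.
    """

    sequences: dict[str, str]
    counts: pd.DataFrame  # index = haplotype ids, columns = populations
    partitions: list[Partition] = field(default_factory=list)

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def frequency(self, hap_id: str) -> int:
        return int(self.counts.loc[hap_id].sum())

    def population_sizes(self) -> dict[str, int]:
        return {p: int(self.counts[p].sum()) for p in self.populations}

    def counts_in(self, populations: Iterable[str]) -> pd.Series:
        return self.counts[list(populations)].sum(axis=1)

    def subset_populations(self, populations: Iterable[str]) -> "HaplotypeTable":
        pops = list(populations)
        sub = self.counts[pops]
        keep = sub.sum(axis=1) > 0
        sub = sub.loc[keep]
        return HaplotypeTable(
            sequences={h: self.sequences[h] for h in sub.index},
            counts=sub.copy(),
            partitions=list(self.partitions),
        )

    def expand(self) -> list[str]:
        """Reconstruct the multiset of sequences (order: haplotype-major)."""
        out = []
        for hap in self.haplotype_ids:
            out.extend([self.sequences[hap]] * self.frequency(hap))
        return out


def _strict_key(seq: str) -> str:
    return seq


def collapse_haplotypes(
    aln: PartitionedAlignment,
    popmap: PopulationMap,
    ambiguity_rule: str = "strict",
) -> HaplotypeTable:
    """Merge identical sequences into haplotypes with per-population counts.

    ``ambiguity_rule='strict'`` treats ``N`` and ``-`` as ordinary fifth/sixth
    states, so sequences must match character-for-character to merge; under
    ``'pairwise-ignore'`` sites missing in either sequence are skipped for
    the identity comparison and each sequence is merged greedily into the
    first previously seen haplotype it matches.
    """
    if ambiguity_rule not in ("strict", "pairwise-ignore"):
        raise ValueError(f"unknown ambiguity rule '{ambiguity_rule}'")
    unmapped = [s for s in aln.sample_ids if s not in popmap.assignments]
    if unmapped:
        raise FormatError(f"samples missing from popmap: {unmapped}")
    populations = popmap.populations

    hap_seqs: list[str] = []
    hap_of_sample: list[int] = []
    if ambiguity_rule == "strict":
        seen: dict[str, int] = {}
        for seq in aln.sequences:
            idx = seen.setdefault(seq, len(hap_seqs))
            if idx == len(hap_seqs):
                hap_seqs.append(seq)
            hap_of_sample.append(idx)
    else:
        for seq in aln.sequences:
            for idx, rep in enumerate(hap_seqs):
                if _matches_ignoring_missing(seq, rep):
                    hap_of_sample.append(idx)
                    break
            else:
                hap_of_sample.append(len(hap_seqs))
                hap_seqs.append(seq)

    width = max(3, len(str(len(hap_seqs))))
    ids = [f"H{i + 1:0{width}d}" for i in range(len(hap_seqs))]
    counts = pd.DataFrame(0, index=ids, columns=populations, dtype=int)
    for sid, hap_idx in zip(aln.sample_ids, hap_of_sample):
        counts.loc[ids[hap_idx], popmap.population_of(sid)] += 1
    return HaplotypeTable(
        sequences=dict(zip(ids, hap_seqs)),
        counts=counts,
        partitions=list(aln.partitions),
    )


def _matches_ignoring_missing(a: str, b: str) -> bool:
    return all(x == y or x in MISSING or y in MISSING for x, y in zip(a, b))
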