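import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from clupeagen.seq_io import (
    HaplotypeTable,
    Partition,
    PartitionedAlignment,
    PopulationMap,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_alignment(rng, n=10, length=60, partitions=None, n_variable=10):
    """Random aligned sequences sharing a template with scattered variants."""
    template = rng.choice(list("ACGT"), size=length)
    seqs = []
    var_sites = rng.choice(length, size=min(n_variable, length), replace=False)
    for _ in range(n):
        seq = template.copy()
        for site in var_sites:
            if rng.random() < 0.3:
                seq[site] = rng.choice([b for b in "ACGT" if b != template[site]])
        seqs.append("".join(seq))
    partitions = partitions or [Partition("g", 0, length)]
    return PartitionedAlignment(
        sample_ids=[f"s{i:02d}" for i in range(n)],
        sequences=seqs,
        partitions=partitions,
    )


@pytest.fixture
def toy_alignment(rng):
    return random_alignment(rng, n=12, length=40)


@pytest.fixture
def toy_popmap(toy_alignment):
    half = len(toy_alignment.sample_ids) // 2
    return PopulationMap(
        {
            sid: ("P1" if i < half else "P2", "G1" if i < half else "G2")
            for i, sid in enumerate(toy_alignment.sample_ids)
        }
    )


def haplotype_table(seq_count_pairs, populations, length=None):
    """Build a HaplotypeTable from [(sequence, {pop: count}), ...]."""
    ids = [f"H{i+1:03d}" for i in range(len(seq_count_pairs))]
    seqs = {h: s for h, (s, _) in zip(ids, seq_count_pairs)}
    counts = pd.DataFrame(
        [[cnt.get(p, 0) for p in populations] for _, cnt in seq_count_pairs],
        index=ids,
        columns=populations,
        dtype=int,
    )
    L = length or len(seq_count_pairs[0][0])
    return HaplotypeTable(sequences=seqs, counts=counts, partitions=[Partition("g", 0, L)])
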