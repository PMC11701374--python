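"""Shared fixtures: a toy allele database and a small simulated locus.

The expensive fixtures are session-scoped; every test that mutates data
must copy it first.
"""

from __future__ import annotations

import numpy as np
import pytest

from kirdecomp.alleledb import load_db
from kirdecomp.align import Read
from kirdecomp.simkir import SimConfig, make_database, simulate_diploid


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_genes=3,
        gene_len=1600,
        alleles_per_gene=4,
        coverage=15.0,
        spacer_len=300,
        neutral_len=1500,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_db_products(small_cfg):
    rng = np.random.default_rng(small_cfg.seed)
    return make_database(small_cfg, rng)


@pytest.fixture(scope="session")
def small_db(small_db_products, tmp_path_factory):
    db_fasta, _, _ = small_db_products
    path = tmp_path_factory.mktemp("db") / "alleles.fasta"
    path.write_text(db_fasta)
    return load_db(path)


@pytest.fixture(scope="session")
def small_sample(small_cfg, small_db_products):
    db_fasta, gene_sequences, truth = small_db_products
    return simulate_diploid(
        small_cfg, db_fasta, gene_sequences, truth.variants, sample_seed=7
    )


@pytest.fixture(scope="session")
def small_reads(small_sample) -> list[Read]:
    return [
        Read(f"{rid}/{i}", seq)
        for rid, r1, r2 in small_sample.reads
        for i, seq in ((1, r1), (2, r2))
    ]


def as_functional(genotype: dict[str, dict[str, int]]) -> dict[str, dict[str, int]]:
    """Collapse a genotype to bare 3-digit allele keys per gene."""
    out: dict[str, dict[str, int]] = {}
    for gene, alleles in genotype.items():
        agg: dict[str, int] = {}
        for name, cn in alleles.items():
            key = name.rsplit("*", 1)[-1][:3]
            agg[key] = agg.get(key, 0) + cn
        out[gene] = agg
    return out
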