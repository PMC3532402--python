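from __future__ import annotations

import numpy as np
import pytest

from tilemark.types import GeneModel, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=42,
        genome_length_bp=200_000,
        n_genes=40,
        n_tissues=8,
        gene_type_fractions={"protein_coding": 0.5, "transposon": 0.3, "pseudogene": 0.2},
    )


def make_gene(gene_id="g1", chrom="chr1", start=1000, end=2000, strand="+",
              gene_type="protein_coding", te_class=None) -> GeneModel:
    return GeneModel(gene_id, chrom, start, end, strand, gene_type, te_class)


@pytest.fixture
def gene_factory():
    return make_gene
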