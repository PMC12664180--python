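"""Shared fixtures: one synthetic bundle reused across the suite."""

from __future__ import annotations

import pytest

from famscan.genome_io import load_gene_models
from famscan.synthetic_data import SimConfig, generate_genome_annotation

MASTER_SEED = 1


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def bundle(sim_config):
    return generate_genome_annotation(sim_config, MASTER_SEED)


@pytest.fixture(scope="session")
def gene_models(bundle, tmp_path_factory):
    gff = tmp_path_factory.mktemp("gff") / "annotation.gff3"
    gff.write_text(bundle.gff_text)
    return load_gene_models(gff, bundle.proteins)


@pytest.fixture(scope="session")
def primary_models(gene_models):
    """One model per gene locus (isoform transcripts excluded)."""
    return {m.gene_id: m for m in gene_models if "." not in m.gene_id}
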