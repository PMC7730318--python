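"""Shared fixtures: small hand-built inputs and session-scoped synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

from tssnuc.classify import build_classification
from tssnuc.model import RESISTANT, SENSITIVE
from tssnuc.profiles import build_count_matrix
from tssnuc.simulate import (
    SimulationConfig,
    generate_expression,
    generate_genome,
    generate_nucleosomes,
    genes_from_tables,
)

#: seed for every session-scoped default dataset; fixed up front
DEFAULT_SEED = 20


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 5000 genes, planted architecture.

    Returns a dict with the generator tables, materialised genes,
    classification result and per-sensitivity count matrices — the
    expensive objects every planted-recovery test shares.
    """
    cfg = SimulationConfig()
    gene_table, domains = generate_genome(cfg, DEFAULT_SEED + 1)
    expression = generate_expression(gene_table, cfg, DEFAULT_SEED + 2)
    resistant, sensitive = generate_nucleosomes(gene_table, expression, cfg, DEFAULT_SEED + 3)
    genes = genes_from_tables(gene_table, expression)
    classification = build_classification(genes, domains, cfg.mapping)
    matrices = {
        RESISTANT: build_count_matrix(genes, resistant, sensitivity=RESISTANT),
        SENSITIVE: build_count_matrix(genes, sensitive, sensitivity=SENSITIVE),
    }
    return {
        "config": cfg,
        "gene_table": gene_table,
        "domains": domains,
        "expression": expression,
        "genes": genes,
        "classification": classification,
        "matrices": matrices,
    }


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small on-disk bundle for I/O and pipeline round-trip tests."""
    from tssnuc.simulate import generate_bundle

    outdir = tmp_path_factory.mktemp("bundle") / "small"
    cfg = SimulationConfig(n_genes=300)
    manifest = generate_bundle(cfg, outdir, DEFAULT_SEED)
    return {"dir": outdir, "manifest": manifest, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(DEFAULT_SEED)
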