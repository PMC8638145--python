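"""Shared fixtures.

The full synthetic E-genome run (assembly, homology discovery,
annotation, tandem clustering) is expensive, so it is built once per
session and shared by the integration and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from prolaminkit import pipeline as pl
from prolaminkit import synthgen as sg
from prolaminkit.homology import QuerySet, ScanParams


@dataclass
class GenomeBundle:
    genomes: list
    models: list
    truth: pd.DataFrame
    records: list          # annotated GeneRecord list (discovery-matched)
    loci: list
    clusters: list
    proportions: dict
    lengths: pd.Series


def _build_bundle(spec, seed: int) -> GenomeBundle:
    rng = np.random.default_rng(seed)
    genomes, models, truth = sg.assemble_genome(spec, rng)
    queries = QuerySet(tuple(sg.generate_query_set(rng)))
    loci, hints = pl.discover_loci(genomes, queries, ScanParams())
    by_gene = pl.match_loci_to_models(loci, models)
    matched = [m for m in models if m.gene_id in by_gene]
    records = pl.annotate_genes(matched, genomes, loci_by_gene=by_gene,
                                hints=hints)
    clusters, proportions = pl.tandem_analysis(records)
    lengths = pd.Series({m.gene_id: m.spliced_length for m in models},
                        name="length_nt")
    return GenomeBundle(genomes, models, truth, records, loci,
                        clusters, proportions, lengths)


@pytest.fixture(scope="session")
def e_genome() -> GenomeBundle:
    """The default E-genome study conditions, run end-to-end once."""
    return _build_bundle(sg.thinopyrum_e_spec(), seed=20240901)


@pytest.fixture(scope="session")
def demo_genome() -> GenomeBundle:
    """Small one-chromosome genome for cheap integration checks."""
    return _build_bundle(sg.small_demo_spec(), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
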