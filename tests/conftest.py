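"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from lrapa.annotation_io import GenomeSequence, load_reference_pas, parse_gene_models
from lrapa.pas_calling import call_pas
from lrapa.quantification import count_reads_at_pas
from lrapa.synthetic_fixtures import simulate_read_ends, simulate_reference


@pytest.fixture(scope="session")
def small_ref(tmp_path_factory):
    """30-gene reference with planted lengthening effects and artifact decoys."""
    out = tmp_path_factory.mktemp("smallref")
    return simulate_reference(
        30,
        seed=101,
        out_dir=out,
        frac_lengthening=0.2,
        frac_artifact_genes=0.3,
    )


@pytest.fixture(scope="session")
def small_table(small_ref):
    return simulate_read_ends(small_ref, depth_mean=200, n_replicates=3, seed=102)


@pytest.fixture(scope="session")
def small_models(small_ref):
    return parse_gene_models(small_ref.gtf_path)


@pytest.fixture(scope="session")
def small_genome(small_ref):
    return GenomeSequence(small_ref.fasta_path)


@pytest.fixture(scope="session")
def small_refpas(small_ref):
    return load_reference_pas(small_ref.bed_path)


@pytest.fixture(scope="session")
def small_catalog(small_table, small_models, small_refpas, small_genome):
    return call_pas(
        small_table, small_models, reference=small_refpas, genome=small_genome
    )


@pytest.fixture(scope="session")
def small_matrix(small_table, small_catalog):
    return count_reads_at_pas(small_table, small_catalog)
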