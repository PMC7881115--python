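import numpy as np
import pytest

from charflow.genome_annotation import TranscriptRecord, build_unique_gene_models
from charflow.intervals import GenomicInterval
from charflow.pipeline import RunConfig, run_pipeline
from charflow.synthetic import FixtureSpec, generate_fixture


def make_transcript(gene_id, exons, strand="+", chrom="chr1",
                    biotype="protein_coding", tx_id=None):
    return TranscriptRecord(
        gene_id=gene_id,
        transcript_id=tx_id or f"{gene_id}.t1",
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture
def toy_gene_models():
    """Three genes on chr1: plus-strand, minus-strand, and a distal one."""
    txs = [
        make_transcript("geneA", [(10_000, 10_500), (12_000, 13_000)], "+"),
        make_transcript("geneB", [(40_000, 41_000), (44_000, 45_000)], "-"),
        make_transcript("geneC", [(200_000, 203_000)], "+"),
    ]
    return build_unique_gene_models(txs)


@pytest.fixture(scope="session")
def small_spec():
    """Down-sized bundle spec for fast generation-heavy tests."""
    return FixtureSpec(
        seed=7,
        n_chromosomes=2,
        chromosome_length=300_000,
        n_genes=60,
        n_peaks=120,
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Full default fixture bundle (the study-design-sized dataset)."""
    out = tmp_path_factory.mktemp("bundle")
    truth = generate_fixture(FixtureSpec(seed=0), out)
    return truth, out


@pytest.fixture(scope="session")
def pipeline_run(default_bundle, tmp_path_factory):
    """One full pipeline execution on the default bundle, shared by tests."""
    truth, bundle_dir = default_bundle
    out = tmp_path_factory.mktemp("run")
    config = RunConfig.from_yaml(bundle_dir / "run_config.yaml")
    results = run_pipeline(config, out)
    return truth, results, out
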