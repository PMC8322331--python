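import pytest

from peakminer.genome_model import AttributeParams, GenomeAnnotation, TranscriptModel
from peakminer.simulate import FixtureSpec, synth_genome


@pytest.fixture
def params():
    return AttributeParams()


def make_transcript(
    tid="t1",
    gid="g1",
    chrom="chr1",
    strand="+",
    tx=(10_000, 20_000),
    cds=(10_300, 19_600),
    exons=None,
):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        gene_name=gid.upper(),
        chrom=chrom,
        strand=strand,
        tx_start=tx[0],
        tx_end=tx[1],
        cds_start=None if cds is None else cds[0],
        cds_end=None if cds is None else cds[1],
        exons=tuple(exons) if exons else ((tx[0], tx[1]),),
    )


def single_gene_genome(chrom_len=1_000_000, **kwargs) -> GenomeAnnotation:
    t = make_transcript(**kwargs)
    return GenomeAnnotation(
        genes={t.gene_id: [t]}, chrom_sizes={t.chrom: chrom_len}, source_label="toy"
    )


@pytest.fixture
def small_genome():
    """A deterministic 30-gene synthetic genome."""
    return synth_genome(FixtureSpec(seed=7, n_genes=30, chrom_len=300_000))


@pytest.fixture
def small_spec():
    return FixtureSpec(seed=7, n_genes=30, chrom_len=300_000, n_decoy_tfs=5)
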