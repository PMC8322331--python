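import textwrap

import pytest

from conftest import make_transcript, single_gene_genome

from peakminer.genome_model import (
    AnnotationError,
    AttributeParams,
    derive_attribute_regions,
    load_annotation,
    select_isoforms,
    write_bed12,
)
from peakminer.simulate import FixtureSpec, synth_genome


def regions_by_kind(t, p, chrom_len=None):
    return {r.kind: (r.start, r.end) for r in derive_attribute_regions(t, p, chrom_len)}


class TestLoadAnnotation:
    def test_empty_files_give_empty_annotation(self, tmp_path):
        for fmt, name in [("bed12", "a.bed"), ("gff3", "a.gff3")]:
            path = tmp_path / name
            path.write_text("")
            assert load_annotation(str(path), fmt).n_genes == 0

    def test_bed12_blocks_hand_decoded(self, tmp_path):
        # blockSizes 200,300 at offsets 0,700 from start 100 -> exons
        # [100,300) and [800,1100); thickStart == thickEnd -> non-coding
        path = tmp_path / "one.bed"
        path.write_text(
            "chr1\t100\t1100\tt1|g1|G1\t0\t+\t100\t100\t0,0,0\t2\t200,300\t0,700\n"
        )
        ga = load_annotation(str(path), "bed12")
        (t,) = ga.genes["g1"]
        assert (t.tx_start, t.tx_end) == (100, 1100)
        assert t.exons == ((100, 300), (800, 1100))
        assert not t.is_coding

    def test_gff3_one_based_start_shifts(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(
            textwrap.dedent(
                """\
                ##gff-version 3
                chr1\ttest\tgene\t101\t1100\t.\t+\t.\tID=geneA
                chr1\ttest\tmRNA\t101\t1100\t.\t+\t.\tID=tA1;Parent=geneA
                chr1\ttest\texon\t101\t1100\t.\t+\t.\tID=e1;Parent=tA1
                chr1\ttest\tCDS\t201\t900\t.\t+\t.\tID=c1;Parent=tA1
                """
            )
        )
        ga = load_annotation(str(path), "gff3")
        (t,) = ga.genes["geneA"]
        assert (t.tx_start, t.tx_end) == (100, 1100)
        assert (t.cds_start, t.cds_end) == (200, 900)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("chr1\ttest\tgene\t101\t1100\t.\t+\n")
        with pytest.raises(AnnotationError, match="line 1"):
            load_annotation(str(path), "gff3")

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "x.txt"
        path.write_text("")
        with pytest.raises(ValueError, match="format"):
            load_annotation(str(path), "sam")

    def test_bed12_round_trip(self, tmp_path):
        ga = synth_genome(FixtureSpec(seed=3, n_genes=25, chrom_len=250_000))
        out = tmp_path / "genome.bed12"
        write_bed12(ga, str(out))
        ga2 = load_annotation(str(out), "bed12")
        assert ga2.gene_ids() == ga.gene_ids()
        for gid in ga.gene_ids():
            orig = {t.transcript_id: t for t in ga.genes[gid]}
            back = {t.transcript_id: t for t in ga2.genes[gid]}
            assert back == orig


class TestSelectIsoforms:
    def test_singleton(self):
        t = make_transcript()
        assert select_isoforms([t], "longest") == [t]

    def test_strict_maximum_wins(self):
        short = make_transcript(tid="tS", tx=(0, 1000), cds=None)
        long = make_transcript(tid="tL", tx=(0, 2000), cds=None)
        assert select_isoforms([short, long], "longest") == [long]

    def test_equal_spans_tie_break_on_id(self):
        tb = make_transcript(tid="tB", tx=(0, 1000), cds=None)
        ta = make_transcript(tid="tA", tx=(5000, 6000), cds=None)
        assert select_isoforms([tb, ta], "longest")[0].transcript_id == "tA"

    def test_all_mode_returns_input(self):
        txs = [make_transcript(tid=f"t{i}", cds=None) for i in range(3)]
        assert select_isoforms(txs, "all") == txs

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            select_isoforms([], "longest")


class TestAttributeRegions:
    def test_plus_strand_promoter_window(self, params):
        t = make_transcript(strand="+", tx=(10_000, 20_000))
        assert regions_by_kind(t, params)["TSS"] == (8_000, 10_500)

    def test_minus_strand_promoter_mirrors(self, params):
        t = make_transcript(strand="-", tx=(10_000, 20_000))
        assert regions_by_kind(t, params)["TSS"] == (19_500, 22_000)

    def test_clipped_at_chromosome_origin(self, params):
        t = make_transcript(tx=(500, 3_000), cds=None)
        assert regions_by_kind(t, params)["TSS"] == (0, 1_000)

    def test_clipped_at_chromosome_end(self, params):
        t = make_transcript(strand="-", tx=(10_000, 20_000))
        assert regions_by_kind(t, params, chrom_len=21_000)["TSS"] == (19_500, 21_000)

    def test_utrs_and_cds_tile_transcript(self):
        p = AttributeParams()
        for strand in "+-":
            t = make_transcript(strand=strand, tx=(10_000, 20_000), cds=(10_300, 19_600))
            r = regions_by_kind(t, p)
            pieces = sorted([r["UTR5"], r["CDS"], r["UTR3"]])
            assert pieces[0][0] == 10_000 and pieces[-1][1] == 20_000
            assert pieces[0][1] == pieces[1][0] and pieces[1][1] == pieces[2][0]

    def test_cds_spans_introns(self, params):
        t = make_transcript(
            tx=(10_000, 20_000), cds=(10_300, 19_600),
            exons=[(10_000, 12_000), (15_000, 20_000)],
        )
        assert regions_by_kind(t, params)["CDS"] == (10_300, 19_600)

    def test_noncoding_gets_gene_body(self, params):
        t = make_transcript(cds=None)
        r = regions_by_kind(t, params)
        assert r["CDS"] == (10_000, 20_000)
        assert "UTR5" not in r and "UTR3" not in r

    def test_ignoring_strand_treats_minus_as_plus(self):
        p = AttributeParams(respect_strand=False)
        minus = make_transcript(strand="-", tx=(10_000, 20_000))
        plus = make_transcript(strand="+", tx=(10_000, 20_000))
        assert regions_by_kind(minus, p) == regions_by_kind(plus, p)

    def test_strand_symmetry_under_coordinate_reflection(self, params):
        """A '-' transcript's attributes are the mirror image of its reflected
        '+' twin's attributes."""
        L = 100_000
        minus = make_transcript(strand="-", tx=(10_000, 20_000), cds=(10_300, 19_600))
        plus = make_transcript(
            strand="+",
            tx=(L - 20_000, L - 10_000),
            cds=(L - 19_600, L - 10_300),
        )
        mirrored = {
            kind: (L - e, L - s) for kind, (s, e) in regions_by_kind(plus, params).items()
        }
        assert regions_by_kind(minus, params) == mirrored

    def test_zero_length_regions_emitted_degenerate(self):
        p = AttributeParams(flank5_len=0, flank3_len=0)
        t = make_transcript(cds=None)
        r = regions_by_kind(t, p)
        assert r["FLANK5"][0] == r["FLANK5"][1]
        assert r["FLANK3"][0] == r["FLANK3"][1]


def test_transcript_invariants_rejected():
    with pytest.raises(AnnotationError):
        make_transcript(tx=(100, 100), cds=None)
    with pytest.raises(AnnotationError):
        make_transcript(tx=(0, 1000), cds=(500, 2000))
    with pytest.raises(AnnotationError):
        make_transcript(tx=(0, 1000), cds=None, exons=[(0, 600), (500, 1000)])
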