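"""Gene models and gene-feature attribute regions.

Parses genome annotations (GFF3, GTF or BED12) into transcript models and
derives, per transcript, the strand-aware gene-feature attributes used
throughout the toolkit:

* ``FLANK5`` — user-sized region upstream of the transcript body,
* ``TSS``    — promoter window around the transcription start site
  (default 2000 bp upstream to 500 bp downstream),
* ``UTR5`` / ``CDS`` / ``UTR3`` — the annotated untranslated regions and the
  coding span (exons *and* introns between the CDS boundaries),
* ``FLANK3`` — user-sized region downstream of the transcript body.

All internal coordinates are 0-based, half-open (BED convention); GFF3/GTF
starts are shifted by -1 on read. Non-coding transcripts carry no UTRs and
their ``CDS`` attribute is the full transcript span (a gene-body stand-in),
so they remain annotatable. Regions running off a chromosome edge are
clipped, never discarded.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import gffutils

#: Canonical order of gene-feature attribute kinds.
ATTRIBUTE_KINDS = ("FLANK5", "TSS", "UTR5", "CDS", "UTR3", "FLANK3")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: span, strand, exon structure and optional CDS."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int
    tx_end: int
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.tx_start < self.tx_end:
            raise AnnotationError(
                f"transcript {self.transcript_id}: tx_start must be < tx_end "
                f"({self.tx_start} >= {self.tx_end})"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.transcript_id}: cds_start and cds_end must both be set or absent"
            )
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                    f"not contained in transcript span [{self.tx_start},{self.tx_end})"
                )
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon [{s},{e}) outside transcript span"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted at [{s},{e})"
                )
            prev_end = e

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    def tss(self, respect_strand: bool = True) -> int:
        """TSS coordinate: tx_start on '+', tx_end on '-' (when strand is respected)."""
        if respect_strand and self.strand == "-":
            return self.tx_end
        return self.tx_start

    def effective_strand(self, respect_strand: bool = True) -> str:
        return self.strand if respect_strand else "+"


@dataclass
class GenomeAnnotation:
    """A set of gene models keyed by gene id, with optional chromosome sizes."""

    genes: dict[str, list[TranscriptModel]] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    source_label: str = ""

    def transcripts(self) -> Iterator[TranscriptModel]:
        for txs in self.genes.values():
            yield from txs

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def chromosomes(self) -> set[str]:
        return {t.chrom for t in self.transcripts()}

    def gene_span(self, gene_id: str) -> tuple[str, int, int, str]:
        """(chrom, start, end, strand) covering all isoforms of a gene."""
        txs = self.genes[gene_id]
        return (
            txs[0].chrom,
            min(t.tx_start for t in txs),
            max(t.tx_end for t in txs),
            txs[0].strand,
        )

    def validate(self) -> None:
        for gid, txs in self.genes.items():
            if not txs:
                raise AnnotationError(f"gene {gid} has no transcripts")
            for t in txs:
                if t.gene_id != gid:
                    raise AnnotationError(
                        f"transcript {t.transcript_id} filed under {gid} but reports {t.gene_id}"
                    )
            if len({t.chrom for t in txs}) != 1:
                raise AnnotationError(f"gene {gid}: isoforms on different chromosomes")


@dataclass(frozen=True)
class AttributeParams:
    """Parameters controlling attribute-region construction.

    tss_upstream / tss_downstream size the promoter window around the TSS
    (defaults 2000 / 500 bp). flank5_len / flank3_len size the flanking
    regions beyond the transcript body (default 5000 bp each).
    isoform_mode 'longest' keeps one isoform per gene; 'all' keeps every
    isoform. respect_strand=False treats every transcript as '+'.
    """

    tss_upstream: int = 2000
    tss_downstream: int = 500
    flank5_len: int = 5000
    flank3_len: int = 5000
    isoform_mode: str = "longest"
    respect_strand: bool = True

    def __post_init__(self) -> None:
        for name in ("tss_upstream", "tss_downstream", "flank5_len", "flank3_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.isoform_mode not in ("longest", "all"):
            raise ValueError(f"isoform_mode must be 'longest' or 'all', got {self.isoform_mode!r}")


@dataclass(frozen=True)
class AttributeRegion:
    """A strand-aware interval labelled with one gene-feature attribute."""

    gene_id: str
    transcript_id: str
    kind: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ATTRIBUTE_KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(
                f"region {self.gene_id}/{self.kind}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# isoform selection and attribute derivation
# ---------------------------------------------------------------------------

def select_isoforms(transcripts: Sequence[TranscriptModel], mode: str) -> list[TranscriptModel]:
    """Pick the isoforms to annotate for one gene.

    mode='all' returns the input unchanged; mode='longest' returns the single
    transcript maximizing span length, ties broken by lexicographically
    smallest transcript id.
    """
    if not transcripts:
        raise ValueError("select_isoforms requires a non-empty transcript list")
    if mode == "all":
        return list(transcripts)
    if mode == "longest":
        best = min(transcripts, key=lambda t: (-t.length, t.transcript_id))
        return [best]
    raise ValueError(f"unknown isoform mode {mode!r}")


def _clip(start: int, end: int, chrom_len: Optional[int]) -> tuple[int, int]:
    start = max(0, start)
    end = max(0, end)
    if chrom_len is not None:
        start = min(start, chrom_len)
        end = min(end, chrom_len)
    if end < start:
        end = start
    return start, end


def derive_attribute_regions(
    t: TranscriptModel,
    p: AttributeParams,
    chrom_len: Optional[int] = None,
) -> list[AttributeRegion]:
    """Derive the gene-feature attribute regions of one transcript.

    TSS, FLANK5 and FLANK3 are always emitted. UTR5/CDS/UTR3 are emitted only
    for coding transcripts; a non-coding transcript instead gets a CDS region
    equal to its full span (gene body). Degenerate (zero-length) regions are
    emitted with start == end; chromosome-edge regions are clipped.
    """
    strand = t.effective_strand(p.respect_strand)
    s, e = t.tx_start, t.tx_end
    raw: list[tuple[str, int, int]] = []
    if strand == "+":
        raw.append(("TSS", s - p.tss_upstream, s + p.tss_downstream))
        raw.append(("FLANK5", s - p.flank5_len, s))
        raw.append(("FLANK3", e, e + p.flank3_len))
        if t.is_coding:
            raw.append(("UTR5", s, t.cds_start))
            raw.append(("CDS", t.cds_start, t.cds_end))
            raw.append(("UTR3", t.cds_end, e))
        else:
            raw.append(("CDS", s, e))
    else:
        raw.append(("TSS", e - p.tss_downstream, e + p.tss_upstream))
        raw.append(("FLANK5", e, e + p.flank5_len))
        raw.append(("FLANK3", s - p.flank3_len, s))
        if t.is_coding:
            raw.append(("UTR5", t.cds_end, e))
            raw.append(("CDS", t.cds_start, t.cds_end))
            raw.append(("UTR3", s, t.cds_start))
        else:
            raw.append(("CDS", s, e))

    out = []
    for kind, rs, re_ in raw:
        rs, re_ = _clip(rs, re_, chrom_len)
        out.append(
            AttributeRegion(
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                kind=kind,
                chrom=t.chrom,
                strand=strand,
                start=rs,
                end=re_,
            )
        )
    order = {k: i for i, k in enumerate(ATTRIBUTE_KINDS)}
    out.sort(key=lambda r: order[r.kind])
    return out


def iter_attribute_regions(
    ga: GenomeAnnotation,
    p: AttributeParams,
    kinds: Optional[Iterable[str]] = None,
) -> Iterator[AttributeRegion]:
    """All attribute regions of an annotation under isoform selection."""
    wanted = set(ATTRIBUTE_KINDS if kinds is None else kinds)
    unknown = wanted - set(ATTRIBUTE_KINDS)
    if unknown:
        raise ValueError(f"unknown attribute kind(s): {sorted(unknown)}")
    for gid in ga.gene_ids():
        for t in select_isoforms(ga.genes[gid], p.isoform_mode):
            chrom_len = ga.chrom_sizes.get(t.chrom)
            for r in derive_attribute_regions(t, p, chrom_len):
                if r.kind in wanted:
                    yield r


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _add_transcript(genes: dict[str, list[TranscriptModel]], t: TranscriptModel) -> None:
    genes.setdefault(t.gene_id, []).append(t)


def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise AnnotationError(f"line {lineno}: BED12 record has {len(fields)} fields, expected 12")
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3]
        strand = fields[5]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: malformed BED12 record ({exc})") from exc
    if len(sizes) != block_count or len(offsets) != block_count:
        raise AnnotationError(f"line {lineno}: block count does not match block lists")
    if strand not in ("+", "-"):
        strand = "+"
    # name encodes transcript|gene|gene_name; bare names serve as all three
    parts = name.split("|")
    tx_id = parts[0]
    gene_id = parts[1] if len(parts) > 1 and parts[1] else tx_id
    gene_name = parts[2] if len(parts) > 2 and parts[2] else gene_id
    exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
    cds_start: Optional[int] = thick_start
    cds_end: Optional[int] = thick_end
    if thick_start >= thick_end:  # UCSC convention for non-coding
        cds_start = cds_end = None
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        gene_name=gene_name,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=exons,
    )


def _load_bed12(path: str) -> GenomeAnnotation:
    genes: dict[str, list[TranscriptModel]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            _add_transcript(genes, _parse_bed12_line(line, lineno))
    return GenomeAnnotation(genes=genes, source_label=os.path.basename(path))


def _validate_gff_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            n = len(stripped.split("\t"))
            if n != 9:
                raise AnnotationError(
                    f"line {lineno}: expected 9 tab-separated columns, found {n}"
                )


def _first_attr(feature, *names: str, default: str = "") -> str:
    for n in names:
        if n in feature.attributes:
            v = feature.attributes[n]
            if v:
                return v[0]
    return default


_TRANSCRIPT_TYPES = (
    "mRNA",
    "transcript",
    "ncRNA",
    "lnc_RNA",
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "pseudogenic_transcript",
)


def _load_gff_like(path: str, dialect: str) -> GenomeAnnotation:
    _validate_gff_lines(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return GenomeAnnotation(source_label=os.path.basename(path))
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=(dialect == "gff3"),
        disable_infer_transcripts=(dialect == "gff3"),
    )
    genes: dict[str, list[TranscriptModel]] = {}
    seen: set[str] = set()
    for ttype in _TRANSCRIPT_TYPES:
        for tf in db.features_of_type(ttype):
            if tf.id in seen:
                continue
            seen.add(tf.id)
            tx_id = _first_attr(tf, "transcript_id", "ID", default=tf.id)
            gene_id = _first_attr(tf, "gene_id", "Parent", default=tx_id)
            gene_name = _first_attr(tf, "gene_name", "Name", default=gene_id)
            exons = sorted(
                (c.start - 1, c.end) for c in db.children(tf, featuretype="exon")
            )
            cds = [(c.start - 1, c.end) for c in db.children(tf, featuretype="CDS")]
            tx_start, tx_end = tf.start - 1, tf.end
            if not exons:
                exons = [(tx_start, tx_end)]
            cds_start = min(c[0] for c in cds) if cds else None
            cds_end = max(c[1] for c in cds) if cds else None
            _add_transcript(
                genes,
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    gene_name=gene_name,
                    chrom=tf.seqid,
                    strand=tf.strand if tf.strand in ("+", "-") else "+",
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=tuple(exons),
                ),
            )
    return GenomeAnnotation(genes=genes, source_label=os.path.basename(path))


def load_annotation(path: str, format: str) -> GenomeAnnotation:
    """Load a genome annotation from GFF3, GTF or BED12.

    Coordinates are normalized to 0-based half-open; GFF3/GTF starts are
    shifted by -1. Malformed records raise :class:`AnnotationError` naming
    the offending line.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "bed12":
        ga = _load_bed12(path)
    elif fmt in ("gff3", "gff", "gtf"):
        ga = _load_gff_like(path, "gff3" if fmt in ("gff3", "gff") else "gtf")
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    ga.validate()
    return ga


def write_bed12(ga: GenomeAnnotation, path: str) -> None:
    """Write an annotation as BED12, one line per transcript.

    The name field packs transcript|gene|gene_name so a re-parse round-trips
    the full identity.
    """
    with open(path, "w") as fh:
        for gid in ga.gene_ids():
            for t in sorted(ga.genes[gid], key=lambda x: x.transcript_id):
                name = f"{t.transcript_id}|{t.gene_id}|{t.gene_name}"
                thick_s = t.cds_start if t.is_coding else t.tx_start
                thick_e = t.cds_end if t.is_coding else t.tx_start
                sizes = ",".join(str(e - s) for s, e in t.exons)
                offsets = ",".join(str(s - t.tx_start) for s, e in t.exons)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            t.chrom,
                            t.tx_start,
                            t.tx_end,
                            name,
                            0,
                            t.strand,
                            thick_s,
                            thick_e,
                            "0,0,0",
                            len(t.exons),
                            sizes,
                            offsets,
                        )
                    )
                    + "\n"
                )


def load_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV (chrom, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationError(f"line {lineno}: expected 'name<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes
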