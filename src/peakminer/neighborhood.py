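"""Gene neighborhoods of a peak: nearest-neighbor slots and windowed retrieval.

``nearby_genes`` extracts the gene overlapping a peak plus the five nearest
genes on each side and classifies every slot by the direction of
differential expression of its genes (UP / DOWN / MIXED / UNCHANGED /
EMPTY). Presence of a gene in the user's differential-expression table is
taken to mean the gene is significantly deregulated, with direction given
by the sign of its log2 fold-change column.

``long_range_genes`` retrieves every gene intersecting a user-sized window
(default 50 kb on each side) around the peak, split into upstream /
overlap / downstream blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .genome_model import GenomeAnnotation
from .intervals import Peak, overlap_bp
from .peak_tools import AnnotationTable, _norm_id

N_NEIGHBORS = 5

SLOT_NAMES = tuple(
    [f"up{i}" for i in range(N_NEIGHBORS, 0, -1)]
    + ["overlap"]
    + [f"down{i}" for i in range(1, N_NEIGHBORS + 1)]
)


@dataclass(frozen=True)
class SlotGene:
    gene_id: str
    distance_bp: int  # 0 for the overlap slot
    log2fc: Optional[float]  # None when not in the DE table

    @property
    def direction(self) -> int:
        """+1 up, -1 down, 0 not deregulated."""
        if self.log2fc is None or self.log2fc == 0:
            return 0
        return 1 if self.log2fc > 0 else -1


@dataclass
class Slot:
    name: str
    genes: list[SlotGene] = field(default_factory=list)

    @property
    def label(self) -> str:
        return classify_slot(self.genes)


@dataclass
class NeighborhoodResult:
    peak: Peak
    slots: list[Slot]

    def slot(self, name: str) -> Slot:
        for s in self.slots:
            if s.name == name:
                return s
        raise KeyError(name)

    def labels(self) -> dict[str, str]:
        return {s.name: s.label for s in self.slots}


@dataclass(frozen=True)
class WindowSpec:
    upstream_bp: int = 50_000
    downstream_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window sizes must be non-negative")


def classify_slot(genes: list[SlotGene]) -> str:
    """Majority-direction label of a slot.

    UP if more genes are upregulated than down (and at least one is), DOWN
    for the converse, MIXED for an equal non-zero split, UNCHANGED when no
    gene is deregulated, EMPTY when the slot holds no genes.
    """
    if not genes:
        return "EMPTY"
    n_up = sum(1 for g in genes if g.direction > 0)
    n_down = sum(1 for g in genes if g.direction < 0)
    if n_up == 0 and n_down == 0:
        return "UNCHANGED"
    if n_up > n_down:
        return "UP"
    if n_down > n_up:
        return "DOWN"
    return "MIXED"


def _de_lookup(table: AnnotationTable, log2fc_column: Optional[str]) -> dict[str, float]:
    col = log2fc_column or table.first_numeric_column()
    if col is None:
        raise ValueError("the annotation table has no numeric log2FC column")
    if col not in table.frame.columns:
        raise ValueError(f"column {col!r} not in annotation table")
    series = pd.to_numeric(table.frame[col], errors="coerce")
    return {gid: v for gid, v in series.items() if pd.notna(v)}


def _gene_spans(ga: GenomeAnnotation, chrom: str) -> list[tuple[str, int, int, str]]:
    spans = []
    for gid in ga.gene_ids():
        c, s, e, strand = ga.gene_span(gid)
        if c == chrom:
            spans.append((gid, s, e, strand))
    return spans


def nearby_genes(
    peak: Peak,
    ga: GenomeAnnotation,
    table: AnnotationTable,
    respect_strand: bool = False,
    log2fc_column: Optional[str] = None,
) -> NeighborhoodResult:
    """Slot the overlapping gene and the 5 nearest genes per side of a peak.

    Distance is measured from the peak edge to the nearest gene-span edge;
    ties break by gene id. Without strand handling, 'up' slots hold genes
    genomically left of the peak; with respect_strand=True a gene on the
    '-' strand swaps sides, so slots are relative to gene orientation.
    """
    spans = _gene_spans(ga, peak.chrom)
    if not spans and peak.chrom not in ga.chromosomes():
        raise ValueError(f"peak chromosome {peak.chrom!r} absent from the annotation")
    de = _de_lookup(table, log2fc_column)

    def de_value(gid: str) -> Optional[float]:
        return de.get(_norm_id(gid))

    overlapping: list[SlotGene] = []
    left: list[tuple[int, str]] = []
    right: list[tuple[int, str]] = []
    for gid, s, e, strand in spans:
        if overlap_bp((s, e), (peak.start, peak.end)) > 0:
            overlapping.append(SlotGene(gid, 0, de_value(gid)))
            continue
        if e <= peak.start:
            side, dist = "left", peak.start - e
        else:
            side, dist = "right", s - peak.end
        if respect_strand and strand == "-":
            side = "right" if side == "left" else "left"
        (left if side == "left" else right).append((dist, gid))
    left.sort()
    right.sort()

    slots = [Slot(name) for name in SLOT_NAMES]
    by_name = {s.name: s for s in slots}
    by_name["overlap"].genes = sorted(overlapping, key=lambda g: g.gene_id)
    for i, (dist, gid) in enumerate(left[:N_NEIGHBORS], start=1):
        by_name[f"up{i}"].genes = [SlotGene(gid, dist, de_value(gid))]
    for i, (dist, gid) in enumerate(right[:N_NEIGHBORS], start=1):
        by_name[f"down{i}"].genes = [SlotGene(gid, dist, de_value(gid))]
    return NeighborhoodResult(peak=peak, slots=slots)


def aggregate_neighborhoods(results: list[NeighborhoodResult]) -> dict[str, str]:
    """Aggregate slot classes across peaks by the same majority rule."""
    out: dict[str, str] = {}
    for name in SLOT_NAMES:
        genes = [g for r in results for g in r.slot(name).genes]
        out[name] = classify_slot(genes)
    return out


def long_range_genes(
    peak: Peak,
    w: WindowSpec,
    ga: GenomeAnnotation,
    table: Optional[AnnotationTable] = None,
    log2fc_column: Optional[str] = None,
) -> dict[str, pd.DataFrame]:
    """Genes intersecting the upstream / downstream windows around a peak.

    Returns 'upstream', 'overlap' and 'downstream' blocks. A gene intersecting
    [peak.start - upstream_bp, peak.start) goes upstream, one intersecting
    [peak.end, peak.end + downstream_bp) goes downstream; genes intersecting
    the peak itself form the overlap block. DE columns are joined when a
    table is given.
    """
    spans = _gene_spans(ga, peak.chrom)
    up_iv = (peak.start - w.upstream_bp, peak.start)
    down_iv = (peak.end, peak.end + w.downstream_bp)
    blocks: dict[str, list[dict]] = {"upstream": [], "overlap": [], "downstream": []}
    for gid, s, e, strand in spans:
        row = {"gene_id": gid, "start": s, "end": e, "strand": strand}
        if overlap_bp((s, e), (peak.start, peak.end)) > 0:
            blocks["overlap"].append(row)
            continue
        if overlap_bp((s, e), up_iv) > 0:
            blocks["upstream"].append(row)
        if overlap_bp((s, e), down_iv) > 0:
            blocks["downstream"].append(row)
    out: dict[str, pd.DataFrame] = {}
    for name, rows in blocks.items():
        df = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])
        df = df.sort_values(["start", "gene_id"], kind="mergesort").reset_index(drop=True)
        if table is not None:
            df = table.join(df)
        out[name] = df
    return out


def neighborhood_frame(result: NeighborhoodResult) -> pd.DataFrame:
    rows = []
    for s in result.slots:
        for g in s.genes:
            rows.append(
                {
                    "slot": s.name,
                    "gene_id": g.gene_id,
                    "distance_bp": g.distance_bp,
                    "log2fc": g.log2fc,
                    "slot_class": s.label,
                }
            )
        if not s.genes:
            rows.append(
                {
                    "slot": s.name,
                    "gene_id": "",
                    "distance_bp": pd.NA,
                    "log2fc": pd.NA,
                    "slot_class": "EMPTY",
                }
            )
    return pd.DataFrame(rows, columns=["slot", "gene_id", "distance_bp", "log2fc", "slot_class"])
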