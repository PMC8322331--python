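"""Peak annotation and multi-track peak integration.

``annotate_peaks`` computes the coverage profile of one peak track over the
gene-feature attributes and returns the table of genes whose selected
attribute(s) meet the overlap criterion, optionally joined with a
user-supplied gene-keyed annotation table (e.g. differential expression).

``integrate_peaks`` runs the same annotation for two to five tracks and
keeps only genes hit in *all* of them (set intersection at gene level).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genome_model import AttributeParams, GenomeAnnotation
from .intervals import (
    CoverageEntry,
    GeneHit,
    OverlapCriterion,
    PeakSet,
    coverage_profile,
    drop_unknown_chroms,
    find_gene_hits,
    gene_hits_frame,
)

logger = logging.getLogger(__name__)

MAX_TRACKS = 5


def _norm_id(x: str) -> str:
    return str(x).strip().casefold()


@dataclass
class AnnotationTable:
    """Gene-keyed annotation table: first column gene IDs, up to 5 more columns.

    Matching is exact after whitespace trimming and case folding.
    """

    frame: pd.DataFrame  # index: normalized gene id; columns: annotation columns

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        if df.shape[1] < 1:
            raise ValueError("annotation table needs at least a gene-ID column")
        if df.shape[1] > 6:
            raise ValueError(f"annotation table has {df.shape[1]} columns, at most 6 allowed")
        ids = df.iloc[:, 0].astype(str).map(_norm_id)
        if (ids == "").any():
            raise ValueError("annotation table has empty gene IDs in column 1")
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())[:5]
            raise ValueError(f"annotation table has duplicate gene IDs (e.g. {dups})")
        body = df.iloc[:, 1:].copy()
        body.index = ids
        body.index.name = "gene_id_key"
        return cls(frame=body)

    @classmethod
    def load(cls, path: str) -> "AnnotationTable":
        sep = "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"
        return cls.from_frame(pd.read_csv(path, sep=sep))

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def first_numeric_column(self) -> Optional[str]:
        for c in self.frame.columns:
            if pd.api.types.is_numeric_dtype(self.frame[c]):
                return c
        return None

    def join(self, table: pd.DataFrame, on: str = "gene_id") -> pd.DataFrame:
        """Left-join annotation columns onto a gene table; blanks where unmatched."""
        keys = table[on].astype(str).map(_norm_id)
        joined = table.copy()
        matched = keys.isin(self.frame.index)
        if len(table) and not matched.any():
            logger.warning(
                "annotation table IDs are disjoint from the gene table (join rate 0)"
            )
        for c in self.frame.columns:
            col = self.frame[c].reindex(keys)
            col.index = table.index
            joined[c] = col
        return joined


def annotate_peaks(
    ps: PeakSet,
    ga: GenomeAnnotation,
    kinds: Sequence[str],
    crit: OverlapCriterion,
    params: AttributeParams,
    table: Optional[AnnotationTable] = None,
) -> tuple[dict[str, CoverageEntry], pd.DataFrame]:
    """Coverage profile plus the gene-hit table for the selected attributes.

    The hit table is the union of per-attribute gene hits, one row per
    (gene, transcript) with qualifying attributes listed, joined with the
    optional annotation table.
    """
    if not kinds:
        raise ValueError("at least one attribute kind must be selected")
    ps = drop_unknown_chroms(ps, ga)
    profile = coverage_profile(ps, ga, params)
    all_hits: list[GeneHit] = []
    for kind in kinds:
        all_hits.extend(find_gene_hits(ps, ga, kind, crit, params))
    df = gene_hits_frame(all_hits)
    if len(df):
        df = (
            df.groupby(["gene_id", "transcript_id"], as_index=False)
            .agg(
                attributes=("attribute", lambda s: ";".join(sorted(set(s)))),
                overlap_bp=("overlap_bp", "max"),
                peak_names=(
                    "peak_names",
                    lambda s: ";".join(sorted({n for row in s for n in row.split(";") if n})),
                ),
            )
            .sort_values(["gene_id", "transcript_id"], kind="mergesort")
            .reset_index(drop=True)
        )
    else:
        df = pd.DataFrame(
            columns=["gene_id", "transcript_id", "attributes", "overlap_bp", "peak_names"]
        )
    if table is not None:
        df = table.join(df)
    return profile, df


def annotate_gene_set(
    ps: PeakSet,
    ga: GenomeAnnotation,
    kinds: Sequence[str],
    crit: OverlapCriterion,
    params: AttributeParams,
) -> set[str]:
    """The set of gene IDs hit by one track (a gene counts once across isoforms)."""
    _, df = annotate_peaks(ps, ga, kinds, crit, params)
    return set(df["gene_id"]) if len(df) else set()


def integrate_peaks(
    spec: Sequence[tuple[PeakSet, str, OverlapCriterion]],
    ga: GenomeAnnotation,
    params: AttributeParams,
    table: Optional[AnnotationTable] = None,
) -> pd.DataFrame:
    """Genes meeting the overlap criterion in every provided track.

    Each track carries its own target attribute and criterion. Intersection
    is at gene level; per-track overlap details are reported side by side.
    """
    if not 2 <= len(spec) <= MAX_TRACKS:
        raise ValueError(f"peak integration takes 2 to {MAX_TRACKS} tracks, got {len(spec)}")
    per_track: list[pd.DataFrame] = []
    labels: list[str] = []
    for i, (ps, kind, crit) in enumerate(spec):
        _, df = annotate_peaks(ps, ga, [kind], crit, params)
        label = ps.label or f"track{i + 1}"
        if label in labels:
            label = f"{label}_{i + 1}"
        labels.append(label)
        per_gene = (
            df.groupby("gene_id")["overlap_bp"].max().rename(f"{label}_overlap_bp")
            if len(df)
            else pd.Series(name=f"{label}_overlap_bp", dtype=int)
        )
        per_track.append(per_gene.to_frame())
    common: Optional[set[str]] = None
    for t in per_track:
        genes = set(t.index)
        common = genes if common is None else (common & genes)
    common_sorted = sorted(common or set())
    out = pd.DataFrame({"gene_id": common_sorted})
    for t in per_track:
        col = t.columns[0]
        out[col] = t[col].reindex(common_sorted).to_numpy()
    if table is not None:
        out = table.join(out)
    return out
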