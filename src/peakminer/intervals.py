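"""Interval arithmetic: peak sets, merging, coverage and gene-hit retrieval.

The coverage of a peak set over a gene-feature attribute is reported as
covered base pairs / total attribute length, with overlapping peaks merged
first so that the fraction is a true proportion in [0, 1]. Gene-hit
retrieval applies a minimum-overlap criterion, expressed either as absolute
base pairs or as a percentage of the peak's length.
"""

from __future__ import annotations

import json
import logging
import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_model import (
    ATTRIBUTE_KINDS,
    AttributeParams,
    GenomeAnnotation,
    iter_attribute_regions,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name or ''} has start >= end ({self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """A named, (chrom, start)-sorted collection of peaks."""

    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def chromosomes(self) -> set[str]:
        return {p.chrom for p in self.peaks}

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


@dataclass(frozen=True)
class OverlapCriterion:
    """Minimum peak/attribute overlap: 'bp' (absolute) or 'percent' of peak length."""

    mode: str
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("bp", "percent"):
            raise ValueError(f"overlap mode must be 'bp' or 'percent', got {self.mode!r}")
        if self.value <= 0:
            raise ValueError("overlap value must be positive")
        if self.mode == "percent" and self.value > 100:
            raise ValueError("percent overlap must be in (0, 100]")

    def required_bp(self, peak_length: int) -> float:
        if self.mode == "bp":
            return self.value
        return self.value / 100.0 * peak_length


@dataclass(frozen=True)
class CoverageEntry:
    covered_bp: int
    total_bp: int

    @property
    def fraction(self) -> float:
        return self.covered_bp / self.total_bp if self.total_bp else 0.0


@dataclass(frozen=True)
class GeneHit:
    gene_id: str
    transcript_id: str
    kind: str
    overlap_bp: int
    peak_names: tuple[str, ...]


# ---------------------------------------------------------------------------
# primitive interval ops
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open intervals into a sorted, disjoint, union-preserving set.

    Adjacent intervals (end == next start) merge, since their union is one
    contiguous run of bases.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two half-open intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


class _MergedCover:
    """Merged intervals of one chromosome with O(log n) overlap queries."""

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        merged = merge_intervals(intervals)
        self.starts = [s for s, _ in merged]
        self.ends = [e for _, e in merged]
        self.cum = [0]
        for s, e in merged:
            self.cum.append(self.cum[-1] + (e - s))

    def covered_in(self, start: int, end: int) -> int:
        """Total covered bases within [start, end)."""
        if not self.starts or end <= start:
            return 0
        lo = bisect_right(self.ends, start)
        hi = bisect_left(self.starts, end)
        if lo >= hi:
            return 0
        total = self.cum[hi] - self.cum[lo]
        total -= max(0, start - self.starts[lo])
        total -= max(0, self.ends[hi - 1] - end)
        return total


# ---------------------------------------------------------------------------
# coverage and gene hits
# ---------------------------------------------------------------------------

def coverage_profile(
    ps: PeakSet,
    ga: GenomeAnnotation,
    p: AttributeParams,
) -> dict[str, CoverageEntry]:
    """Cumulative coverage of a peak set over each gene-feature attribute.

    For each attribute kind, covered_bp sums the merged-peak overlap over
    all attribute regions (one region per selected isoform) and total_bp
    sums the region lengths.
    """
    ga_chroms = ga.chromosomes()
    ps_chroms = ps.chromosomes()
    if ps.peaks and ga_chroms and not (ga_chroms & ps_chroms):
        logger.warning(
            "peak set %r and annotation share no chromosomes (%s vs %s); "
            "coverage is all-zero",
            ps.label, sorted(ps_chroms), sorted(ga_chroms),
        )
    covers = {
        chrom: _MergedCover((pk.start, pk.end) for pk in pks)
        for chrom, pks in ps.by_chrom().items()
    }
    covered = {k: 0 for k in ATTRIBUTE_KINDS}
    total = {k: 0 for k in ATTRIBUTE_KINDS}
    for r in iter_attribute_regions(ga, p):
        total[r.kind] += r.length
        cover = covers.get(r.chrom)
        if cover is not None:
            covered[r.kind] += cover.covered_in(r.start, r.end)
    return {k: CoverageEntry(covered[k], total[k]) for k in ATTRIBUTE_KINDS}


def _peak_trees(ps: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, pks in ps.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples(
            (pk.start, pk.end, i) for i, pk in enumerate(pks)
        )
    return trees


def find_gene_hits(
    ps: PeakSet,
    ga: GenomeAnnotation,
    kind: str,
    crit: OverlapCriterion,
    p: AttributeParams,
) -> list[GeneHit]:
    """Genes whose selected attribute region meets the overlap criterion.

    A gene is hit iff some single peak overlaps its attribute region by at
    least crit.value bp (mode='bp') or by at least crit.value percent of the
    peak's own length (mode='percent'). One hit per (gene, transcript) under
    the isoform mode; overlap_bp reports the largest qualifying overlap.
    """
    if kind not in ATTRIBUTE_KINDS:
        raise ValueError(f"unknown attribute kind {kind!r}")
    by_chrom = ps.by_chrom()
    trees = _peak_trees(ps)
    hits: list[GeneHit] = []
    for r in iter_attribute_regions(ga, p, kinds=[kind]):
        if r.length == 0:
            continue
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        pks = by_chrom[r.chrom]
        best = 0
        names: list[str] = []
        for iv in sorted(tree.overlap(r.start, r.end), key=lambda iv: iv.data):
            pk = pks[iv.data]
            ov = overlap_bp((pk.start, pk.end), (r.start, r.end))
            if ov >= crit.required_bp(pk.length) and ov >= 1:
                best = max(best, ov)
                names.append(pk.name or f"{pk.chrom}:{pk.start}-{pk.end}")
        if best > 0:
            hits.append(GeneHit(r.gene_id, r.transcript_id, kind, best, tuple(names)))
    hits.sort(key=lambda h: (h.gene_id, h.transcript_id))
    return hits


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_peaks(path: str, label: Optional[str] = None) -> PeakSet:
    """Read BED3/BED6/narrowPeak. narrowPeak columns 7-10 are tolerated but
    only coordinates, name, score and strand are kept. Records on any
    chromosome are accepted; filtering against an annotation happens later.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            name = f[3] if len(f) > 3 and f[3] not in (".", "") else None
            score: Optional[float] = None
            if len(f) > 4 and f[4] not in (".", ""):
                try:
                    score = float(f[4])
                except ValueError:
                    score = None
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else None
            peaks.append(Peak(f[0], start, end, name=name, score=score, strand=strand))
    return PeakSet(label=label or os.path.splitext(os.path.basename(path))[0], peaks=peaks)


def drop_unknown_chroms(ps: PeakSet, ga: GenomeAnnotation) -> PeakSet:
    """Drop peaks on chromosomes absent from the annotation, logging a count."""
    known = ga.chromosomes()
    kept = [p for p in ps.peaks if p.chrom in known]
    n_dropped = len(ps.peaks) - len(kept)
    if n_dropped:
        logger.info("peak set %r: ignored %d peak(s) on unknown chromosomes", ps.label, n_dropped)
    return PeakSet(label=ps.label, peaks=kept)


def gene_hits_frame(hits: Sequence[GeneHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "transcript_id": h.transcript_id,
                "attribute": h.kind,
                "overlap_bp": h.overlap_bp,
                "peak_names": ";".join(h.peak_names),
            }
            for h in hits
        ],
        columns=["gene_id", "transcript_id", "attribute", "overlap_bp", "peak_names"],
    )


def write_coverage_json(profile: dict[str, CoverageEntry], path: str) -> None:
    payload = {
        k: {"covered_bp": v.covered_bp, "total_bp": v.total_bp, "fraction": v.fraction}
        for k, v in profile.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
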