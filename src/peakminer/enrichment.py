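"""TF / histone-mark over-representation analysis on gene lists.

Against a local store of ChIP-seq peak datasets, each dataset's *target
genes* are the genes whose promoter window overlaps one of its peaks. For a
submitted gene list the 2x2 contingency counts (listHits, listSize,
genomeHits, genomeSize) feed a one-tailed hypergeometric test, a
Benjamini-Hochberg correction across all datasets, an enrichment score

    score = (listHits / listSize) / (genomeHits / genomeSize)

and the ranking statistic

    combined score = score * -log10(p).

Promoter windows are either fixed (default 2000 bp upstream / 500 bp
downstream of the TSS; histone marks always use fixed windows) or
*dynamic*: per-dataset upstream boundaries estimated from the dataset's own
peak-to-TSS distance histogram. The dynamic estimator bins upstream
peak-midpoint-to-nearest-TSS distances at 50 bp resolution over [0, 20 kb),
sets a noise floor at median + 3*std of the 5-20 kb bins, smooths the
histogram with a 3-bin simple moving average and reports the first distance
at which the smoothed curve drops below the noise floor.
"""

from __future__ import annotations

import glob
import json
import logging
import math
import os
import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import AttributeParams, GenomeAnnotation, select_isoforms
from .intervals import OverlapCriterion, PeakSet, load_peaks, overlap_bp
from .peak_tools import _norm_id

logger = logging.getLogger(__name__)

BIN_WIDTH = 50
MAX_DISTANCE = 20_000
N_BINS = MAX_DISTANCE // BIN_WIDTH  # 400
NOISE_WINDOW_START = 5_000
SMA_WINDOW = 3
FALLBACK_UPSTREAM = 2_000
DYNAMIC_DOWNSTREAM_DEFAULT = 50


@dataclass
class TFDataset:
    """One stored ChIP-seq experiment: peaks plus free-text metadata."""

    dataset_id: str
    factor_name: str
    peakset: PeakSet
    metadata: str = ""


@dataclass(frozen=True)
class PromoterSpec:
    """Promoter window definition for target calling.

    mode='fixed' uses upstream_bp/downstream_bp for every dataset;
    mode='dynamic' uses each dataset's estimated upstream boundary with a
    common downstream margin (default 50 bp).
    """

    mode: str = "fixed"
    upstream_bp: int = 2_000
    downstream_bp: int = 500

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "dynamic"):
            raise ValueError(f"promoter mode must be 'fixed' or 'dynamic', got {self.mode!r}")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("promoter margins must be non-negative")

    @classmethod
    def dynamic(cls, downstream_bp: int = DYNAMIC_DOWNSTREAM_DEFAULT) -> "PromoterSpec":
        return cls(mode="dynamic", upstream_bp=0, downstream_bp=downstream_bp)


@dataclass(frozen=True)
class DynamicRange:
    """Per-dataset peak-to-TSS distance histogram and derived upstream boundary."""

    dataset_id: str
    histogram: tuple[int, ...]  # counts per 50 bp bin over [0, 20000)
    noise_level: float
    sma: tuple[float, ...]
    upstream_tss: int
    bin_width: int = BIN_WIDTH

    def __post_init__(self) -> None:
        if len(self.histogram) != N_BINS or len(self.sma) != N_BINS:
            raise ValueError(f"histogram and sma must have {N_BINS} bins")
        if not (0 < self.upstream_tss <= MAX_DISTANCE) or self.upstream_tss % self.bin_width:
            raise ValueError("upstream_tss must be a positive multiple of the bin width <= 20000")


@dataclass(frozen=True)
class EnrichmentRecord:
    dataset_id: str
    factor_name: str
    metadata: str
    list_hits: int
    list_size: int
    genome_hits: int
    genome_size: int
    p_value: float
    fdr: float
    score: Optional[float]
    combined_score: Optional[float]
    target_genes: tuple[str, ...]


@dataclass
class IDMapping:
    """Deterministic source->target gene-ID mapping with a drop report."""

    mapping: dict[str, str]

    @classmethod
    def load(cls, path: str) -> "IDMapping":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("ID mapping must have two tab-separated columns")
        mapping: dict[str, str] = {}
        for src, dst in zip(df.iloc[:, 0], df.iloc[:, 1]):
            key = _norm_id(src)
            if key in mapping and mapping[key] != str(dst).strip():
                logger.warning("duplicate mapping for %r; keeping first occurrence", src)
                continue
            mapping.setdefault(key, str(dst).strip())
        return cls(mapping=mapping)

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "IDMapping":
        return cls({_norm_id(i): str(i).strip() for i in ids})


def convert_ids(ids: Sequence[str], mapping: IDMapping) -> tuple[list[str], list[str]]:
    """Map IDs through the table, order-preserving.

    Unmapped IDs are dropped and reported; duplicates after mapping collapse
    to their first occurrence (with a warning).
    """
    converted: list[str] = []
    dropped: list[str] = []
    seen: set[str] = set()
    for raw in ids:
        target = mapping.mapping.get(_norm_id(raw))
        if target is None:
            dropped.append(str(raw))
            continue
        key = _norm_id(target)
        if key in seen:
            logger.warning("IDs collapse to duplicate target %r after conversion", target)
            continue
        seen.add(key)
        converted.append(target)
    return converted, dropped


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def hypergeom_p(list_hits: int, list_size: int, genome_hits: int, genome_size: int) -> float:
    """One-tailed (over-representation) hypergeometric p-value: P(X >= listHits).

    X counts dataset targets in a random draw of list_size genes from a
    genome_size background containing genome_hits targets.
    """
    if not (
        0 <= list_hits <= min(list_size, genome_hits)
        and genome_hits <= genome_size
        and 0 <= list_size <= genome_size
    ):
        raise ValueError(
            f"inconsistent contingency counts: listHits={list_hits}, listSize={list_size}, "
            f"genomeHits={genome_hits}, genomeSize={genome_size}"
        )
    return float(stats.hypergeom.sf(list_hits - 1, genome_size, genome_hits, list_size))


def enrichment_score(
    list_hits: int, list_size: int, genome_hits: int, genome_size: int
) -> Optional[float]:
    """(listHits/listSize) / (genomeHits/genomeSize); None when undefined."""
    if list_size == 0 or genome_hits == 0 or genome_size == 0:
        return None
    return (list_hits / list_size) / (genome_hits / genome_size)


def combined_score(score: Optional[float], p_value: float) -> Optional[float]:
    """score * -log10(p); exact-zero p-values are floored at the smallest float."""
    if score is None:
        return None
    p = p_value
    if p <= 0.0:
        logger.warning("p-value of 0 floored at %.3g for combined score", sys.float_info.min)
        p = sys.float_info.min
    return score * -math.log10(p)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# target calling
# ---------------------------------------------------------------------------

def _promoter_window(tss: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    if strand == "+":
        return max(0, tss - upstream), tss + downstream
    return max(0, tss - downstream), tss + upstream


def _gene_tss_table(ga: GenomeAnnotation, params: AttributeParams) -> list[tuple[str, str, int, str]]:
    """(gene_id, chrom, tss, strand) per selected isoform."""
    rows = []
    for gid in ga.gene_ids():
        for t in select_isoforms(ga.genes[gid], params.isoform_mode):
            strand = t.effective_strand(params.respect_strand)
            rows.append((gid, t.chrom, t.tss(params.respect_strand), strand))
    return rows


def build_target_set(
    d: TFDataset,
    ga: GenomeAnnotation,
    spec: PromoterSpec,
    crit: OverlapCriterion,
    params: AttributeParams,
    dynamic: Optional[DynamicRange] = None,
) -> set[str]:
    """Genes whose promoter window overlaps a dataset peak by the criterion."""
    if spec.mode == "dynamic":
        if dynamic is None:
            raise ValueError(
                f"dataset {d.dataset_id}: dynamic promoter mode requires a computed DynamicRange"
            )
        upstream = dynamic.upstream_tss
    else:
        upstream = spec.upstream_bp
    downstream = spec.downstream_bp
    by_chrom = d.peakset.by_chrom()
    # sorted arrays per chromosome for a windowed scan
    arr = {
        c: (np.array([p.start for p in pks]), np.array([p.end for p in pks]), pks)
        for c, pks in by_chrom.items()
    }
    targets: set[str] = set()
    for gid, chrom, tss, strand in _gene_tss_table(ga, params):
        if gid in targets or chrom not in arr:
            continue
        ws, we = _promoter_window(tss, strand, upstream, downstream)
        starts, ends, pks = arr[chrom]
        cand = np.nonzero((starts < we) & (ends > ws))[0]
        for i in cand:
            pk = pks[i]
            ov = overlap_bp((pk.start, pk.end), (ws, we))
            if ov >= crit.required_bp(pk.length) and ov >= 1:
                targets.add(gid)
                break
    return targets


def compute_dynamic_range(d: TFDataset, ga: GenomeAnnotation,
                          params: Optional[AttributeParams] = None) -> DynamicRange:
    """Estimate a dataset-specific upstream promoter boundary.

    Each peak contributes one count: the distance from its midpoint to the
    nearest TSS it lies upstream of, provided that distance falls in
    [0, 20000). Bin counts (50 bp bins) whose distances span 5-20 kb define
    the noise floor (median + 3 * population std); a 3-bin moving average
    (truncated at the edges) smooths the histogram, and the boundary is the
    left edge of the first bin, scanning outward from the TSS, where the
    smoothed curve falls below the noise floor. No crossing -> 20000 bp; a
    crossing at bin 0 or an empty histogram falls back to 2000 bp.
    """
    params = params or AttributeParams()
    tss_rows = _gene_tss_table(ga, params)
    if not tss_rows:
        raise ValueError("cannot compute a dynamic range against an empty annotation")
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r[1] for r in tss_rows}:
        plus = np.array(sorted(t for g, c, t, s in tss_rows if c == chrom and s == "+"))
        minus = np.array(sorted(t for g, c, t, s in tss_rows if c == chrom and s == "-"))
        tss_by_chrom[chrom] = (plus, minus)

    counts = np.zeros(N_BINS, dtype=int)
    for pk in d.peakset.peaks:
        entry = tss_by_chrom.get(pk.chrom)
        if entry is None:
            continue
        mid = (pk.start + pk.end) // 2
        best = None
        plus, minus = entry
        if plus.size:  # upstream of a '+' TSS: mid <= tss, distance tss - mid
            i = np.searchsorted(plus, mid, side="left")
            if i < plus.size:
                best = plus[i] - mid
        if minus.size:  # upstream of a '-' TSS: mid >= tss, distance mid - tss
            i = np.searchsorted(minus, mid, side="right")
            if i > 0:
                dist = mid - minus[i - 1]
                if best is None or dist < best:
                    best = dist
        if best is not None and 0 <= best < MAX_DISTANCE:
            counts[int(best) // BIN_WIDTH] += 1

    noise_bins = counts[NOISE_WINDOW_START // BIN_WIDTH:]
    noise = float(np.median(noise_bins) + 3.0 * np.std(noise_bins))
    sma = np.array(
        [counts[max(0, i - 1): i + 2].mean() for i in range(N_BINS)]
    )
    upstream = None
    if counts.sum() > 0:
        below = np.nonzero(sma < noise)[0]
        if below.size == 0:
            upstream = MAX_DISTANCE
        elif below[0] == 0:
            upstream = None  # immediate crossing: no enrichment shoulder
        else:
            upstream = int(below[0]) * BIN_WIDTH
    if upstream is None or upstream == 0:
        upstream = FALLBACK_UPSTREAM
    return DynamicRange(
        dataset_id=d.dataset_id,
        histogram=tuple(int(c) for c in counts),
        noise_level=noise,
        sma=tuple(float(x) for x in sma),
        upstream_tss=upstream,
    )


def compute_all_dynamic_ranges(
    store: Sequence[TFDataset], ga: GenomeAnnotation, params: Optional[AttributeParams] = None
) -> dict[str, DynamicRange]:
    return {d.dataset_id: compute_dynamic_range(d, ga, params) for d in store}


# ---------------------------------------------------------------------------
# enrichment of a gene list
# ---------------------------------------------------------------------------

def enrich_gene_list(
    genes: Sequence[str],
    store: Sequence[TFDataset],
    ga: GenomeAnnotation,
    spec: PromoterSpec,
    crit: OverlapCriterion,
    params: Optional[AttributeParams] = None,
    mapping: Optional[IDMapping] = None,
    dynamic_ranges: Optional[Mapping[str, DynamicRange]] = None,
    target_sets: Optional[Mapping[str, set[str]]] = None,
) -> list[EnrichmentRecord]:
    """Rank every stored dataset by over-representation in a gene list.

    The background is the full gene complement of the annotation under the
    chosen isoform mode. FDR is a single BH family across all datasets;
    records are sorted by combined score (descending), ties by p-value then
    dataset id. ``target_sets`` short-circuits target calling when the same
    store is queried repeatedly.
    """
    if not store:
        raise ValueError("the dataset store is empty")
    params = params or AttributeParams()
    if mapping is not None:
        genes, dropped = convert_ids(genes, mapping)
        if not genes:
            raise ValueError(
                f"all gene IDs were dropped by ID conversion ({len(dropped)} unmapped)"
            )
    background = set(ga.gene_ids())
    genome_size = len(background)
    norm_to_bg = {_norm_id(g): g for g in background}
    query = {norm_to_bg[_norm_id(g)] for g in genes if _norm_id(g) in norm_to_bg}
    n_outside = len({_norm_id(g) for g in genes}) - len(query)
    if n_outside:
        logger.info("%d submitted gene ID(s) not in the background and ignored", n_outside)
    if not query:
        raise ValueError("no submitted gene ID matches the annotation background")
    list_size = len(query)

    raw: list[dict] = []
    for d in sorted(store, key=lambda x: x.dataset_id):
        if target_sets is not None and d.dataset_id in target_sets:
            targets = set(target_sets[d.dataset_id]) & background
        else:
            dyn = (dynamic_ranges or {}).get(d.dataset_id)
            targets = build_target_set(d, ga, spec, crit, params, dynamic=dyn) & background
        hits = sorted(query & targets)
        p = hypergeom_p(len(hits), list_size, len(targets), genome_size)
        score = enrichment_score(len(hits), list_size, len(targets), genome_size)
        raw.append(
            {
                "d": d,
                "hits": hits,
                "targets": len(targets),
                "p": p,
                "score": score,
                "combined": combined_score(score, p),
            }
        )
    fdrs = bh_adjust([r["p"] for r in raw])
    records = [
        EnrichmentRecord(
            dataset_id=r["d"].dataset_id,
            factor_name=r["d"].factor_name,
            metadata=r["d"].metadata,
            list_hits=len(r["hits"]),
            list_size=list_size,
            genome_hits=r["targets"],
            genome_size=genome_size,
            p_value=r["p"],
            fdr=f,
            score=r["score"],
            combined_score=r["combined"],
            target_genes=tuple(r["hits"]),
        )
        for r, f in zip(raw, fdrs)
    ]
    records.sort(
        key=lambda rec: (
            -(rec.combined_score if rec.combined_score is not None else -math.inf),
            rec.p_value,
            rec.dataset_id,
        )
    )
    return records


def records_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id,
                "factor": r.factor_name,
                "metadata": r.metadata,
                "listHits": r.list_hits,
                "listSize": r.list_size,
                "genomeHits": r.genome_hits,
                "genomeSize": r.genome_size,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "score": r.score,
                "combined_score": r.combined_score,
                "target_genes": ";".join(r.target_genes),
            }
            for r in records
        ],
        columns=[
            "dataset_id", "factor", "metadata", "listHits", "listSize",
            "genomeHits", "genomeSize", "p_value", "fdr", "score",
            "combined_score", "target_genes",
        ],
    )


# ---------------------------------------------------------------------------
# dataset store I/O
# ---------------------------------------------------------------------------

def load_store(directory: str, metadata_name: str = "metadata.tsv") -> list[TFDataset]:
    """Load a dataset store: a directory of BED/narrowPeak files plus a
    metadata sheet with columns dataset_id, factor and optional free-text
    metadata / file columns. Without a 'file' column, peaks are looked up as
    <dataset_id>.<bed|narrowPeak> in the directory.
    """
    meta_path = os.path.join(directory, metadata_name)
    if not os.path.exists(meta_path):
        raise FileNotFoundError(meta_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    required = {"dataset_id", "factor"}
    if not required <= set(meta.columns):
        raise ValueError(f"store metadata must have columns {sorted(required)}")
    if meta["dataset_id"].duplicated().any():
        raise ValueError("store metadata has duplicate dataset_id values")
    datasets: list[TFDataset] = []
    for _, row in meta.iterrows():
        if "file" in meta.columns and row["file"]:
            path = os.path.join(directory, row["file"])
        else:
            cands = sorted(
                glob.glob(os.path.join(directory, f"{row['dataset_id']}.bed"))
                + glob.glob(os.path.join(directory, f"{row['dataset_id']}.narrowPeak"))
            )
            if not cands:
                raise FileNotFoundError(
                    f"no peak file for dataset {row['dataset_id']} in {directory}"
                )
            path = cands[0]
        extra = [c for c in meta.columns if c not in ("dataset_id", "factor", "file")]
        metadata = "; ".join(f"{c}={row[c]}" for c in extra if row[c])
        datasets.append(
            TFDataset(
                dataset_id=row["dataset_id"],
                factor_name=row["factor"],
                peakset=load_peaks(path, label=row["dataset_id"]),
                metadata=metadata,
            )
        )
    return datasets


def write_dynamic_range_json(dr: DynamicRange, path: str) -> None:
    payload = {
        "dataset_id": dr.dataset_id,
        "bin_width": dr.bin_width,
        "histogram": list(dr.histogram),
        "noise_level": dr.noise_level,
        "sma": list(dr.sma),
        "upstream_tss": dr.upstream_tss,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_gene_list(path: str) -> list[str]:
    """Plain text, one gene ID per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out
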