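"""Deterministic synthetic fixtures with known ground truth.

Generates, from one seed: a toy annotated genome (non-overlapping coding
genes on alternating strands, with UTRs, introns and exons), a store of TF
ChIP-seq-like peak datasets in which one *planted* regulator binds the
promoters of a recorded target-gene subset while decoys carry only
background peaks, differential-expression tables, and suites of
perturbation experiments for benchmarking the enrichment ranking.

Default scale is one 1 Mb chromosome with 100 genes and 20 decoy datasets:
small enough for seconds-scale tests, large enough for stable statistics.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .benchmark import PerturbationExperiment
from .enrichment import TFDataset
from .genome_model import GenomeAnnotation, TranscriptModel, write_bed12
from .intervals import Peak, PeakSet
from .peak_tools import AnnotationTable

CHROM = "chr1"


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study system."""

    seed: int = 0
    n_genes: int = 100
    chrom_len: int = 1_000_000
    n_decoy_tfs: int = 20
    planted_tf_name: str = "TF_PLANTED"
    planted_target_fraction: float = 0.3
    promoter_boundary_bp: int = 2_000
    noise_peak_rate: float = 20.0  # expected background peaks per dataset
    de_fraction: float = 0.2
    strand_mode: str = "alternate"  # 'alternate' or 'plus' (single-strand genome)

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.chrom_len <= 0 or self.n_decoy_tfs < 0:
            raise ValueError("counts must be non-negative (chrom_len positive)")
        if not (0 < self.planted_target_fraction <= 1):
            raise ValueError("planted_target_fraction must be in (0, 1]")
        if not (0 < self.de_fraction <= 1):
            raise ValueError("de_fraction must be in (0, 1]")
        if self.promoter_boundary_bp <= 0 or self.noise_peak_rate < 0:
            raise ValueError("promoter_boundary_bp must be positive, noise_peak_rate >= 0")
        if self.strand_mode not in ("alternate", "plus"):
            raise ValueError("strand_mode must be 'alternate' or 'plus'")


def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), salt]))


GENE_SLOT_MIN = 10_000  # bp of chromosome reserved per gene


def synth_genome(spec: FixtureSpec) -> GenomeAnnotation:
    """A toy genome: one chromosome, evenly slotted non-overlapping genes.

    Each gene gets one coding transcript (5'UTR / multi-exon CDS / 3'UTR)
    placed inside its slot with generous margins so promoter and flank
    regions rarely collide with neighbours. Strands alternate.
    """
    if spec.n_genes and spec.chrom_len < spec.n_genes * GENE_SLOT_MIN:
        raise ValueError(
            f"cannot pack {spec.n_genes} genes into {spec.chrom_len} bp "
            f"(needs >= {GENE_SLOT_MIN} bp per gene)"
        )
    rng = _rng(spec, 1)
    genes: dict[str, list[TranscriptModel]] = {}
    if spec.n_genes:
        slot = spec.chrom_len // spec.n_genes
        width = len(str(spec.n_genes))
        for i in range(spec.n_genes):
            slot_start = i * slot
            margin = 3_000  # room for promoters/flanks inside the slot
            tx_len = int(rng.integers(2_000, min(6_000, slot - 2 * margin)))
            lo = slot_start + margin
            hi = slot_start + slot - margin - tx_len
            tx_start = int(rng.integers(lo, max(lo + 1, hi)))
            tx_end = tx_start + tx_len
            strand = "+" if (spec.strand_mode == "plus" or i % 2 == 0) else "-"
            utr5 = int(rng.integers(100, 400))
            utr3 = int(rng.integers(100, 400))
            cds_start = tx_start + utr5
            cds_end = tx_end - utr3
            if strand == "-":
                cds_start = tx_start + utr3
                cds_end = tx_end - utr5
            n_exons = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(np.arange(1, tx_len), size=2 * (n_exons - 1), replace=False)) if n_exons > 1 else np.array([], dtype=int)
            bounds = [tx_start] + [tx_start + int(c) for c in cuts] + [tx_end]
            exons = tuple(
                (bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)
            )
            gid = f"gene{i:0{width}d}"
            tid = f"{gid}.t1"
            genes[gid] = [
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    gene_name=gid.upper(),
                    chrom=CHROM,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=exons,
                )
            ]
    ga = GenomeAnnotation(
        genes=genes,
        chrom_sizes={CHROM: spec.chrom_len},
        source_label=f"synthetic(seed={spec.seed})",
    )
    ga.validate()
    return ga


def _tss_strand(ga: GenomeAnnotation, gid: str) -> tuple[int, str]:
    t = ga.genes[gid][0]
    return t.tss(), t.strand


def _background_peaks(rng: np.random.Generator, spec: FixtureSpec) -> list[Peak]:
    n = int(rng.poisson(spec.noise_peak_rate))
    peaks = []
    for j in range(n):
        width = int(rng.integers(150, 400))
        start = int(rng.integers(0, max(1, spec.chrom_len - width)))
        peaks.append(Peak(CHROM, start, start + width, name=f"bg{j}"))
    return peaks


def _promoter_peak(
    rng: np.random.Generator, tss: int, strand: str, boundary: int, chrom_len: int, name: str
) -> Peak:
    # midpoint uniform within (0, boundary) bp upstream of the TSS
    d = int(rng.integers(1, boundary))
    mid = tss - d if strand == "+" else tss + d
    width = int(rng.integers(150, 400))
    start = max(0, min(mid - width // 2, chrom_len - width))
    return Peak(CHROM, start, start + width, name=name)


def synth_tf_store(
    spec: FixtureSpec, ga: GenomeAnnotation
) -> tuple[list[TFDataset], dict[str, list[str]]]:
    """A planted regulator plus background-only decoys.

    The planted dataset carries one promoter-proximal peak (midpoint within
    ``promoter_boundary_bp`` upstream of the TSS) for each gene of a seeded
    target subset, on top of Poisson background peaks; decoy datasets carry
    background peaks only. Returns the datasets and the ground-truth target
    lists per dataset id.
    """
    if not ga.genes:
        raise ValueError("cannot build a store against an empty annotation")
    rng = _rng(spec, 2)
    gene_ids = ga.gene_ids()
    n_targets = max(1, round(spec.planted_target_fraction * len(gene_ids)))
    targets = sorted(rng.choice(gene_ids, size=n_targets, replace=False).tolist())

    datasets: list[TFDataset] = []
    truth: dict[str, list[str]] = {}

    planted_id = "ds_planted"
    peaks = []
    for k, gid in enumerate(targets):
        tss, strand = _tss_strand(ga, gid)
        peaks.append(
            _promoter_peak(rng, tss, strand, spec.promoter_boundary_bp, spec.chrom_len, f"tgt{k}")
        )
    peaks.extend(_background_peaks(rng, spec))
    datasets.append(
        TFDataset(
            dataset_id=planted_id,
            factor_name=spec.planted_tf_name,
            peakset=PeakSet(label=planted_id, peaks=peaks),
            metadata="planted regulator",
        )
    )
    truth[planted_id] = targets

    width = len(str(max(1, spec.n_decoy_tfs)))
    for i in range(spec.n_decoy_tfs):
        ds_id = f"ds_decoy{i:0{width}d}"
        datasets.append(
            TFDataset(
                dataset_id=ds_id,
                factor_name=f"TF_DECOY{i:0{width}d}",
                peakset=PeakSet(label=ds_id, peaks=_background_peaks(rng, spec)),
                metadata="background-only decoy",
            )
        )
        truth[ds_id] = []
    return datasets, truth


def synth_boundary_dataset(
    spec: FixtureSpec,
    ga: GenomeAnnotation,
    boundary_bp: int,
    peaks_per_gene: int = 5,
    background_peaks: int = 0,
) -> TFDataset:
    """A dataset whose binding density drops sharply at a known distance.

    Places ``peaks_per_gene`` promoter peaks per gene with midpoints uniform
    within ``boundary_bp`` upstream of the TSS, plus uniformly scattered
    background peaks, for exercising the boundary estimator.
    """
    rng = _rng(spec, 3)
    peaks: list[Peak] = []
    k = 0
    for gid in ga.gene_ids():
        tss, strand = _tss_strand(ga, gid)
        for _ in range(peaks_per_gene):
            peaks.append(
                _promoter_peak(rng, tss, strand, boundary_bp, spec.chrom_len, f"sig{k}")
            )
            k += 1
    for j in range(background_peaks):
        width = int(rng.integers(150, 400))
        start = int(rng.integers(0, max(1, spec.chrom_len - width)))
        peaks.append(Peak(CHROM, start, start + width, name=f"noise{j}"))
    return TFDataset(
        dataset_id=f"ds_boundary{boundary_bp}",
        factor_name="TF_BOUNDARY",
        peakset=PeakSet(label=f"ds_boundary{boundary_bp}", peaks=peaks),
        metadata=f"planted boundary {boundary_bp} bp",
    )


def synth_de_table(
    ga: GenomeAnnotation,
    spec: FixtureSpec,
    de_genes: Optional[Sequence[str]] = None,
) -> tuple[AnnotationTable, list[str]]:
    """A DE table over a seeded (or caller-chosen) gene subset.

    Columns: gene_id, log2FC (signed, ~N(0, 2) away from zero), FDR.
    Returns the table and the identity of the deregulated subset.
    """
    rng = _rng(spec, 4)
    gene_ids = ga.gene_ids()
    if de_genes is None:
        n = max(1, round(spec.de_fraction * len(gene_ids)))
        de_genes = sorted(rng.choice(gene_ids, size=n, replace=False).tolist())
    else:
        de_genes = sorted(de_genes)
    lfc = rng.normal(0.0, 2.0, size=len(de_genes))
    lfc = np.where(np.abs(lfc) < 0.25, np.sign(lfc + 1e-9) * 0.25, lfc)  # keep a clear sign
    fdr = rng.uniform(1e-8, 0.05, size=len(de_genes))
    df = pd.DataFrame(
        {"gene_id": list(de_genes), "log2FC": np.round(lfc, 4), "FDR": np.round(fdr, 8)}
    )
    return AnnotationTable.from_frame(df), list(de_genes)


def synth_perturbation_suite(
    store: Sequence[TFDataset],
    truth: dict[str, list[str]],
    ga: GenomeAnnotation,
    spec: FixtureSpec,
    n_experiments: int = 75,
    signature_size: int = 50,
    target_fraction: float = 1.0,
) -> list[PerturbationExperiment]:
    """Perturbation experiments for TFs with planted targets.

    Each experiment perturbs a TF that has recorded targets in the store and
    draws its signature as ``target_fraction`` planted targets topped up
    with seeded random genes (target_fraction=0 gives pure-random null
    signatures).
    """
    rng = _rng(spec, 5)
    gene_ids = ga.gene_ids()
    perturbable = [d for d in store if truth.get(d.dataset_id)]
    if not perturbable and target_fraction > 0:
        raise ValueError("no stored dataset has planted targets to perturb")
    factors = sorted({d.factor_name for d in (perturbable or store)})
    exps: list[PerturbationExperiment] = []
    for i in range(n_experiments):
        tf = factors[i % len(factors)]
        planted = sorted(
            {g for d in store if d.factor_name == tf for g in truth.get(d.dataset_id, [])}
        )
        n_from_targets = min(len(planted), int(round(target_fraction * signature_size)))
        sig = (
            rng.choice(planted, size=n_from_targets, replace=False).tolist()
            if n_from_targets
            else []
        )
        remaining = [g for g in gene_ids if g not in set(sig)]
        n_fill = min(len(remaining), signature_size - len(sig))
        if n_fill > 0:
            sig += rng.choice(remaining, size=n_fill, replace=False).tolist()
        exps.append(
            PerturbationExperiment(
                experiment_id=f"exp{i:03d}",
                perturbed_tf=tf,
                signature_gene_set=tuple(sorted(sig)),
            )
        )
    return exps


def synth_null_ranks(
    n_experiments: int, n_datasets: int, seed: int
) -> list[tuple[int, int]]:
    """Ranks of a TF that carries no signal: uniform on 1..n_datasets."""
    rng = np.random.default_rng(seed)
    return [(int(r), n_datasets) for r in rng.integers(1, n_datasets + 1, size=n_experiments)]


# ---------------------------------------------------------------------------
# fixture directory writer
# ---------------------------------------------------------------------------

def write_fixture_dir(spec: FixtureSpec, out_dir: str, n_experiments: int = 10) -> dict:
    """Materialize a complete fixture directory.

    Writes genome.bed12, a store/ directory (peak BEDs + metadata.tsv), a DE
    table, the planted gene list, signature gene-set files and
    ground_truth.json. Returns the ground-truth payload.
    """
    os.makedirs(out_dir, exist_ok=True)
    ga = synth_genome(spec)
    write_bed12(ga, os.path.join(out_dir, "genome.bed12"))
    with open(os.path.join(out_dir, "chrom.sizes"), "w") as fh:
        for chrom, ln in sorted(ga.chrom_sizes.items()):
            fh.write(f"{chrom}\t{ln}\n")

    store, truth = synth_tf_store(spec, ga)
    store_dir = os.path.join(out_dir, "store")
    os.makedirs(store_dir, exist_ok=True)
    meta_rows = []
    for d in store:
        bed = os.path.join(store_dir, f"{d.dataset_id}.bed")
        with open(bed, "w") as fh:
            for p in d.peakset.peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t0\t+\n")
        meta_rows.append(
            {"dataset_id": d.dataset_id, "factor": d.factor_name, "condition": d.metadata}
        )
    pd.DataFrame(meta_rows).to_csv(
        os.path.join(store_dir, "metadata.tsv"), sep="\t", index=False
    )

    table, de_genes = synth_de_table(ga, spec)
    de_df = table.frame.reset_index().rename(columns={"gene_id_key": "gene_id"})
    de_df.to_csv(os.path.join(out_dir, "de_table.tsv"), sep="\t", index=False)

    planted = truth["ds_planted"]
    with open(os.path.join(out_dir, "planted_targets.txt"), "w") as fh:
        fh.write("\n".join(planted) + "\n")

    exps = synth_perturbation_suite(store, truth, ga, spec, n_experiments=n_experiments)
    sig_dir = os.path.join(out_dir, "signatures")
    os.makedirs(sig_dir, exist_ok=True)
    gt_rows = []
    for e in exps:
        with open(os.path.join(sig_dir, f"{e.experiment_id}.txt"), "w") as fh:
            fh.write("\n".join(e.signature_gene_set) + "\n")
        gt_rows.append({"experiment_id": e.experiment_id, "perturbed_tf": e.perturbed_tf})
    pd.DataFrame(gt_rows).to_csv(
        os.path.join(sig_dir, "ground_truth.tsv"), sep="\t", index=False
    )

    payload = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "chrom_len": spec.chrom_len,
        "planted_tf": spec.planted_tf_name,
        "planted_targets": planted,
        "de_genes": de_genes,
        "datasets": {d.dataset_id: d.factor_name for d in store},
        "n_experiments": len(exps),
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
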