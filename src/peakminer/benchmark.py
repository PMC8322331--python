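"""Evaluation protocol for enrichment rankings.

Each perturbation experiment supplies a signature gene set for a TF that is
known to drive it. The enrichment ranking of all stored datasets is scored
by where the perturbed TF lands: its (best) rank forms the positive class,
every other dataset's rank the negative class. Pooled over experiments,
performance is summarized by

* bootstrap ROC / PR AUC: the negative class is repeatedly down-sampled to
  the positive class size, per-replicate curves are linearly interpolated
  onto a common grid and the AUCs averaged;
* an Anderson-Darling test of the normalized ranks against Uniform(0, 1)
  (a well-ranking TF concentrates near 0, rejecting uniformity);
* the percentage of experiments whose TF ranks within the first percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from .enrichment import (
    AttributeParams,
    DynamicRange,
    EnrichmentRecord,
    GenomeAnnotation,
    OverlapCriterion,
    PromoterSpec,
    TFDataset,
    enrich_gene_list,
)

DEFAULT_REPS = 5_000
GRID_POINTS = 1_001


@dataclass(frozen=True)
class PerturbationExperiment:
    experiment_id: str
    perturbed_tf: str
    signature_gene_set: tuple[str, ...]


@dataclass(frozen=True)
class BenchmarkResult:
    roc_auc: float
    pr_auc: float
    pct_first_percentile: float
    ad_p_value: float
    n_experiments: int
    n_bootstrap: int


def rank_perturbed_tf(records: Sequence[EnrichmentRecord], tf: str) -> tuple[int, int]:
    """Best 1-based rank of a factor in a ranking, and the ranking length."""
    if not records:
        raise ValueError("empty ranking")
    positions = [i for i, r in enumerate(records, start=1) if r.factor_name == tf]
    if not positions:
        raise ValueError(f"factor {tf!r} has no dataset in the ranking")
    return min(positions), len(records)


def rank_to_score(rank: int, total: int) -> float:
    """Map a 1-based rank to a score in (0, 1]; higher = better."""
    return 1.0 - (rank - 1) / total


def _rep_aucs(fg: np.ndarray, bg: np.ndarray, grid: np.ndarray) -> tuple[float, float]:
    y = np.concatenate([np.ones(fg.size), np.zeros(bg.size)])
    s = np.concatenate([fg, bg])
    fpr, tpr, _ = roc_curve(y, s)
    roc = float(np.trapezoid(np.interp(grid, fpr, tpr), grid))
    precision, recall, _ = precision_recall_curve(y, s)
    # walk points by decreasing threshold (recall non-decreasing) and keep,
    # per recall level, the precision where that recall is first attained
    recall, precision = recall[::-1], precision[::-1]
    lv, first = np.unique(recall, return_index=True)
    prec_i = np.interp(grid, lv, precision[first])
    pr = float(np.trapezoid(prec_i, grid))
    return roc, pr


def bootstrap_auc(
    fg: Sequence[float],
    bg: Sequence[float],
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean ROC and PR AUC over down-sampled bootstrap replicates.

    Per replicate, |fg| negatives are sampled from bg without replacement
    (with replacement, and a warning, if bg is smaller than fg), both curves
    are linearly interpolated onto a common 1001-point grid, and AUCs are
    averaged over replicates. Deterministic under a fixed seed.
    """
    fg_arr = np.asarray(fg, dtype=float)
    bg_arr = np.asarray(bg, dtype=float)
    if fg_arr.size == 0 or bg_arr.size == 0:
        raise ValueError("fg and bg score sets must be non-empty")
    replace = bg_arr.size < fg_arr.size
    if replace:
        import warnings

        warnings.warn(
            "background smaller than foreground; down-sampling with replacement",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, GRID_POINTS)
    roc_sum = 0.0
    pr_sum = 0.0
    for _ in range(reps):
        sample = rng.choice(bg_arr, size=fg_arr.size, replace=replace)
        roc, pr = _rep_aucs(fg_arr, sample, grid)
        roc_sum += roc
        pr_sum += pr
    return roc_sum / reps, pr_sum / reps


# Anderson-Darling against a fully specified Uniform(0,1) ("case 0"). The
# p-value uses the standard asymptotic distribution of A^2 (Marsaglia &
# Marsaglia's rational approximations to its CDF).
def _ad_statistic(u: np.ndarray) -> float:
    n = u.size
    u = np.sort(u)
    eps = np.finfo(float).tiny
    u = np.clip(u, eps, 1 - 1e-16)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))


def _ad_pvalue(a2: float) -> float:
    if a2 <= 0:
        return 1.0
    if a2 < 2.0:
        cdf = (
            math.exp(-1.2337141 / a2)
            / math.sqrt(a2)
            * (2.00012 + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * a2) * a2) * a2) * a2) * a2)
        )
    else:
        # the fitted polynomial is only meaningful near its range; beyond
        # A^2 ~ 10 the tail probability is effectively zero anyway
        z = min(a2, 10.0)
        cdf = math.exp(
            -math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z) * z)
        )
        if a2 > 10.0:
            return max(0.0, 1.0 - cdf) * math.exp(-(a2 - 10.0) / 2.0)
    return min(1.0, max(0.0, 1.0 - cdf))


def ad_uniformity(ranks: Sequence[tuple[int, int]]) -> float:
    """Anderson-Darling p-value for normalized ranks against Uniform(0,1).

    Each rank is normalized with a mid-rank correction u = (rank - 0.5) / total
    to avoid the 0/1 endpoints. Requires at least 5 experiments.
    """
    if len(ranks) < 5:
        raise ValueError(f"Anderson-Darling test needs >= 5 ranks, got {len(ranks)}")
    u = np.array([(r - 0.5) / t for r, t in ranks], dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("normalized ranks must fall strictly inside (0, 1)")
    return _ad_pvalue(_ad_statistic(u))


def first_percentile_pct(ranks: Sequence[tuple[int, int]]) -> float:
    """Percentage of experiments whose TF ranks within the top 1%."""
    if not ranks:
        raise ValueError("no ranks given")
    n_hit = sum(1 for r, t in ranks if r / t <= 0.01)
    return 100.0 * n_hit / len(ranks)


def collect_ranks(
    experiments: Sequence[PerturbationExperiment],
    store: Sequence[TFDataset],
    ga: GenomeAnnotation,
    spec: PromoterSpec,
    crit: OverlapCriterion,
    params: Optional[AttributeParams] = None,
    dynamic_ranges: Optional[Mapping[str, DynamicRange]] = None,
    target_sets: Optional[Mapping[str, set[str]]] = None,
) -> tuple[list[tuple[int, int]], list[float], list[float]]:
    """Run enrichment per experiment; pool fg / bg rank scores.

    Returns (ranks, fg_scores, bg_scores) where ranks holds the perturbed
    TF's best (rank, total) per experiment, fg_scores the corresponding
    rank scores and bg_scores the scores of every other ranked dataset.
    """
    ranks: list[tuple[int, int]] = []
    fg: list[float] = []
    bg: list[float] = []
    for exp in experiments:
        records = enrich_gene_list(
            list(exp.signature_gene_set),
            store,
            ga,
            spec,
            crit,
            params=params,
            dynamic_ranges=dynamic_ranges,
            target_sets=target_sets,
        )
        rank, total = rank_perturbed_tf(records, exp.perturbed_tf)
        ranks.append((rank, total))
        fg.append(rank_to_score(rank, total))
        best_seen = False
        for pos, rec in enumerate(records, start=1):
            if rec.factor_name == exp.perturbed_tf and pos == rank and not best_seen:
                best_seen = True  # the positive entry; everything else is background
                continue
            bg.append(rank_to_score(pos, total))
    return ranks, fg, bg


def run_benchmark(
    experiments: Sequence[PerturbationExperiment],
    store: Sequence[TFDataset],
    ga: GenomeAnnotation,
    spec: PromoterSpec,
    crit: OverlapCriterion,
    params: Optional[AttributeParams] = None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    dynamic_ranges: Optional[Mapping[str, DynamicRange]] = None,
    target_sets: Optional[Mapping[str, set[str]]] = None,
) -> BenchmarkResult:
    """Full evaluation: enrichment per experiment, then pooled metrics."""
    ranks, fg, bg = collect_ranks(
        experiments, store, ga, spec, crit, params=params,
        dynamic_ranges=dynamic_ranges, target_sets=target_sets,
    )
    roc, pr = bootstrap_auc(fg, bg, reps=reps, seed=seed)
    return BenchmarkResult(
        roc_auc=roc,
        pr_auc=pr,
        pct_first_percentile=first_percentile_pct(ranks),
        ad_p_value=ad_uniformity(ranks),
        n_experiments=len(experiments),
        n_bootstrap=reps,
    )
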