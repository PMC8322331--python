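"""Independent reference implementations used only by the tests.

These deliberately use the dumbest correct algorithm available (per-base
counting, exact rational combinatorics, textbook step-up) so they share no
code path with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

from peakminer.genome_model import AttributeParams, GenomeAnnotation, iter_attribute_regions
from peakminer.intervals import PeakSet


def per_base_coverage(
    ps: PeakSet, ga: GenomeAnnotation, params: AttributeParams
) -> dict[str, tuple[int, int]]:
    """Coverage by marking every covered base in a boolean mask."""
    masks: dict[str, np.ndarray] = {}
    ext = 50_000  # head-room for regions clipped only at 0
    for chrom in ga.chromosomes():
        length = ga.chrom_sizes.get(chrom)
        if length is None:
            length = max(
                [t.tx_end for t in ga.transcripts() if t.chrom == chrom], default=0
            ) + ext
        masks[chrom] = np.zeros(length + ext, dtype=bool)
    for p in ps.peaks:
        if p.chrom in masks:
            masks[p.chrom][p.start: p.end] = True
    out: dict[str, tuple[int, int]] = {}
    for r in iter_attribute_regions(ga, params):
        covered, total = out.get(r.kind, (0, 0))
        mask = masks.get(r.chrom)
        c = int(mask[r.start: r.end].sum()) if mask is not None else 0
        out[r.kind] = (covered + c, total + r.length)
    return out


def hypergeom_tail_exact(list_hits: int, list_size: int, genome_hits: int, genome_size: int) -> float:
    """P(X >= list_hits) by exact rational combinatorics."""
    num = sum(
        comb(genome_hits, k) * comb(genome_size - genome_hits, list_size - k)
        for k in range(list_hits, min(list_size, genome_hits) + 1)
        if list_size - k <= genome_size - genome_hits
    )
    return float(Fraction(num, comb(genome_size, list_size)))


def hypergeom_tail_enumerated(list_hits: int, list_size: int, genome_hits: int, genome_size: int) -> float:
    """P(X >= list_hits) by enumerating every possible draw (tiny sizes only)."""
    population = range(genome_size)
    successes = set(range(genome_hits))
    n_total = 0
    n_tail = 0
    for draw in itertools.combinations(population, list_size):
        n_total += 1
        if sum(1 for x in draw if x in successes) >= list_hits:
            n_tail += 1
    return n_tail / n_total


def bh_stepup_reference(p_values) -> list[float]:
    """Textbook Benjamini-Hochberg: sort, p*m/i, right-to-left cumulative min."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adj[i] = min(1.0, running)
    return adj


def mann_whitney_auc(fg, bg) -> float:
    """ROC AUC as the probability a fg score beats a bg score (ties count half)."""
    fg = list(fg)
    bg = list(bg)
    wins = sum(1.0 if f > b else 0.5 if f == b else 0.0 for f in fg for b in bg)
    return wins / (len(fg) * len(bg))
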