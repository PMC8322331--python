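# Methods

This note documents the models and procedures implemented in peakminer,
the defaults and their rationale, the numerical choices made where the
design was open, what the synthetic fixtures emulate, and the known
limitations. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinates and gene models

All internal coordinates are 0-based half-open (BED convention); GFF3/GTF
starts are shifted by −1 on read. A transcript model carries its span,
strand, exon structure and an optional CDS interval. Six gene-feature
attributes are derived per transcript:

| attribute | definition (on '+'; mirrored on '−') | default size |
|---|---|---|
| FLANK5 | `[tx_start − flank5_len, tx_start)` | 5000 bp |
| TSS | `[tx_start − tss_upstream, tx_start + tss_downstream)` | −2000/+500 bp |
| UTR5 | `[tx_start, cds_start)` | annotated |
| CDS | `[cds_start, cds_end)` — exons *and* introns | annotated |
| UTR3 | `[cds_end, tx_end)` | annotated |
| FLANK3 | `[tx_end, tx_end + flank3_len)` | 5000 bp |

Interpretations where the attribute scheme is underdetermined:

* **Non-coding transcripts** have no annotated CDS; they receive a CDS
  attribute equal to the full transcript span (a gene-body stand-in) so
  they remain annotatable, and no UTRs.
* **Isoform selection**: `longest` (default) keeps the single transcript
  maximizing span length; ties break by lexicographically smallest
  transcript id, making the choice deterministic. `all` keeps every
  isoform; gene-level outputs then count a gene once even if several
  isoforms hit, while tables keep one row per transcript.
* **Strand handling**: `respect_strand=False` treats every transcript as
  '+' (the "gene directionality" toggle).
* Regions running past a chromosome edge are clipped, never discarded;
  zero-length regions are emitted degenerate (`start == end`).

## Coverage and gene hits

The coverage of a peak track over an attribute is
`covered_bp / total_bp`, where `covered_bp` sums, over all attribute
regions of the selected isoforms, the overlap with the *merged* peak set,
and `total_bp` sums the region lengths. Merging first means a base covered
by two overlapping peaks counts once, so the fraction is a true proportion
in [0, 1]; the cumulative sum is over disjoint covered intervals, not
double-counted bases.

A gene is *hit* under an overlap criterion iff some single peak overlaps
its selected attribute region by at least `value` bp (`bp` mode) or at
least `value` percent **of the peak's own length** (`percent` mode — the
reference point of the percentage was an open choice; percent-of-peak was
chosen because it is the peak, not the attribute, whose placement is the
observation). The reported `overlap_bp` is the largest qualifying
peak–region overlap. Raising the threshold is monotone: it never adds
genes.

Peak integration intersects the per-track hit gene sets at **gene level**
(not transcript level — an interpretation; transcript-level intersection
would make results depend on isoform naming across tracks). Each track may
target its own attribute with its own criterion; 2–5 tracks are accepted.

## Gene neighborhoods

For a query peak, genes whose span intersects the peak fill the *overlap*
slot; the remaining genes on each side are ranked by the distance from the
peak edge to the nearest gene-span edge (not the TSS — an interpretation;
span edges make "nearest" symmetric for the two sides), ties broken by
gene id, and the five nearest fill the up/down slots. Without strand
handling, "up" means genomically left of the peak; with
`respect_strand=True` a '−'-strand gene swaps sides.

A gene present in the user's annotation table is treated as significantly
deregulated — the table is expected to contain only significant DE genes,
so no internal FDR filtering is applied — with direction given by the sign
of its log2 fold-change column (by default the first numeric column,
overridable by name). Slot classes follow a majority rule: UP if
upregulated genes outnumber downregulated (and exist), DOWN for the
converse, MIXED for an equal non-zero split, UNCHANGED if no gene is
deregulated, EMPTY if the slot has no genes. A multi-peak wrapper pools
slot genes across peaks and applies the same rule.

The long-range view returns every gene whose span intersects
`[peak.start − upstream, peak.start)` or `[peak.end, peak.end + downstream)`
(defaults 50 kb each), split into upstream / overlap / downstream blocks.

## TF / HM enrichment

A dataset's *target set* is the set of genes whose promoter window —
`[TSS − up, TSS + down)` in the direction of transcription — overlaps one
of its peaks under the overlap criterion. Fixed windows default to
−2000/+500 bp; dynamic mode replaces `up` by the dataset's estimated
boundary with a 50 bp downstream margin. Histone-modification datasets use
fixed windows only (a binding-density boundary is not meaningful for broad
chromatin marks).

For a submitted list (after optional offline ID mapping: deterministic
two-column table, unmapped IDs dropped and reported, post-mapping
duplicates collapsed to the first occurrence), the background is the full
gene complement of the annotation. Per dataset the contingency counts feed
`scipy.stats.hypergeom.sf` (one-tailed, `P(X ≥ listHits)`); FDR is a
single Benjamini–Hochberg family across all datasets of the store
(`statsmodels` step-up). Scores:

```
score          = (listHits / listSize) / (genomeHits / genomeSize)
combined score = score * -log10(p)
```

`score` is undefined (reported missing) when `listSize` or `genomeHits` is
zero; p-values of exactly 0 are floored at the smallest positive float
before the log. Records sort by combined score descending, ties by
p-value ascending, then dataset id — making the ranking deterministic and
invariant to input order.

## Dynamic promoter boundaries

For each peak, the distance from its **midpoint** (the anchor was an open
choice; the midpoint is well-defined for BED3 inputs, unlike a summit) to
the nearest TSS it lies upstream of, kept when it falls in [0, 20 000) bp.
Each peak contributes one count, to its nearest upstream TSS only.
Distances are binned at 50 bp (400 bins). The noise floor is
`median + 3·std` (population std) of the bins spanning 5 000–20 000 bp —
distances at which binding is assumed non-specific. The histogram is
smoothed with a 3-bin simple moving average, truncated at the edges so the
smoothed curve keeps 400 bins. Scanning outward from distance 0, the
boundary is the left edge of the first bin where the smoothed count falls
**strictly below** the noise floor — where binding density decays into
noise. Degenerate outcomes: no crossing at all → 20 000 bp (binding
enriched across the whole range); a crossing already at bin 0 or an empty
histogram → fall back to the conventional 2 000 bp (no enrichment shoulder
to measure).

The estimator is a density-threshold method: it needs enough peaks for the
per-bin counts near the TSS to stand several standard deviations above the
noise floor. At a 5× signal-to-background density ratio with tens of
counts per bin it localizes a planted boundary to within one bin (±50 bp,
the smoothing shifts the crossing by at most one bin outward); with only a
few dozen peaks in total — as in the toy planted store — bin counts of 0–3
cannot clear the floor and the estimator falls back. Real per-TF datasets
with thousands of peaks are the intended regime.

## Benchmarking protocol

Each perturbation experiment supplies a signature gene set and the name of
the perturbed TF. The enrichment ranking is computed per experiment; the
perturbed TF's best (minimum) 1-based rank forms the positive class (when
the TF has several datasets, they collapse to the best rank; the remaining
ones join the negative class), every other ranked dataset the negative
class. Ranks map to scores `1 − (rank − 1)/total` so that higher is
better.

Because negatives vastly outnumber positives, each bootstrap replicate
down-samples the negatives to the positive-class size without replacement
(with replacement plus a warning if the background is smaller). Per
replicate, ROC and PR curves are built and linearly interpolated onto a
common 1001-point grid (FPR grid for ROC, recall grid for PR; at tied
recalls the precision where that recall is first attained is used), AUCs
are taken by the trapezoid rule and averaged over replicates (vertical
averaging — the curve-averaging scheme was an open choice). 5000
replicates by default; the test suite and acceptance script use 500, which
leaves the means stable to well under the asserted tolerances. The whole
procedure is bit-reproducible under a fixed seed.

Rank uniformity is tested with an Anderson–Darling statistic against a
fully specified Uniform(0,1), using the mid-rank correction
`u = (rank − 0.5)/total` to avoid the 0/1 endpoints, and the standard
asymptotic approximation of the A² distribution (Marsaglia-style rational
fits; beyond A² ≈ 10 the tail is damped smoothly to zero, where the fitted
polynomial leaves its range). At least five experiments are required.
First-percentile recovery is `100 · #{rank/total ≤ 0.01} / #experiments`;
note it is structurally zero when the store holds fewer than 100 datasets.

## Synthetic fixtures

The generators emulate the study system at toy scale: one chromosome,
default 1 Mb with 100 non-overlapping coding genes (10 kb slots, 2–6 kb
transcripts with UTRs and 1–4 exons, strands alternating), a store with
one planted regulator (one promoter-proximal peak — midpoint uniform
within the planted boundary upstream of the TSS — per target gene, on top
of Poisson background peaks, expected 20 per dataset) and 20
background-only decoys, DE tables over a seeded gene subset (|log2FC| ≥
0.25, FDR ≤ 0.05), and perturbation suites whose signatures mix planted
targets with random genes in a controlled proportion. All generators are
bit-reproducible under a fixed seed.

Boundary-recovery fixtures use a single-strand genome with 25 kb slots:
with alternating strands at close spacing, the upstream windows of facing
genes interleave and the nearest-upstream-TSS assignment truncates the
distance histogram, which is a property of dense toy genomes rather than
of the estimator. Counts are set high (60 peaks per gene, 3000 background)
so the per-bin signal stands clear of the noise floor at a 5× density
ratio.

What passing tests on these fixtures do **not** show: robustness to
overlapping and nested real gene models, many-isoform genes, chromosome
heterogeneity, correlated (non-Poisson) background binding, assembly
mismatches between store and annotation, or ID-space noise beyond simple
mapping tables. The benchmark's null fixture is rank-level (uniform ranks)
rather than a full null pipeline, which keeps its calibration check
independent of the enrichment stage.

## Problem sizes and numerical notes

The test suite checks coverage against a per-base oracle on 100 random
instances (≤ 50 genes, ≤ 200 peaks), the hypergeometric tail against exact
rational combinatorics on 200 tuples (background ≤ 30), boundary recovery
on 10 seeds per planted boundary {500, 2000, 5000} bp, regulator recovery
on 10 seeds of a 1000-gene / 20-decoy / 50-gene-list configuration, and
benchmark calibration with 500 bootstrap replicates, 75-experiment null
fixtures and 100-seed Anderson–Darling coverage. Floating-point
comparisons in enrichment use exact formulas throughout; the only
approximations are the A² p-value fits and the bootstrap means.

Known limitations: GTF reading relies on `gffutils` inference when
transcript feature lines are absent (slow on large files); the store is
loaded eagerly into memory; `percent` overlap of the attribute (rather
than the peak) is not offered; Hi-C-informed window choice for the
long-range view is out of scope.
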