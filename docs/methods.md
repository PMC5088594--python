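# Methods

## Scope and conventions

`tilemeth` implements a qualitative, replicate-free analysis of
whole-genome bisulfite sequencing (WGBS) methylomes on a fixed genomic
grid.  All intervals (tiles, annotations, DMRs, TE indels, bins) are
0-based half-open; a single convention removes off-by-one bug classes at
module boundaries.  Per-cytosine records keep the 1-based position of
the cytosine report they come from and are mapped to tiles with
`index = (pos − 1) // tile_size`.  Zero-coverage cytosines are retained
at parse time so that "cytosines with coverage" filters are applied
where they belong, in the DMR caller.  Strands are never collapsed:
symmetric CpG pairs stay two records, as emitted by the methylation
extractor.

## Tile aggregation and state classification

Each cytosine contributes to exactly one non-overlapping tile (default
100 bp), separately per context (CG/CHG/CHH).  The tile level is
*weighted* methylation — summed methylated reads over summed total reads
— not a mean of per-site fractions, so deeply covered sites carry more
weight and shallow sites do not add noise.  An uncovered tile-context
has an undefined level; it is never coerced to 0.

Per-context methylated/unmethylated calls use strict thresholds
(CG > 0.50, CHG > 0.30, CHH > 0.10).  The thresholds sit in the
antimodes of the respective tile-level distributions: CG and CHG are
bimodal genome-wide, CHH unimodal and low.  Strict inequality is a
deliberate choice — a tile exactly at a threshold is unmethylated — and
is applied uniformly to all three contexts.  The composite state is the
subset of methylated contexts (8 possibilities) and is defined only for
tiles with data in all three contexts.

Annotation intersection uses ≥ 1 bp overlap; a tile overlapping both a
gene and a TE is `gene+TE`.  When several TEs overlap a tile, the family
of the largest overlap wins, ties broken by coordinate (the choice is
arbitrary but deterministic).  Meta-profiles pool read counts per bin
over all features (body rescaled to 20 equal-fraction bins by default,
flanks in fixed 100-bp bins, minus-strand features reversed); 20 body
bins resolves body-vs-edge structure at typical gene lengths while
keeping per-bin counts high, and features shorter than the bin count are
skipped rather than up-sampled.

## DMR calling

For one context and an aligned tile grid, a window is differential
between samples A and B when, in both samples:

* mean depth ≥ 3 reads per covered cytosine (`min_depth`);
* ≥ 2 covered cytosines for CG/CHG, ≥ 8 for CHH (`min_cyt_cov`);

and the effect rule holds: |w_B − w_A| ≥ 0.70 (CG) / 0.50 (CHG); for
CHH, min(w) ≤ 0.05 and max(w) ≥ 0.20.  CHH gets an envelope rule rather
than a difference threshold because CHH levels are an order of magnitude
lower and a difference cutoff scaled to CG/CHG would either never fire
or fire on noise.  "3× coverage" is interpreted as mean reads per
*covered* cytosine per window per sample; this statistic is robust to
the number of cytosines a window happens to contain.  Windows missing in
either sample fail with reason `no-data`; every failing window carries a
reason code (`coverage`, `cytosine-count`, `effect-size`, `no-data`).

Runs of passing windows are collapsed into DMRs only while windows abut
exactly (`end_i == start_{i+1}`) and share a direction.  A gap, a
failing window, or a direction flip breaks the run; no gap tolerance is
allowed.  Direction homogeneity is assumed because a region reported as
"low" or "high" versus the reference is only interpretable if its
windows agree.  Runs shorter than `min_consecutive = 2` are discarded,
fixing the minimum DMR size at 200 bp.  DMR levels per line are pooled
read counts over the span, not means of window levels.

Two presets exist because two filter variants of this style of analysis
are in circulation: `results` (the defaults above) and `methods-strict`
(CG difference 0.80, mean depth 10).  Both are expressible; `results` is
the default.  Under `methods-strict` the CHH envelope rule is retained
(a 20% absolute-difference rule for CHH coincides with the envelope's
high side), with the stricter depth.

Merging across pairwise comparisons: transitively overlapping DMRs (≥ 1
bp) form a component; only the largest region in each component is kept
(ties: leftmost, then source pair alphabetically).  The kept set is
mutually non-overlapping.  Note this is deliberately lossy — a 200-bp
DMR swallowed by an overlapping 700-bp DMR from another comparison
disappears as a region, surviving only through the per-line level matrix
computed afterwards.

## Downstream analyses

**Clustering.**  Lines are clustered on their DMR-level vectors with
average linkage over a pairwise-complete Euclidean distance scaled by
√(n_total / n_complete); the scaling makes distances comparable when
lines share different numbers of observed DMRs.  Metric and linkage are
a design choice (nothing in the problem pins them); columns are sorted
by name so ties resolve deterministically.  A line with no observed
levels is an error, not a guess.

**SNP distances and NJ.**  Only sites called in *all* requested lines
enter the distance matrix; d(i,j) is the mismatch proportion over those
sites.  Neighbor joining is the standard Saitou–Nei agglomeration with
the Studier–Keppler Q criterion, ties broken by the smallest index pair,
and the final three taxa resolved in closed form.  It is implemented
in-package (rather than delegated) so that the tie-break is pinned and
additive matrices are recovered exactly; the scikit-bio implementation
serves as an independent cross-check in the tests.  Trees are
`skbio.TreeNode` objects and serialise to Newick.

**Density correlation.**  SNPs and DMRs are counted in non-overlapping
bins tiled from 0 (1 Mb for CG/CHG, 5 Mb for CHH, where DMRs are
sparser).  A DMR is assigned to the bin containing its midpoint —
assignment by any-overlap would double-count boundary-spanning DMRs.
r² is the squared Pearson correlation over bins with at least one SNP or
DMR; all-empty bins carry no information about the association and are
excluded.  Fewer than 3 usable bins is an error.

**TE-indel proximity.**  A DMR is "near" an indel when the interval gap
(max(0, max(starts) − min(ends)) on half-open intervals) is ≤ 500 bp.
Direction tallies restrict to indels carried by the DMR's non-reference
line: hypermethylation near insertions, hypomethylation near deletions.
The permutation test is an extension beyond raw proximity counts (and is
flagged as such in the result object): DMR positions are re-drawn
uniformly within their chromosome, lengths preserved, and a two-sided
empirical p-value with the +1 correction is attached.  The +1 correction
makes the test conservative on discrete counts, which the calibration
check confirms (well under 10% of null runs below p = 0.05).

**Replicate correlation.**  Per-site levels m/(m+u) are compared between
replicates over sites with ≥ `min_depth` total reads in both.  Site
count is necessarily non-increasing in the floor; r² rises with the
floor on overdispersed data because shallow sites carry binomial noise
that is independent between replicates.  Zero variance in either vector
yields an undefined r², reported as such.

## Synthetic data generator

The generator emulates a small, repeat-rich grass genome and the
qualitative structure WGBS data shows there; defaults (all
configurable):

| parameter | default | rationale |
|---|---|---|
| chromosomes | 2 × 400 kb | enough tiles (8 000) for stable statistics at desk scale |
| cytosine density (CG/CHG/CHH per bp) | 0.07 / 0.05 / 0.20 | dinucleotide-frequency-realistic; ~7/5/20 sites per 100-bp tile, so nearly every tile is analyzable per context |
| gene rate, mean length | 1/4 kb, 1.5 kb | gene-dense arms |
| TE families | DTT (mean 120 bp), RLX (842 bp), RLC (600 bp) | short DNA-transposon class vs long retrotransposon classes |
| pericentromere | central 30%, TE ×3, genes ×0.25 | repeat-rich, gene-poor core |
| read depth | NB(mean 8, shape 2) | one-lane WGBS coverage scale |

Site-level truth is drawn per annotation category (beta distributions:
genes high-CG body / near-zero CHG+CHH; TEs near-saturating CG, high
CHG; DTT-like elements elevated CHH; intergenic a two-component CG/CHG
mixture over latent 1-kb domains, which is what makes tile-level CG/CHG
histograms bimodal).  Truth is drawn per category, not per TE copy —
sufficient for testing the pipeline, far simpler than sequence-level TE
modeling.

Injected DMRs override the per-site level inside tile-aligned spans:
affected lines get the alternate level, all other lines the reference
level (defaults: CG 0.05 vs 0.95, CHG 0.05 vs 0.80, CHH 0.02 vs 0.30).
Base levels are derived from the truth set's master seed and are
identical across lines, so lines differ *only* at injected truth plus
sampling noise.  SNP density follows a latent log-normal diversity track
in 50-kb blocks with per-line divergence drawn from U(0.15, 0.5).  TE
indels are methylation-neutral by default, matching the observed null
for real TE polymorphisms; a positive-control switch (`te_effect > 0`)
plants a CHH methylation change beside each indel in its carrier lines
for power-testing the proximity analysis.

What the generator does **not** model — and hence what passing tests do
not show about real data: bisulfite conversion failure, mapping bias and
mappability gaps, chimeric PBAT reads, genetic divergence breaking read
mapping (a major source of spurious no-data regions in real panels),
linkage between SNPs and methylation state, TE sequence content, and
within-line biological variability.  The recovery figures (sensitivity/
precision ≥ 0.95 for 3-tile CG DMRs at effect 0.9 and 8× depth) are
properties of the caller under this idealised model, not field
performance estimates.

## Numerical choices and degenerate inputs

* Undefined levels propagate as `None`/NaN and are never imputed.
* Empty record set → empty tile list; empty DMR sets merge to empty.
* `weighted_methylation` rejects m > t and negative counts.
* Permutation p-values use (1 + #extreme)/(n_perm + 1), bounded in
  (0, 1]; seeded `numpy.random.default_rng` throughout, with child seeds
  drawn below 2³¹.
* Pipeline stage caching keys on SHA-256 of input files plus parameters;
  outputs are rewritten only when the digest changes.

## Problem sizes

The test suite and the acceptance script run on 100–400 kb synthetic
chromosomes (≈ 1 000–8 000 tiles, ~10⁵ cytosines per line), 40 injected
CG DMRs for recovery, 50 bins for correlation recovery, 200 simulations
× 99 permutations for null calibration, and 4–8-taxon trees for NJ
recovery — sizes at which every statistic assessed is stable while the
full suite completes in well under a minute per module.

## Known limitations

* The caller is qualitative: no within-line variance model, so no
  significance statement per DMR — by design.
* No gap tolerance in run collapsing means a single low-coverage window
  splits (and below 2×-minimum length, kills) an otherwise clear DMR;
  the demo in the README shows one such case.
* Largest-region merging discards smaller overlapping DMRs entirely.
* `metaprofile` skips features shorter than the body bin count.
* The permutation null redraws DMR positions uniformly per chromosome,
  ignoring coverage and annotation structure; it is a calibration
  baseline, not a full null model of DMR placement.
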