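# tilemeth

Tile-based analysis of whole-genome bisulfite sequencing (WGBS)
methylomes for panels of inbred plant lines: weighted methylation over
fixed 100-bp genomic tiles, eight-state methylation classification,
context-specific calling of differentially methylated regions (DMRs),
and the downstream analyses that relate methylation variation to genetic
variation (SNP density, transposable-element indel polymorphisms,
replicate correlation).

## Who this is for

Plant epigenomics groups working with per-cytosine methylation counts
(Bismark-style CX reports) from inbred or highly homozygous material,
who want a transparent, qualitative, replicate-free DMR caller with
explicit filters — as a complement or sanity check to model-based
callers — plus the standard association analyses around it.  A seeded
synthetic-methylome generator with known ground truth makes the whole
pipeline testable without any external data.

## The model

For a genomic region (here a 100-bp tile) with summed methylated read
count *m* and summed total read count *t* in one cytosine sequence
context *c* ∈ {CG, CHG, CHH}, the **weighted methylation level** is

    w_c = m / t          (undefined when t = 0; never treated as 0)

Tiles are called methylated per context with strict thresholds
*w*<sub>CG</sub> > 0.50, *w*<sub>CHG</sub> > 0.30, *w*<sub>CHH</sub> > 0.10
(the tile-level CG/CHG distributions are bimodal; CHH is low and
unimodal).  The subset of methylated contexts gives one of **eight
composite states** (`none`, `CG-only`, …, `CG-CHG-CHH`) for tiles
covered in all three contexts.

A tile is a **differential window** between two samples when, in *both*
samples, it has ≥ 2 covered cytosines (CHH: ≥ 8) with a mean depth of
≥ 3 reads per covered cytosine, and the effect-size rule holds:
|Δw| ≥ 0.70 for CG, ≥ 0.50 for CHG, and for CHH one sample ≤ 0.05
("low") while the other ≥ 0.20 ("high").  Maximal runs of exactly
abutting, same-direction differential windows are collapsed into DMRs;
runs shorter than 2 windows are discarded, so the minimum DMR size is
**200 bp**.  Across pairwise comparisons, transitively overlapping DMRs
are reduced to the single largest region.  A stricter preset
(`methods-strict`: CG |Δw| ≥ 0.80, depth ≥ 10) is available.

Downstream: average-linkage clustering of per-line DMR levels
(pairwise-complete Euclidean distance), pairwise SNP mismatch distances
with a Saitou–Nei neighbor-joining tree, DMR-vs-SNP density correlation
in 1-Mb (CG/CHG) or 5-Mb (CHH) bins, DMR proximity to TE indels within
500 bp with a seeded permutation null, and per-site replicate
correlation under a minimum-depth filter.

## Worked example

Generate a synthetic four-line panel and run the full pipeline:

```
$ tilemeth simulate --out demo --seed 42 --lines 4
dataset in demo; run: tilemeth run --config demo/config.yaml
$ tilemeth run --config demo/config.yaml
n_dmrs_CG: 20
n_dmrs_CHG: 14
n_dmrs_CHH: 10
n_dmrs_per_line_CG: {'acc1': 4, 'acc2': 9, 'acc3': 7}
n_dmrs_per_line_CHG: {'acc1': 3, 'acc2': 6, 'acc3': 5}
n_dmrs_per_line_CHH: {'acc1': 4, 'acc2': 4, 'acc3': 2}
```

The counts are merged non-redundant DMRs per context, then per-line
counts against the reference (`ref`).  This demo's truth set injected
20 CG, 15 CHG and 10 CHH differential segments; the calls land on them
(one CHG segment sits in a sparsely covered span and is dropped by the
coverage filters — the caller is deliberately conservative).  The output
directory contains tile tables, a reference state summary, per-pair and
merged DMR BEDs, the per-line DMR level ("state") matrices, the NJ tree,
density bins, and a TE-proximity table.  A merged DMR BED row looks
like:

```
chr1  14600  14900  CG:ref-acc2  909  .  lower  acc1=0.9167,acc2=0.0541,acc3=0.9573,ref=0.9634
```

i.e. a 300-bp CG DMR where `acc2` is nearly unmethylated (level 0.054)
against ~0.96 in the other three lines; the score is |Δlevel| × 1000.

The same stages are available as a library
(`tilemeth.aggregate_tiles`, `tilemeth.call_dmrs`,
`tilemeth.merge_pairwise`, `tilemeth.neighbor_joining`, …) and as
individual subcommands (`tilemeth tile|state|dmr|njtree|repcor`).
Re-running `tilemeth run` on an unchanged configuration skips completed
stages via content hashing.

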