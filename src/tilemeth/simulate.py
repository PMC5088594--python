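"""Synthetic methylome generator with known ground truth.

Generates everything the pipeline consumes — annotations, per-line
cytosine reports, SNP tables, TE indel calls — from a seeded random
model, so every stage can be tested end to end against injected truth.

The generator emulates the statistical structure of a small, repeat-rich
grass genome profiled by WGBS:

* genes and TEs placed along each chromosome, with a short "DTT-like"
  DNA-transposon class (mean length ~120 bp) and longer retrotransposon
  classes (RLX-like mean ~840 bp), and TE density elevated in a central
  pericentromeric span;
* per-site true methylation drawn from beta distributions conditioned on
  annotation category: genes carry high CG body methylation with
  near-zero CHG/CHH, TEs near-saturating CG and high CHG, DTT-like
  elements elevated CHH, and intergenic space a bimodal CG/CHG mixture
  (methylated domains of ~1 kb) with low CHH — so tile-level CG and CHG
  distributions come out bimodal and CHH low and unimodal;
* read depth negative-binomial with mean 8 (the coverage scale typical
  of one WGBS lane), methylated counts binomial;
* injected DMRs of known context, span, effect size and direction
  (base levels are shared between lines except where a truth DMR makes
  them differ);
* SNPs with spatially varying density from a latent diversity track and
  per-line divergence;
* TE insertion/deletion polymorphisms whose local methylation effect
  defaults to zero (a null, as observed for real TE indels), with a
  positive-control switch that plants a methylation change next to each
  indel carried by a line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    CONTEXTS,
    AnnotationFeature,
    SNPRecord,
    TEPolymorphism,
)
from .dmr import DMR

_CAT_INTERGENIC, _CAT_GENE, _CAT_TE, _CAT_TE_DTT = 0, 1, 2, 3

_TRINUC = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}


@dataclass(frozen=True)
class GenomeSpec:
    """Layout parameters for the synthetic genome."""

    n_chroms: int = 2
    chrom_length: int = 400_000
    gene_rate: float = 1 / 4000.0          # gene starts per intergenic bp
    gene_length_mean: float = 1500.0
    te_rate: float = 1 / 2500.0
    te_family_mix: tuple = (("DTT", 0.45), ("RLX", 0.30), ("RLC", 0.25))
    te_length_mean: tuple = (("DTT", 120.0), ("RLX", 842.0), ("RLC", 600.0))
    cg_density: float = 0.07               # cytosine sites per bp, per context
    chg_density: float = 0.05
    chh_density: float = 0.20
    pericentromere_frac: float = 0.3       # central span with TE-rich layout
    peri_te_multiplier: float = 3.0
    peri_gene_multiplier: float = 0.25

    def __post_init__(self) -> None:
        for v in (self.cg_density, self.chg_density, self.chh_density,
                  self.gene_rate, self.te_rate):
            if v < 0:
                raise ValueError("densities and rates must be >= 0")
        if self.cg_density + self.chg_density + self.chh_density > 1:
            raise ValueError("total cytosine density cannot exceed 1 per bp")


@dataclass(frozen=True)
class MethylationModel:
    """Site-level methylation and read-depth model.

    ``beta`` maps (category, context) to the (a, b) parameters of the
    beta distribution for true site-level methylation.  Intergenic CG and
    CHG are a two-component mixture over latent ~1-kb methylated domains
    (probability ``p_intergenic_domain``), which is what makes tile-level
    CG/CHG distributions bimodal.  Depth is negative-binomial with mean
    ``depth_mean`` and shape ``depth_shape``.
    """

    depth_mean: float = 8.0
    depth_shape: float = 2.0
    p_intergenic_domain: float = 0.40
    domain_size: int = 1000
    beta: tuple = (
        (("gene", "CG"), (50.0, 5.0)),
        (("gene", "CHG"), (1.0, 60.0)),
        (("gene", "CHH"), (1.0, 80.0)),
        (("TE", "CG"), (60.0, 2.0)),
        (("TE", "CHG"), (15.0, 5.0)),
        (("TE", "CHH"), (1.0, 30.0)),
        (("TE_DTT", "CG"), (30.0, 6.0)),
        (("TE_DTT", "CHG"), (10.0, 10.0)),
        (("TE_DTT", "CHH"), (5.0, 15.0)),
        (("intergenic_meth", "CG"), (20.0, 3.0)),
        (("intergenic_unmeth", "CG"), (1.0, 40.0)),
        (("intergenic_meth", "CHG"), (12.0, 6.0)),
        (("intergenic_unmeth", "CHG"), (1.0, 50.0)),
        (("intergenic", "CHH"), (1.0, 40.0)),
    )

    def beta_params(self, category: str, context: str) -> tuple:
        return dict(self.beta)[(category, context)]


@dataclass(frozen=True)
class TruthDMR:
    """An injected differential segment: ground truth for DMR calling."""

    chrom: str
    start: int
    end: int
    context: str
    direction: str      # "higher"/"lower": affected lines vs everyone else
    lines: frozenset    # affected (non-reference) lines
    level_ref: float
    level_alt: float

    @property
    def delta(self) -> float:
        return abs(self.level_alt - self.level_ref)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Ground truth injected into a simulated panel, reproducible from seed."""

    master_seed: int
    lines: list
    reference: str
    dmrs: list = field(default_factory=list)
    snps: list = field(default_factory=list)
    te_indels: list = field(default_factory=list)

    def dmrs_for(self, context: str) -> list:
        return [d for d in self.dmrs if d.context == context]


@dataclass
class Genome:
    """Synthetic genome: chromosome sizes, annotations and cytosine sites."""

    chroms: dict
    genes: list
    tes: list
    sites: dict  # chrom -> DataFrame(pos [1-based], context, strand, trinucleotide)
    _categories: dict = field(default_factory=dict, repr=False)

    def category_array(self, chrom: str) -> np.ndarray:
        """Per-bp annotation category codes (intergenic/gene/TE/TE-DTT)."""
        if chrom not in self._categories:
            arr = np.full(self.chroms[chrom], _CAT_INTERGENIC, dtype=np.int8)
            for te in self.tes:
                if te.chrom == chrom:
                    arr[te.start:te.end] = (
                        _CAT_TE_DTT if te.family == "DTT" else _CAT_TE
                    )
            for g in self.genes:
                if g.chrom == chrom:
                    arr[g.start:g.end] = _CAT_GENE
            self._categories[chrom] = arr
        return self._categories[chrom]


def _place_features(
    rng: np.random.Generator,
    length: int,
    rate: float,
    peri: tuple,
    peri_multiplier: float,
    length_sampler,
    blocked: Optional[np.ndarray] = None,
) -> list[tuple]:
    """Sequential Poisson-gap placement of non-overlapping intervals."""
    out = []
    pos = 0
    peri_lo, peri_hi = peri
    while True:
        local = rate * (peri_multiplier if peri_lo <= pos < peri_hi else 1.0)
        if local <= 0:
            break
        pos += 1 + int(rng.exponential(1.0 / local))
        flen = max(40, int(length_sampler()))
        if pos + flen >= length:
            break
        if blocked is not None and blocked[pos:pos + flen].any():
            pos += flen
            continue
        out.append((pos, pos + flen))
        pos += flen
    return out


def generate_genome(spec: GenomeSpec, seed: int) -> Genome:
    """Generate annotations and the per-context cytosine site map.

    Deterministic given ``seed``.  Genes are placed first; TEs fill the
    remaining space (family drawn from the spec's mix, length from a
    gamma with the family's mean, density boosted in the pericentromeric
    span where gene density is reduced).
    """
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)}
    genes: list[AnnotationFeature] = []
    tes: list[AnnotationFeature] = []
    sites: dict[str, pd.DataFrame] = {}
    fam_names = [f for f, _ in spec.te_family_mix]
    fam_probs = np.array([p for _, p in spec.te_family_mix], dtype=float)
    fam_probs = fam_probs / fam_probs.sum()
    fam_len = dict(spec.te_length_mean)

    for chrom, length in chroms.items():
        half_span = spec.pericentromere_frac / 2.0
        peri = (int(length * (0.5 - half_span)), int(length * (0.5 + half_span)))
        gene_iv = _place_features(
            rng, length, spec.gene_rate, peri, spec.peri_gene_multiplier,
            lambda: rng.gamma(4.0, spec.gene_length_mean / 4.0),
        )
        blocked = np.zeros(length, dtype=bool)
        for s, e in gene_iv:
            blocked[s:e] = True
        for i, (s, e) in enumerate(gene_iv):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                AnnotationFeature(chrom, s, e, strand, "gene", "", f"{chrom}g{i:04d}")
            )
        # TEs: family chosen per element, lengths family-specific
        pos = 0
        te_iv = []
        peri_lo, peri_hi = peri
        while spec.te_rate > 0:
            local = spec.te_rate * (
                spec.peri_te_multiplier if peri_lo <= pos < peri_hi else 1.0
            )
            pos += 1 + int(rng.exponential(1.0 / local))
            fam = fam_names[rng.choice(len(fam_names), p=fam_probs)]
            flen = max(40, int(rng.gamma(4.0, fam_len[fam] / 4.0)))
            if pos + flen >= length:
                break
            if blocked[pos:pos + flen].any():
                pos += flen
                continue
            te_iv.append((pos, pos + flen, fam))
            blocked[pos:pos + flen] = True
            pos += flen
        for i, (s, e, fam) in enumerate(te_iv):
            strand = "+" if rng.random() < 0.5 else "-"
            tes.append(
                AnnotationFeature(chrom, s, e, strand, "TE", fam, f"{chrom}te{i:04d}")
            )
        # cytosine sites: one context per position, thinned uniformly
        total = spec.cg_density + spec.chg_density + spec.chh_density
        u = rng.random(length)
        is_site = u < total
        pos0 = np.flatnonzero(is_site)
        # context by renormalised sub-interval of the uniform draw
        edges = np.cumsum([spec.cg_density, spec.chg_density, spec.chh_density])
        ctx_idx = np.searchsorted(edges, u[pos0], side="right")
        contexts = np.array(CONTEXTS)[ctx_idx]
        strands = np.where(rng.random(pos0.size) < 0.5, "+", "-")
        sites[chrom] = pd.DataFrame(
            {
                "pos": pos0 + 1,
                "context": contexts,
                "strand": strands,
                "trinucleotide": [_TRINUC[c] for c in contexts],
            }
        )
    return Genome(chroms=chroms, genes=genes, tes=tes, sites=sites)


# ---------------------------------------------------------------------------
# Truth injection


def make_truth(
    genome: Genome,
    lines: Sequence[str],
    reference: str,
    seed: int,
    n_dmrs_per_context: Optional[Mapping[str, int]] = None,
    dmr_tile_counts: Sequence[int] = (3, 4, 5),
    tile_size: int = 100,
    dmr_levels: Optional[Mapping[str, tuple]] = None,
    snp_rate: float = 1 / 500.0,
    n_te_indels: int = 60,
    te_effect: float = 0.0,
    min_gap: int = 1000,
) -> TruthSet:
    """Inject DMRs, SNPs and TE indels with reproducible ground truth.

    ``dmr_levels`` maps context to (reference level, alternate level) for
    injected segments; defaults give effect sizes of 0.90 (CG), 0.75
    (CHG) and a 0.02/0.30 low/high pair (CHH).  Injected DMR spans are
    tile-aligned, mutually separated by at least ``min_gap`` bp and each
    affects one randomly chosen non-reference line.  ``te_effect > 0``
    plants a positive-control methylation change of that size next to
    every TE indel, in its carrier lines (insertions hyper, deletions
    hypo); at the default 0 the TE indels are methylation-neutral.
    """
    if reference not in lines:
        raise ValueError("reference must be among lines")
    alt_lines = [ln for ln in lines if ln != reference]
    if not alt_lines:
        # reference-only panel: nothing to differ from, so no injections
        n_dmrs_per_context = {}
        n_te_indels = 0
    rng = np.random.default_rng(seed)
    truth = TruthSet(master_seed=int(rng.integers(2**31)), lines=list(lines),
                     reference=reference)
    levels = {"CG": (0.05, 0.95), "CHG": (0.05, 0.80), "CHH": (0.02, 0.30)}
    if dmr_levels:
        levels.update(dmr_levels)
    n_dmrs = {"CG": 20, "CHG": 15, "CHH": 10}
    if n_dmrs_per_context is not None:
        n_dmrs = dict(n_dmrs_per_context)

    chrom_names = sorted(genome.chroms)
    occupied: dict[str, list] = {c: [] for c in chrom_names}

    def free(chrom: str, start: int, end: int) -> bool:
        return all(
            e + min_gap <= start or end + min_gap <= s
            for s, e in occupied[chrom]
        )

    for context in CONTEXTS:
        ref_level, alt_level = levels[context]
        for _ in range(n_dmrs.get(context, 0)):
            for _attempt in range(200):
                chrom = chrom_names[rng.integers(len(chrom_names))]
                n_tiles = int(
                    dmr_tile_counts[rng.integers(len(dmr_tile_counts))]
                )
                max_tile = genome.chroms[chrom] // tile_size - n_tiles - 1
                start = int(rng.integers(1, max_tile)) * tile_size
                end = start + n_tiles * tile_size
                if free(chrom, start, end):
                    break
            else:
                continue
            occupied[chrom].append((start, end))
            direction = "higher" if rng.random() < 0.5 else "lower"
            affected = frozenset({alt_lines[rng.integers(len(alt_lines))]})
            lo, hi = (ref_level, alt_level)
            if direction == "lower":
                lo, hi = hi, lo
            truth.dmrs.append(
                TruthDMR(chrom, start, end, context, direction, affected,
                         level_ref=lo, level_alt=hi)
            )

    # SNPs: latent diversity track modulates a Poisson position process
    divergence = {ln: rng.uniform(0.15, 0.5) for ln in alt_lines}
    block = 50_000
    for chrom in chrom_names:
        length = genome.chroms[chrom]
        n_blocks = int(np.ceil(length / block))
        track = np.exp(rng.normal(0.0, 0.6, size=n_blocks))
        u = rng.random(length)
        thresh = snp_rate * track[np.arange(length) // block]
        for pos0 in np.flatnonzero(u < thresh):
            calls = {reference: "reference"}
            for ln in alt_lines:
                r = rng.random()
                if r < 0.02:
                    calls[ln] = "missing"
                elif r < 0.02 + divergence[ln]:
                    calls[ln] = "alternate"
                else:
                    calls[ln] = "reference"
            truth.snps.append(SNPRecord(chrom, int(pos0) + 1, calls))

    # TE indel polymorphisms
    for i in range(n_te_indels):
        carrier = frozenset({alt_lines[rng.integers(len(alt_lines))]})
        if genome.tes and rng.random() < 0.6:
            te = genome.tes[rng.integers(len(genome.tes))]
            indel = TEPolymorphism(te.chrom, te.start, te.end, "deletion",
                                   te.family, carrier)
        else:
            chrom = chrom_names[rng.integers(len(chrom_names))]
            point = int(rng.integers(1000, genome.chroms[chrom] - 1000))
            fam = ("DTT", "RLX", "RLC")[rng.integers(3)]
            indel = TEPolymorphism(chrom, point, point, "insertion", fam, carrier)
        truth.te_indels.append(indel)
        if te_effect > 0:
            # positive control: methylation change flanking the indel site
            start = max(0, (indel.start // tile_size - 2) * tile_size)
            end = min(
                genome.chroms[indel.chrom],
                ((indel.end // tile_size) + 3) * tile_size,
            )
            direction = "higher" if indel.type == "insertion" else "lower"
            lo, hi = 0.02, min(0.99, 0.02 + te_effect)
            if direction == "lower":
                lo, hi = hi, lo
            truth.dmrs.append(
                TruthDMR(indel.chrom, start, end, "CHH", direction, carrier,
                         level_ref=lo, level_alt=hi)
            )
    return truth


# ---------------------------------------------------------------------------
# Methylome simulation


def _base_levels(genome: Genome, model: MethylationModel, master_seed: int) -> dict:
    """Per-site true methylation shared by all lines (before DMR overrides)."""
    rng = np.random.default_rng(master_seed)
    cat_name = {_CAT_GENE: "gene", _CAT_TE: "TE", _CAT_TE_DTT: "TE_DTT"}
    out: dict[str, np.ndarray] = {}
    for chrom in sorted(genome.chroms):
        sites = genome.sites[chrom]
        pos0 = sites["pos"].to_numpy() - 1
        cats = genome.category_array(chrom)[pos0]
        n_blocks = int(np.ceil(genome.chroms[chrom] / model.domain_size))
        dom = rng.random(n_blocks) < model.p_intergenic_domain
        site_dom = dom[pos0 // model.domain_size]
        a = np.empty(len(sites))
        b = np.empty(len(sites))
        ctx = sites["context"].to_numpy()
        for context in CONTEXTS:
            cmask = ctx == context
            for code, name in cat_name.items():
                m = cmask & (cats == code)
                if m.any():
                    a[m], b[m] = model.beta_params(name, context)
            inter = cmask & (cats == _CAT_INTERGENIC)
            if context == "CHH":
                a[inter], b[inter] = model.beta_params("intergenic", "CHH")
            else:
                for dom_state, name in (
                    (True, "intergenic_meth"), (False, "intergenic_unmeth"),
                ):
                    m = inter & (site_dom == dom_state)
                    if m.any():
                        a[m], b[m] = model.beta_params(name, context)
        out[chrom] = rng.beta(a, b)
    return out


def simulate_methylome(
    genome: Genome,
    model: MethylationModel,
    line: str,
    truth: TruthSet,
    seed: int,
    path=None,
):
    """Draw one line's cytosine report from the shared truth.

    Base per-site levels are derived deterministically from
    ``truth.master_seed`` and are identical across lines; injected truth
    DMRs override the level inside their span for every line (affected
    lines get the alternate level, all others the reference level).  Read
    depth and methylated counts are then drawn with the per-line
    ``seed``.  Returns the records as a DataFrame (CX column layout); if
    ``path`` is given, also writes a 7-column CX report.
    """
    if line not in truth.lines:
        raise ValueError(f"line {line!r} not in the truth set")
    levels = _base_levels(genome, model, truth.master_seed)
    for d in truth.dmrs:
        sites = genome.sites[d.chrom]
        mask = (
            (sites["context"] == d.context)
            & (sites["pos"] > d.start)
            & (sites["pos"] <= d.end)
        ).to_numpy()
        levels[d.chrom][mask] = d.level_alt if line in d.lines else d.level_ref
    rng = np.random.default_rng(seed)
    frames = []
    shape = model.depth_shape
    p_nb = shape / (shape + model.depth_mean)
    for chrom in sorted(genome.chroms):
        sites = genome.sites[chrom]
        n = len(sites)
        depth = (
            rng.negative_binomial(shape, p_nb, size=n)
            if model.depth_mean > 0
            else np.zeros(n, dtype=int)
        )
        meth = rng.binomial(depth, levels[chrom])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sites["pos"].to_numpy(),
                    "strand": sites["strand"].to_numpy(),
                    "count_meth": meth,
                    "count_unmeth": depth - meth,
                    "context": sites["context"].to_numpy(),
                    "trinucleotide": sites["trinucleotide"].to_numpy(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False)
    return df


# ---------------------------------------------------------------------------
# Recovery evaluation


def evaluate_recovery(
    called: Sequence[DMR],
    truth_dmrs: Sequence[TruthDMR],
    min_overlap_frac: float = 0.5,
) -> tuple[float, Optional[float], pd.DataFrame]:
    """Score called DMRs against injected truth for one context.

    A truth DMR counts as recovered when a single called DMR covers at
    least ``min_overlap_frac`` of it; precision counts called DMRs that
    overlap any truth DMR by >= 1 bp.  Returns (sensitivity, precision,
    per-truth match table); precision is None when nothing was called.
    """
    contexts = {d.context for d in called} | {t.context for t in truth_dmrs}
    if len(contexts) > 1:
        raise ValueError(f"mixed contexts: {sorted(contexts)}")
    rows = []
    n_recovered = 0
    for t in truth_dmrs:
        best = 0
        best_call = None
        for c in called:
            if c.chrom != t.chrom:
                continue
            ov = min(c.end, t.end) - max(c.start, t.start)
            if ov > best:
                best, best_call = ov, c
        frac = best / t.length
        recovered = frac >= min_overlap_frac
        n_recovered += recovered
        rows.append(
            (t.chrom, t.start, t.end, t.context, frac, recovered,
             None if best_call is None else f"{best_call.chrom}:{best_call.start}-{best_call.end}")
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "overlap_frac",
                 "recovered", "best_call"],
    )
    sensitivity = n_recovered / len(truth_dmrs) if truth_dmrs else 1.0
    if not called:
        return sensitivity, None, table
    n_true_pos = sum(
        any(
            c.chrom == t.chrom and c.start < t.end and t.start < c.end
            for t in truth_dmrs
        )
        for c in called
    )
    precision = n_true_pos / len(called)
    return sensitivity, precision, table


# ---------------------------------------------------------------------------
# Dataset export


def write_dataset(
    genome: Genome,
    model: MethylationModel,
    truth: TruthSet,
    outdir,
    seed: int,
) -> dict:
    """Write a complete synthetic dataset (CX reports, annotations, SNPs,
    TE indels, truth JSON) and return the path map."""
    import json

    from .io import write_snp_table, write_te_polymorphisms

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    rng = np.random.default_rng(seed)
    for line in truth.lines:
        p = outdir / f"{line}.cx.tsv"
        simulate_methylome(genome, model, line, truth,
                           seed=int(rng.integers(2**31)), path=p)
        paths[f"cx:{line}"] = str(p)
    genes_p = outdir / "genes.gff3"
    with genes_p.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id}\n"
            )
    tes_p = outdir / "tes.bed"
    with tes_p.open("w") as fh:
        for t in genome.tes:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}\t0\t{t.strand}\t{t.family}\n"
            )
    snps_p = outdir / "snps.tsv"
    write_snp_table(truth.snps, snps_p)
    indels_p = outdir / "te_indels.bed"
    write_te_polymorphisms(truth.te_indels, indels_p)
    truth_p = outdir / "truth.json"
    with truth_p.open("w") as fh:
        json.dump(
            {
                "master_seed": truth.master_seed,
                "lines": truth.lines,
                "reference": truth.reference,
                "dmrs": [
                    {
                        "chrom": d.chrom, "start": d.start, "end": d.end,
                        "context": d.context, "direction": d.direction,
                        "lines": sorted(d.lines), "level_ref": d.level_ref,
                        "level_alt": d.level_alt,
                    }
                    for d in truth.dmrs
                ],
                "n_snps": len(truth.snps),
                "n_te_indels": len(truth.te_indels),
            },
            fh,
            indent=1,
        )
    paths.update(
        genes=str(genes_p), tes=str(tes_p), snps=str(snps_p),
        te_indels=str(indels_p), truth=str(truth_p),
    )
    return paths
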