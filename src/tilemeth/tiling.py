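"""Tile aggregation, weighted methylation and the eight-state classification.

Per-cytosine read counts are aggregated into non-overlapping fixed-width
genomic tiles (100 bp by default), separately for the CG, CHG and CHH
sequence contexts.  A tile's methylation level is the *weighted*
methylation of Schultz et al.: summed methylated read counts divided by
summed total read counts over the tile — coverage-weighted, not a mean of
per-site fractions.  Tiles are then called methylated or unmethylated per
context against context-specific thresholds (the genome-wide tile-level
distributions are bimodal for CG and CHG, and low and unimodal for CHH,
which motivates per-context cutoffs), yielding one of eight composite
methylation states for tiles covered in all three contexts.  Tiles are
finally annotated by the genomic features they intersect (gene, TE, both,
or intergenic) and can be summarised as strand-aware meta-profiles over
features with flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CONTEXTS, AnnotationFeature, CytosineRecord, records_to_frame

import logging

logger = logging.getLogger(__name__)

#: The eight composite methylation states (subsets of {CG, CHG, CHH}).
STATE_LABELS = (
    "none",
    "CG-only",
    "CHG-only",
    "CHH-only",
    "CG-CHG",
    "CG-CHH",
    "CHG-CHH",
    "CG-CHG-CHH",
)


def weighted_methylation(reads_meth: int, reads_total: int) -> Optional[float]:
    """Weighted methylation level: summed meth reads over summed total reads.

    Returns ``None`` (undefined) when ``reads_total`` is zero — an
    uncovered region has no level; it is never treated as 0.
    """
    if reads_meth < 0 or reads_total < 0:
        raise ValueError("read counts must be non-negative")
    if reads_meth > reads_total:
        raise ValueError(f"reads_meth {reads_meth} > reads_total {reads_total}")
    if reads_total == 0:
        return None
    return reads_meth / reads_total


@dataclass
class TileProfile:
    """Per-context aggregated counts for one genomic tile [start, end).

    ``n_cyt_total[c]`` counts cytosine positions of context ``c`` in the
    tile (covered or not); ``n_cyt_cov[c]`` those with at least one read;
    ``reads_meth[c]`` / ``reads_total[c]`` are summed read counts.
    """

    chrom: str
    start: int
    end: int
    n_cyt_total: dict = field(default_factory=dict)
    n_cyt_cov: dict = field(default_factory=dict)
    reads_meth: dict = field(default_factory=dict)
    reads_total: dict = field(default_factory=dict)

    def level(self, context: str) -> Optional[float]:
        """Weighted methylation for ``context``; None when uncovered."""
        return weighted_methylation(
            self.reads_meth.get(context, 0), self.reads_total.get(context, 0)
        )

    def mean_depth(self, context: str) -> Optional[float]:
        """Mean reads per *covered* cytosine of ``context`` in the tile."""
        ncov = self.n_cyt_cov.get(context, 0)
        if ncov == 0:
            return None
        return self.reads_total.get(context, 0) / ncov


@dataclass(frozen=True)
class StateThresholds:
    """Per-context weighted-methylation cutoffs for calling a tile methylated.

    A tile is methylated in a context when its level strictly exceeds the
    threshold.  Defaults: >50% for CG, >30% for CHG, >10% for CHH,
    matching the modes of the respective tile-level distributions.
    """

    cg: float = 0.50
    chg: float = 0.30
    chh: float = 0.10

    def __post_init__(self) -> None:
        for v in (self.cg, self.chg, self.chh):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")

    def for_context(self, context: str) -> float:
        return {"CG": self.cg, "CHG": self.chg, "CHH": self.chh}[context]


@dataclass
class TileState:
    """Per-context methylation flags plus the composite 8-state label.

    ``flags[c]`` is ``methylated``, ``unmethylated`` or ``no-data``; the
    composite label is defined only when all three contexts have data and
    names exactly the set of contexts flagged methylated.
    """

    flags: dict
    composite: Optional[str]
    annotation: str = "intergenic"
    te_family: str = ""


def composite_label(methylated: Iterable[str]) -> str:
    """Canonical label for a set of methylated contexts."""
    members = [c for c in CONTEXTS if c in set(methylated)]
    if not members:
        return "none"
    if len(members) == 1:
        return f"{members[0]}-only"
    return "-".join(members)


def enumerate_states() -> set:
    """The full composite state space: all 8 subsets of {CG, CHG, CHH}."""
    return set(STATE_LABELS)


def aggregate_tiles(records, tile_size: int = 100) -> list[TileProfile]:
    """Aggregate per-cytosine records into non-overlapping tiles.

    Each cytosine lands in exactly one tile: index ``(pos - 1) // tile_size``
    on its 1-based position, so tile ``i`` covers the 0-based interval
    ``[i * tile_size, (i + 1) * tile_size)``.  Tiles with no cytosine in
    any context are not emitted.  Read counts are conserved: per context,
    the tile sums equal the record sums.

    ``records`` may be a sequence of :class:`CytosineRecord` or an
    equivalent DataFrame (columns chrom, pos, count_meth, count_unmeth,
    context).
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    if df.empty:
        return []
    df = df.assign(
        _tile=(df["pos"] - 1) // tile_size,
        _total=df["count_meth"] + df["count_unmeth"],
    )
    grouped = df.groupby(["chrom", "_tile", "context"], sort=True).agg(
        n_cyt_total=("pos", "size"),
        n_cyt_cov=("_total", lambda s: int((s > 0).sum())),
        reads_meth=("count_meth", "sum"),
        reads_total=("_total", "sum"),
    )
    tiles: dict[tuple, TileProfile] = {}
    for (chrom, tile_idx, context), row in grouped.iterrows():
        key = (chrom, int(tile_idx))
        if key not in tiles:
            start = int(tile_idx) * tile_size
            tiles[key] = TileProfile(chrom, start, start + tile_size)
        t = tiles[key]
        t.n_cyt_total[context] = int(row["n_cyt_total"])
        t.n_cyt_cov[context] = int(row["n_cyt_cov"])
        t.reads_meth[context] = int(row["reads_meth"])
        t.reads_total[context] = int(row["reads_total"])
    return [tiles[k] for k in sorted(tiles)]


def call_tile_state(
    tile: TileProfile, thresholds: StateThresholds = StateThresholds()
) -> TileState:
    """Call per-context methylated/unmethylated flags and the composite state.

    A context with no covered cytosine is ``no-data``; the composite
    8-state label is undefined (None) unless all three contexts have data.
    Comparison is strict: a level exactly at the threshold is
    unmethylated.
    """
    flags = {}
    for c in CONTEXTS:
        level = tile.level(c)
        if level is None:
            flags[c] = "no-data"
        elif level > thresholds.for_context(c):
            flags[c] = "methylated"
        else:
            flags[c] = "unmethylated"
    if any(v == "no-data" for v in flags.values()):
        composite = None
    else:
        composite = composite_label([c for c, v in flags.items() if v == "methylated"])
    return TileState(flags=flags, composite=composite)


# ---------------------------------------------------------------------------
# Annotation intersection


class FeatureIndex:
    """Interval index over annotation features for fast overlap queries."""

    def __init__(self, features: Sequence[AnnotationFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, chrom: str, start: int, end: int) -> list[AnnotationFeature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def annotate_tile(
    tile: TileProfile,
    genes,
    tes,
) -> tuple[str, str]:
    """Classify a tile by the features it intersects (>=1 bp overlap).

    Returns ``(category, te_family)`` with category one of ``gene``,
    ``TE``, ``gene+TE`` or ``intergenic``.  When several TEs overlap, the
    family of the largest-overlap TE wins (ties broken by coordinate).

    ``genes`` / ``tes`` may be feature sequences or prebuilt
    :class:`FeatureIndex` objects (build one per genome when annotating
    many tiles).
    """
    gene_idx = genes if isinstance(genes, FeatureIndex) else FeatureIndex(genes)
    te_idx = tes if isinstance(tes, FeatureIndex) else FeatureIndex(tes)
    has_gene = bool(gene_idx.overlapping(tile.chrom, tile.start, tile.end))
    te_hits = te_idx.overlapping(tile.chrom, tile.start, tile.end)
    family = ""
    if te_hits:
        def overlap_key(f: AnnotationFeature):
            ov = min(tile.end, f.end) - max(tile.start, f.start)
            return (-ov, f.start, f.end)

        family = sorted(te_hits, key=overlap_key)[0].family
    if has_gene and te_hits:
        return "gene+TE", family
    if has_gene:
        return "gene", family
    if te_hits:
        return "TE", family
    return "intergenic", family


def annotate_tiles(
    tiles: Sequence[TileProfile],
    genes: Sequence[AnnotationFeature],
    tes: Sequence[AnnotationFeature],
    thresholds: StateThresholds = StateThresholds(),
) -> list[TileState]:
    """Call states for many tiles and attach annotation categories."""
    gene_idx, te_idx = FeatureIndex(genes), FeatureIndex(tes)
    out = []
    for t in tiles:
        st = call_tile_state(t, thresholds)
        st.annotation, st.te_family = annotate_tile(t, gene_idx, te_idx)
        out.append(st)
    return out


# ---------------------------------------------------------------------------
# Meta-profiles


def metaprofile(
    records: Iterable[CytosineRecord],
    features: Sequence[AnnotationFeature],
    context: str,
    flank: int = 1000,
    n_body_bins: int = 20,
    flank_bin_size: int = 100,
) -> np.ndarray:
    """Pooled weighted-methylation profile over features with flanks.

    The feature body is rescaled to ``n_body_bins`` equal-fraction bins;
    each flank contributes ``flank / flank_bin_size`` fixed-width bins.
    Minus-strand features are reversed so bin 0 is always the far upstream
    flank.  Each bin's value is weighted methylation pooled over all
    features (summed meth reads / summed total reads falling in the bin);
    bins with no coverage are NaN.  Features shorter than ``n_body_bins``
    bp are skipped (logged), as their body cannot fill the bins.

    Returns a vector of length ``2 * flank // flank_bin_size + n_body_bins``.
    """
    if not features:
        raise ValueError("features must be non-empty")
    if flank % flank_bin_size != 0:
        raise ValueError("flank must be a multiple of flank_bin_size")
    n_flank_bins = flank // flank_bin_size
    n_bins = 2 * n_flank_bins + n_body_bins
    meth = np.zeros(n_bins, dtype=float)
    total = np.zeros(n_bins, dtype=float)

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[df["context"] == context]
    by_chrom = {
        chrom: (
            sub["pos"].to_numpy() - 1,  # 0-based
            sub["count_meth"].to_numpy(),
            (sub["count_meth"] + sub["count_unmeth"]).to_numpy(),
        )
        for chrom, sub in df.sort_values("pos").groupby("chrom")
    }

    for feat in features:
        if feat.length < n_body_bins:
            logger.info("metaprofile: skipping %s (shorter than bin count)", feat.id)
            continue
        if feat.chrom not in by_chrom:
            continue
        pos0, m, t = by_chrom[feat.chrom]
        lo, hi = feat.start - flank, feat.end + flank
        i0, i1 = np.searchsorted(pos0, [lo, hi])
        if i0 == i1:
            continue
        p = pos0[i0:i1]
        pm, pt = m[i0:i1], t[i0:i1]
        bins = np.empty(p.shape, dtype=int)
        up = p < feat.start
        down = p >= feat.end
        body = ~(up | down)
        bins[up] = (p[up] - lo) // flank_bin_size
        frac = (p[body] - feat.start) / feat.length
        bins[body] = n_flank_bins + np.minimum(
            (frac * n_body_bins).astype(int), n_body_bins - 1
        )
        bins[down] = (
            n_flank_bins + n_body_bins + (p[down] - feat.end) // flank_bin_size
        )
        if feat.strand == "-":
            bins = n_bins - 1 - bins
        np.add.at(meth, bins, pm)
        np.add.at(total, bins, pt)

    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    return profile


# ---------------------------------------------------------------------------
# Tile table export

_TILE_COLS = ["chrom", "start", "end"] + [
    f"{c}_{x}" for c in CONTEXTS for x in ("n_cyt_total", "n_cyt_cov", "reads_meth", "reads_total")
]


def tiles_to_frame(tiles: Sequence[TileProfile]) -> pd.DataFrame:
    rows = []
    for t in tiles:
        row = [t.chrom, t.start, t.end]
        for c in CONTEXTS:
            row += [
                t.n_cyt_total.get(c, 0),
                t.n_cyt_cov.get(c, 0),
                t.reads_meth.get(c, 0),
                t.reads_total.get(c, 0),
            ]
        rows.append(row)
    df = pd.DataFrame(rows, columns=_TILE_COLS)
    for c in CONTEXTS:
        with np.errstate(invalid="ignore", divide="ignore"):
            df[f"{c}_level"] = np.where(
                df[f"{c}_reads_total"] > 0,
                df[f"{c}_reads_meth"] / df[f"{c}_reads_total"].replace(0, 1),
                np.nan,
            )
    return df


def frame_to_tiles(df: pd.DataFrame) -> list[TileProfile]:
    tiles = []
    for row in df.itertuples(index=False):
        t = TileProfile(row.chrom, int(row.start), int(row.end))
        for c in CONTEXTS:
            t.n_cyt_total[c] = int(getattr(row, f"{c}_n_cyt_total"))
            t.n_cyt_cov[c] = int(getattr(row, f"{c}_n_cyt_cov"))
            t.reads_meth[c] = int(getattr(row, f"{c}_reads_meth"))
            t.reads_total[c] = int(getattr(row, f"{c}_reads_total"))
        tiles.append(t)
    return tiles


def write_tile_table(tiles: Sequence[TileProfile], path) -> None:
    tiles_to_frame(tiles).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tile_table(path) -> list[TileProfile]:
    return frame_to_tiles(pd.read_csv(path, sep="\t"))
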