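"""Context-specific differential-methylation calling on fixed tiles.

Differential methylation between two samples is assessed per tile and per
sequence context, then maximal runs of adjacent, same-direction
differential tiles are collapsed into differentially methylated regions
(DMRs).  The filters are deliberately qualitative and conservative:

* both samples must cover the window adequately — at least
  ``min_cyt_cov`` cytosines with >=1 read and a mean depth per covered
  cytosine of at least ``min_depth``;
* CG and CHG windows are differential when the absolute difference in
  weighted methylation reaches ``diff_threshold`` (defaults 0.70 and
  0.50);
* CHH methylation is an order of magnitude lower, so CHH windows are
  differential when one sample is "low" (<= 5%) and the other "high"
  (>= 20%), with a higher cytosine-count requirement (8);
* a DMR needs at least ``min_consecutive`` (default 2) abutting
  differential windows of the same direction, so the minimum DMR size is
  ``min_consecutive * tile_size`` (200 bp at the defaults).

Two parameter presets are provided: ``results`` (the defaults above) and
``methods-strict`` (CG difference 0.80 and mean depth 10), reflecting the
two filter variants in circulation for this style of analysis.

Across pairwise sample comparisons, overlapping DMRs are reduced to a
non-redundant set by keeping the largest region in every chain of
transitively overlapping regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .io import CONTEXTS
from .tiling import TileProfile, weighted_methylation

#: Failure reason codes for windows that do not pass the DM filters.
FAIL_REASONS = ("no-data", "coverage", "cytosine-count", "effect-size")

PRESETS = ("results", "methods-strict")


@dataclass(frozen=True)
class DMParams:
    """Filter parameters for differential-methylation window calling."""

    context: str
    min_depth: float = 3.0          # mean reads per covered cytosine, per sample
    min_cyt_cov: int = 2            # covered cytosines per window, per sample
    diff_threshold: Optional[float] = 0.70  # |level_b - level_a|; None for CHH
    chh_low: float = 0.05
    chh_high: float = 0.20
    min_consecutive: int = 2
    tile_size: int = 100

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")
        for v in (self.diff_threshold, self.chh_low, self.chh_high):
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def for_context(cls, context: str, preset: str = "results") -> "DMParams":
        """Default parameters for a context under a named preset."""
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
        if context == "CG":
            p = cls(context="CG", diff_threshold=0.70, min_cyt_cov=2)
        elif context == "CHG":
            p = cls(context="CHG", diff_threshold=0.50, min_cyt_cov=2)
        elif context == "CHH":
            p = cls(context="CHH", diff_threshold=None, min_cyt_cov=8)
        else:
            raise ValueError(f"unknown context {context!r}")
        if preset == "methods-strict":
            p = replace(
                p,
                min_depth=10.0,
                diff_threshold=0.80 if context == "CG" else p.diff_threshold,
            )
        return p


@dataclass
class DMWindow:
    """One tile's differential-methylation comparison between two samples.

    ``direction`` is the state of sample B relative to sample A
    (``higher`` / ``lower``) and is defined only for passing windows.
    Read counts are carried so DMR-level pooled levels stay exact.
    """

    chrom: str
    start: int
    end: int
    context: str
    level_a: Optional[float]
    level_b: Optional[float]
    passed_filters: bool
    fail_reason: Optional[str] = None
    direction: Optional[str] = None
    reads_meth_a: int = 0
    reads_total_a: int = 0
    reads_meth_b: int = 0
    reads_total_b: int = 0


@dataclass
class DMR:
    """A collapsed differentially methylated region, 0-based half-open.

    ``levels`` maps line name to the pooled weighted methylation over the
    region (None where the line has no coverage); initially it holds the
    two lines of ``source_pair``.
    """

    chrom: str
    start: int
    end: int
    context: str
    direction: str
    source_pair: tuple
    levels: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def _window_side_ok(tile: Optional[TileProfile], params: DMParams):
    """Check one sample's coverage filters; returns (ok, fail_reason)."""
    c = params.context
    if tile is None or tile.reads_total.get(c, 0) == 0:
        return False, "no-data"
    if tile.n_cyt_cov.get(c, 0) < params.min_cyt_cov:
        return False, "cytosine-count"
    if tile.mean_depth(c) < params.min_depth:
        return False, "coverage"
    return True, None


def call_dm_windows(
    tiles_a: Sequence[TileProfile],
    tiles_b: Sequence[TileProfile],
    params: DMParams,
) -> list[DMWindow]:
    """Compare two tiled samples window by window for one context.

    Both samples must be tiled on the same grid.  Windows present in only
    one sample fail with reason ``no-data``.  The returned windows cover
    the union of both samples' tiles, sorted by (chrom, start).
    """
    c = params.context
    for tiles in (tiles_a, tiles_b):
        for t in tiles:
            if t.start % params.tile_size or t.end - t.start != params.tile_size:
                raise ValueError(
                    f"tile {t.chrom}:{t.start}-{t.end} not aligned to the "
                    f"{params.tile_size}-bp grid"
                )
    index_a = {(t.chrom, t.start): t for t in tiles_a}
    index_b = {(t.chrom, t.start): t for t in tiles_b}
    windows = []
    for key in sorted(set(index_a) | set(index_b)):
        ta, tb = index_a.get(key), index_b.get(key)
        chrom, start = key
        level_a = ta.level(c) if ta is not None else None
        level_b = tb.level(c) if tb is not None else None
        win = DMWindow(
            chrom=chrom,
            start=start,
            end=start + params.tile_size,
            context=c,
            level_a=level_a,
            level_b=level_b,
            passed_filters=False,
            reads_meth_a=ta.reads_meth.get(c, 0) if ta else 0,
            reads_total_a=ta.reads_total.get(c, 0) if ta else 0,
            reads_meth_b=tb.reads_meth.get(c, 0) if tb else 0,
            reads_total_b=tb.reads_total.get(c, 0) if tb else 0,
        )
        ok_a, reason_a = _window_side_ok(ta, params)
        ok_b, reason_b = _window_side_ok(tb, params)
        if not (ok_a and ok_b):
            win.fail_reason = reason_a if not ok_a else reason_b
            windows.append(win)
            continue
        if c == "CHH":
            lo, hi = min(level_a, level_b), max(level_a, level_b)
            differential = lo <= params.chh_low and hi >= params.chh_high
        else:
            differential = abs(level_b - level_a) >= params.diff_threshold
        if differential:
            win.passed_filters = True
            win.direction = "higher" if level_b > level_a else "lower"
        else:
            win.fail_reason = "effect-size"
        windows.append(win)
    return windows


def collapse_dmrs(
    windows: Sequence[DMWindow],
    params: DMParams,
    pair: tuple = ("A", "B"),
) -> list[DMR]:
    """Collapse runs of adjacent passing windows into DMRs.

    A run extends while consecutive passing windows abut exactly
    (``end_i == start_{i+1}`` on the same chromosome) and share a
    direction; a failing or absent window, a gap, or a direction flip
    breaks the run.  Runs shorter than ``min_consecutive`` windows are
    discarded, so every emitted DMR is at least
    ``min_consecutive * tile_size`` bp long.  Region levels for the two
    compared lines are pooled over the run's read counts.
    """
    keys = [(w.chrom, w.start) for w in windows]
    if keys != sorted(keys):
        raise ValueError("windows must be sorted by (chrom, start)")
    dmrs: list[DMR] = []
    run: list[DMWindow] = []

    def flush() -> None:
        if len(run) >= params.min_consecutive:
            ma = sum(w.reads_meth_a for w in run)
            ta = sum(w.reads_total_a for w in run)
            mb = sum(w.reads_meth_b for w in run)
            tb = sum(w.reads_total_b for w in run)
            dmrs.append(
                DMR(
                    chrom=run[0].chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    context=params.context,
                    direction=run[0].direction,
                    source_pair=tuple(pair),
                    levels={
                        pair[0]: weighted_methylation(ma, ta),
                        pair[1]: weighted_methylation(mb, tb),
                    },
                )
            )
        run.clear()

    for w in windows:
        if not w.passed_filters:
            flush()
            continue
        if run and (
            w.chrom != run[-1].chrom
            or w.start != run[-1].end
            or w.direction != run[-1].direction
        ):
            flush()
        run.append(w)
    flush()
    return dmrs


def call_dmrs(
    tiles_a: Sequence[TileProfile],
    tiles_b: Sequence[TileProfile],
    params: DMParams,
    pair: tuple = ("A", "B"),
) -> list[DMR]:
    """Convenience: window calling followed by collapsing."""
    return collapse_dmrs(call_dm_windows(tiles_a, tiles_b, params), params, pair)


def merge_pairwise(dmr_sets: Mapping[tuple, Sequence[DMR]]) -> list[DMR]:
    """Reduce DMRs from several pairwise comparisons to a non-redundant set.

    Within each chain of transitively overlapping (>=1 bp) DMRs, only the
    largest region is kept (ties: leftmost start, then source pair in
    alphabetical order).  The retained regions are mutually
    non-overlapping.  All inputs must share one context.
    """
    all_dmrs = [d for dmrs in dmr_sets.values() for d in dmrs]
    if not all_dmrs:
        return []
    contexts = {d.context for d in all_dmrs}
    if len(contexts) > 1:
        raise ValueError(f"mixed contexts in merge: {sorted(contexts)}")
    all_dmrs.sort(key=lambda d: (d.chrom, d.start, d.end))
    kept: list[DMR] = []
    component: list[DMR] = []
    comp_end = None

    def flush() -> None:
        if component:
            kept.append(
                min(component, key=lambda d: (-d.length, d.start, d.source_pair))
            )

    for d in all_dmrs:
        if component and (d.chrom != component[-1].chrom or d.start >= comp_end):
            flush()
            component = []
            comp_end = None
        component.append(d)
        comp_end = d.end if comp_end is None else max(comp_end, d.end)
    flush()
    return kept


def genotype_dmr_states(
    dmr: DMR, samples: Mapping[str, Sequence[TileProfile]]
) -> dict:
    """Pooled weighted methylation over the DMR span for every line.

    For each line, sums the read counts of its tiles falling inside
    ``[dmr.start, dmr.end)`` for the DMR's context; a line with no reads
    there is undefined (None).
    """
    out = {}
    for line, tiles in samples.items():
        meth = total = 0
        for t in tiles:
            if t.chrom == dmr.chrom and t.start >= dmr.start and t.end <= dmr.end:
                meth += t.reads_meth.get(dmr.context, 0)
                total += t.reads_total.get(dmr.context, 0)
        out[line] = weighted_methylation(meth, total)
    return out


def intersect_dmr_sets(set_a: Sequence[DMR], set_b: Sequence[DMR]) -> dict:
    """Per-side overlap tally between two DMR sets (>=1 bp intersection).

    Returns a dict with ``a_only``, ``b_only``, ``a_overlap`` and
    ``b_overlap`` counts; each DMR is counted once on its own side.
    """
    for d in list(set_a) + list(set_b):
        if d.context != (set_a[0].context if set_a else set_b[0].context):
            raise ValueError("intersect_dmr_sets requires a single context")

    def overlaps_any(d: DMR, others: Sequence[DMR]) -> bool:
        return any(
            o.chrom == d.chrom and o.start < d.end and d.start < o.end for o in others
        )

    a_overlap = sum(overlaps_any(d, set_b) for d in set_a)
    b_overlap = sum(overlaps_any(d, set_a) for d in set_b)
    return {
        "a_only": len(set_a) - a_overlap,
        "b_only": len(set_b) - b_overlap,
        "a_overlap": a_overlap,
        "b_overlap": b_overlap,
    }


def write_dmr_bed(dmrs: Sequence[DMR], path) -> None:
    """Write DMRs as BED6+ (name=context:pair, score=|Δlevel|x1000 capped)."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        for d in sorted(dmrs, key=lambda d: (d.chrom, d.start)):
            a, b = d.source_pair
            la, lb = d.levels.get(a), d.levels.get(b)
            delta = abs((lb or 0.0) - (la or 0.0))
            score = min(1000, int(round(delta * 1000)))
            levels_s = ",".join(
                f"{line}={'' if lvl is None else f'{lvl:.4f}'}"
                for line, lvl in sorted(d.levels.items())
            )
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.context}:{a}-{b}\t{score}\t.\t"
                f"{d.direction}\t{levels_s}\n"
            )
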