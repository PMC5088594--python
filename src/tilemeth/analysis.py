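"""Association analyses downstream of DMR calling.

Covers five analyses that relate methylation variation to genetic
variation between inbred lines:

* hierarchical clustering of per-line DMR methylation states;
* pairwise SNP mismatch distances and a neighbor-joining tree;
* correlation of DMR density with SNP density in large genomic bins;
* proximity of DMRs to TE insertion/deletion polymorphisms, with a
  seeded permutation null (an extension over raw proximity counts);
* per-site replicate correlation with minimum-depth filtering.

Neighbor joining is implemented here (Saitou–Nei agglomeration with the
Studier–Keppler Q criterion and a smallest-index-pair tie-break) so that
additive distance matrices are recovered exactly and the output is
deterministic; trees are returned as :class:`skbio.TreeNode` and
serialise to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import pearsonr
from skbio import TreeNode

from .dmr import DMR
from .io import SNPRecord, TEPolymorphism

__all__ = [
    "Dendrogram",
    "cluster_dmr_states",
    "snp_distance_matrix",
    "neighbor_joining",
    "random_additive_tree",
    "density_correlation",
    "te_dmr_proximity",
    "ProximityResult",
    "replicate_correlation",
]


# ---------------------------------------------------------------------------
# DMR-state clustering


@dataclass
class Dendrogram:
    """Average-linkage dendrogram over lines.

    ``linkage`` is a scipy linkage matrix; ``labels`` the line names in
    column order; ``nested`` a nested-tuple rendering ``((A, B), C)`` of
    the topology with merge heights available from ``linkage``.
    """

    linkage: np.ndarray
    labels: list
    nested: tuple


def _pairwise_complete_euclidean(mat: np.ndarray) -> np.ndarray:
    """Euclidean distance over rows ignoring missing entries.

    For each pair, squared differences are summed over entries complete in
    both rows and rescaled by ``n_total / n_complete`` so sparsely shared
    pairs are not biased short.
    """
    n, p = mat.shape
    dist = np.zeros((n, n))
    present = ~np.isnan(mat)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            n_complete = int(both.sum())
            if n_complete == 0:
                raise ValueError(
                    "no complete observations shared between two lines"
                )
            sq = np.sum((mat[i, both] - mat[j, both]) ** 2)
            dist[i, j] = dist[j, i] = np.sqrt(sq * p / n_complete)
    return dist


def cluster_dmr_states(matrix: pd.DataFrame) -> Dendrogram:
    """Cluster lines by their DMR methylation-level profiles.

    ``matrix`` has DMR ids as rows and line names as columns; values are
    weighted levels in [0, 1] with NaN for missing.  Distance is
    pairwise-complete Euclidean (scaled by sqrt(n_total/n_complete));
    linkage is average.  Columns are ordered by name first so ties break
    deterministically.  A line with no observed values is an error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 lines to cluster")
    matrix = matrix[sorted(matrix.columns)]
    values = matrix.to_numpy(dtype=float).T  # lines x DMRs
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        bad = [c for c, m in zip(matrix.columns, all_missing) if m]
        raise ValueError(f"line(s) with all-missing values: {bad}")
    dist = _pairwise_complete_euclidean(values)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = sch.linkage(condensed, method="average")
    labels = list(matrix.columns)

    def build(node) -> object:
        if node.is_leaf():
            return labels[node.id]
        return (build(node.get_left()), build(node.get_right()))

    nested = build(sch.to_tree(linkage))
    return Dendrogram(linkage=linkage, labels=labels, nested=nested)


# ---------------------------------------------------------------------------
# SNP distances and neighbor joining


def snp_distance_matrix(
    snps: Sequence[SNPRecord], lines: Sequence[str]
) -> pd.DataFrame:
    """Pairwise mismatch proportions over SNPs called in *all* lines.

    Sites with a missing call in any requested line are excluded, then
    ``d(i, j)`` is the fraction of used sites where the two lines' calls
    (reference vs alternate) differ.
    """
    lines = list(lines)
    rows = []
    for s in snps:
        calls = [s.calls.get(ln, "missing") for ln in lines]
        if "missing" in calls:
            continue
        rows.append([1 if c == "alternate" else 0 for c in calls])
    if not rows:
        raise ValueError("no SNP has calls for all requested lines")
    mat = np.asarray(rows)  # sites x lines
    n_sites = mat.shape[0]
    diff = (mat[:, :, None] != mat[:, None, :]).sum(axis=0) / n_sites
    return pd.DataFrame(diff, index=lines, columns=lines)


def neighbor_joining(dist, labels: Optional[Sequence[str]] = None) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou–Nei agglomeration: at each step the pair (i, j)
    minimising ``Q_ij = (n - 2) d_ij - r_i - r_j`` is joined, with ties
    broken by the smallest index pair; branch lengths follow the usual
    two-point formulas and the three-taxon remainder is resolved in
    closed form.  Additive distance matrices are recovered exactly (the
    tree's tip-to-tip path lengths equal the input distances).  Returns
    an unrooted tree as a trifurcating-root :class:`skbio.TreeNode`.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = list(dist.columns)
        dist = dist.to_numpy(dtype=float)
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    nodes = [TreeNode(name=str(lbl)) for lbl in labels]

    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) in row-major order
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        last_col = np.append(new_d[keep], 0.0)
        d = np.hstack([d, last_col[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        n -= 1

    # closed-form resolution of the final three nodes around the root
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
        root.append(node)
    return root


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator
) -> tuple[TreeNode, pd.DataFrame]:
    """Random binary tree with positive branch lengths and its path-distance matrix.

    Useful for validating distance-based tree reconstruction: the matrix
    of tip-to-tip path lengths of any tree is additive, so neighbor
    joining must recover both topology and branch lengths exactly.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-star, then attach remaining tips to random edges
    tree = TreeNode()
    tips = {}
    for lbl in labels[:3]:
        tip = TreeNode(name=lbl, length=rng.uniform(0.5, 2.0))
        tree.append(tip)
        tips[lbl] = tip
    for lbl in labels[3:]:
        # attach the new tip to a uniformly chosen existing edge
        candidates = [t for t in tree.traverse() if t is not tree]
        edge = candidates[rng.integers(len(candidates))]
        split = rng.uniform(0.2, 0.8) * edge.length
        stem = rng.uniform(0.5, 2.0)
        parent = edge.parent
        joint = TreeNode(length=edge.length - split)
        parent.remove(edge)
        edge.length = split
        joint.append(edge)
        new_tip = TreeNode(name=lbl, length=stem)
        joint.append(new_tip)
        parent.append(joint)
        tips[lbl] = new_tip
    dm = tree.tip_tip_distances()
    mat = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    mat = mat.loc[labels, labels]
    return tree, mat


# ---------------------------------------------------------------------------
# DMR density vs SNP density


def density_correlation(
    dmrs: Sequence[DMR],
    snps: Sequence[SNPRecord],
    bin_size: int,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[pd.DataFrame, float]:
    """Bin DMR and SNP counts genome-wide and correlate them.

    Bins are non-overlapping, tiled from position 0 on each chromosome
    (1 Mb is conventional for CG/CHG DMR sets, 5 Mb for the sparser CHH
    sets).  A DMR is assigned to the bin containing its midpoint; SNPs by
    position.  The squared Pearson correlation is computed over bins with
    at least one SNP or one DMR; fewer than 3 usable bins is an error.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    ends: dict[str, int] = dict(chrom_lengths or {})
    for d in dmrs:
        ends[d.chrom] = max(ends.get(d.chrom, 0), d.end)
    for s in snps:
        ends[s.chrom] = max(ends.get(s.chrom, 0), s.pos)
    counts: dict[tuple, list] = {}
    for chrom, length in ends.items():
        for b in range(int(np.ceil(length / bin_size))):
            counts[(chrom, b)] = [0, 0]  # [snp_count, dmr_count]
    for s in snps:
        counts[(s.chrom, (s.pos - 1) // bin_size)][0] += 1
    for d in dmrs:
        mid = (d.start + d.end) // 2
        counts[(d.chrom, mid // bin_size)][1] += 1
    rows = [
        (chrom, b * bin_size, (b + 1) * bin_size, snp, dmr)
        for (chrom, b), (snp, dmr) in sorted(counts.items())
    ]
    bins = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "snp_count", "dmr_count"]
    )
    usable = bins[(bins.snp_count > 0) | (bins.dmr_count > 0)]
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} usable bins; need >= 3")
    x = usable.snp_count.to_numpy(dtype=float)
    y = usable.dmr_count.to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(pearsonr(x, y)[0] ** 2)
    return bins, r2


# ---------------------------------------------------------------------------
# TE-polymorphism proximity


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two half-open intervals (0 when they touch or overlap)."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


@dataclass
class ProximityResult:
    """Counts of DMRs near TE insertion/deletion polymorphisms.

    "Near" means an interval distance of at most ``window`` bp.  The
    direction tallies restrict to indels carried by the DMR's non-reference
    line: ``hyper`` counts DMRs where that line is the higher-methylated
    one.  The permutation p-values (an extension over raw counts) come
    from re-drawing DMR positions uniformly within their chromosome.
    """

    window: int
    n_insertions: int
    n_deletions: int
    n_dmrs: int
    near_insertion: int
    near_deletion: int
    near_any: int
    hyper_near_insertion: int = 0
    hypo_near_insertion: int = 0
    hyper_near_deletion: int = 0
    hypo_near_deletion: int = 0
    p_insertion: Optional[float] = None
    p_deletion: Optional[float] = None
    p_any: Optional[float] = None
    n_perm: int = 0


def _near_counts(
    starts: np.ndarray,
    ends: np.ndarray,
    chroms: np.ndarray,
    te_by_chrom: Mapping[str, tuple],
    window: int,
) -> np.ndarray:
    """Boolean near-flag per DMR against one set of TE intervals."""
    near = np.zeros(starts.shape[0], dtype=bool)
    for chrom, (tc, td) in te_by_chrom.items():
        mask = chroms == chrom
        if not mask.any() or tc.size == 0:
            continue
        s, e = starts[mask], ends[mask]
        gap = np.maximum(
            0,
            np.maximum(s[:, None], tc[None, :]) - np.minimum(e[:, None], td[None, :]),
        )
        near[mask] = (gap <= window).any(axis=1)
    return near


def _two_sided_empirical_p(obs: float, null: np.ndarray) -> float:
    n = null.size
    p_ge = (1 + int((null >= obs).sum())) / (n + 1)
    p_le = (1 + int((null <= obs).sum())) / (n + 1)
    return min(1.0, 2.0 * min(p_ge, p_le))


def te_dmr_proximity(
    dmrs: Sequence[DMR],
    tes: Sequence[TEPolymorphism],
    window: int = 500,
    n_perm: int = 0,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    seed: Optional[int] = None,
) -> ProximityResult:
    """Count DMRs lying within ``window`` bp of TE indel polymorphisms.

    Direction tallies pair each DMR with indels carried by its
    non-reference line (``source_pair[1]``).  With ``n_perm > 0``, DMR
    positions are re-drawn uniformly within their chromosome (lengths
    preserved) and two-sided empirical p-values are attached for the
    near-insertion, near-deletion and near-any counts.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    dmrs = list(dmrs)
    ins = [t for t in tes if t.type == "insertion"]
    dels = [t for t in tes if t.type == "deletion"]

    def group(te_list):
        out: dict[str, tuple] = {}
        for chrom in {t.chrom for t in te_list}:
            sub = [t for t in te_list if t.chrom == chrom]
            out[chrom] = (
                np.array([t.start for t in sub]),
                np.array([t.end for t in sub]),
            )
        return out

    ins_idx, del_idx = group(ins), group(dels)
    starts = np.array([d.start for d in dmrs], dtype=int)
    ends = np.array([d.end for d in dmrs], dtype=int)
    chroms = np.array([d.chrom for d in dmrs])

    near_ins = _near_counts(starts, ends, chroms, ins_idx, window)
    near_del = _near_counts(starts, ends, chroms, del_idx, window)

    result = ProximityResult(
        window=window,
        n_insertions=len(ins),
        n_deletions=len(dels),
        n_dmrs=len(dmrs),
        near_insertion=int(near_ins.sum()),
        near_deletion=int(near_del.sum()),
        near_any=int((near_ins | near_del).sum()),
    )

    # direction tallies, restricted to indels carried by the DMR's alt line
    for kind, te_list, which in (
        ("insertion", ins, "near_insertion"),
        ("deletion", dels, "near_deletion"),
    ):
        hyper = hypo = 0
        for d in dmrs:
            alt = d.source_pair[1] if len(d.source_pair) > 1 else None
            carried = [t for t in te_list if alt in t.lines and t.chrom == d.chrom]
            if not carried:
                continue
            if any(
                interval_distance(d.start, d.end, t.start, t.end) <= window
                for t in carried
            ):
                if d.direction == "higher":
                    hyper += 1
                else:
                    hypo += 1
        if kind == "insertion":
            result.hyper_near_insertion, result.hypo_near_insertion = hyper, hypo
        else:
            result.hyper_near_deletion, result.hypo_near_deletion = hyper, hypo

    if n_perm > 0 and dmrs:
        lengths: dict[str, int] = dict(chrom_lengths or {})
        for arr_chrom, end in zip(chroms, ends):
            lengths[arr_chrom] = max(lengths.get(arr_chrom, 0), int(end))
        for t in tes:
            lengths[t.chrom] = max(lengths.get(t.chrom, 0), t.end)
        rng = np.random.default_rng(seed)
        sizes = ends - starts
        max_start = np.array([lengths[c] for c in chroms]) - sizes
        null_ins = np.empty(n_perm)
        null_del = np.empty(n_perm)
        null_any = np.empty(n_perm)
        for k in range(n_perm):
            perm_starts = (rng.random(len(dmrs)) * np.maximum(max_start, 1)).astype(int)
            perm_ends = perm_starts + sizes
            pi = _near_counts(perm_starts, perm_ends, chroms, ins_idx, window)
            pdl = _near_counts(perm_starts, perm_ends, chroms, del_idx, window)
            null_ins[k] = pi.sum()
            null_del[k] = pdl.sum()
            null_any[k] = (pi | pdl).sum()
        result.p_insertion = _two_sided_empirical_p(result.near_insertion, null_ins)
        result.p_deletion = _two_sided_empirical_p(result.near_deletion, null_del)
        result.p_any = _two_sided_empirical_p(result.near_any, null_any)
        result.n_perm = n_perm
    return result


# ---------------------------------------------------------------------------
# Replicate correlation


def replicate_correlation(
    rep_a,
    rep_b,
    context: str,
    min_depth: int = 1,
) -> tuple[Optional[float], int]:
    """Squared Pearson correlation of per-site levels between two replicates.

    A site is used when it is present with at least ``min_depth`` total
    reads in *both* replicates.  Returns ``(r_squared, n_sites)``;
    ``r_squared`` is None when either replicate's levels have zero
    variance over the used sites.  Raising the depth floor trades sites
    for per-site precision, which matters most for the low-level CHH
    context.
    """
    from .io import records_to_frame

    frames = []
    for rep in (rep_a, rep_b):
        df = rep if isinstance(rep, pd.DataFrame) else records_to_frame(rep)
        df = df[df["context"] == context].copy()
        df["depth"] = df["count_meth"] + df["count_unmeth"]
        frames.append(df[["chrom", "pos", "count_meth", "depth"]])
    merged = frames[0].merge(
        frames[1], on=["chrom", "pos"], suffixes=("_a", "_b")
    )
    merged = merged[
        (merged.depth_a >= min_depth) & (merged.depth_b >= min_depth)
    ]
    n_sites = len(merged)
    if n_sites == 0:
        raise ValueError("no site passes the depth filter in both replicates")
    la = merged.count_meth_a / merged.depth_a
    lb = merged.count_meth_b / merged.depth_b
    if la.std() == 0 or lb.std() == 0:
        return None, n_sites
    r = float(pearsonr(la, lb)[0])
    return r * r, n_sites
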