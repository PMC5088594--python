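"""Clustering, NJ trees, density correlation, TE proximity, replicate correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tilemeth import analysis
from tilemeth.dmr import DMR
from tilemeth.io import SNPRecord, TEPolymorphism
from tilemeth.tiling import TileProfile


# ---------------------------------------------------------------------------
# hierarchical clustering


def brute_force_average_linkage(dist, labels):
    """O(n^3) agglomeration oracle: cluster distance is the mean of the
    original pairwise distances between members (UPGMA/average linkage)."""
    label_index = {lbl: i for i, lbl in enumerate(labels)}

    def cdist(ca, cb):
        return float(
            np.mean([dist[label_index[a]][label_index[b]] for a in ca for b in cb])
        )

    clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        (i, j), _ = min(
            (
                ((a, b), cdist(clusters[a], clusters[b]))
                for a in clusters
                for b in clusters
                if a < b
            ),
            key=lambda kv: (kv[1], kv[0]),
        )
        merged = clusters.pop(i) | clusters.pop(j)
        merges.append(merged)
        clusters[next_id] = merged
        next_id += 1
    return merges


def merge_sets(dend, labels):
    """Cluster membership sets in merge order from a scipy linkage matrix."""
    sets = {i: frozenset([lbl]) for i, lbl in enumerate(labels)}
    out = []
    n = len(labels)
    for k, (a, b, _h, _c) in enumerate(dend.linkage):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + k] = merged
        out.append(merged)
    return out


class TestClusterDmrStates:
    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        col = rng.random(30)
        mat = pd.DataFrame({"A": col, "B": col, "C": rng.random(30)})
        dend = analysis.cluster_dmr_states(mat)
        first = merge_sets(dend, dend.labels)[0]
        assert first == frozenset({"A", "B"})
        assert dend.linkage[0, 2] == pytest.approx(0.0)

    def test_opposite_line_is_outgroup(self):
        col = np.linspace(0, 1, 25)
        mat = pd.DataFrame({"A": col, "B": col, "C": 1 - col})
        dend = analysis.cluster_dmr_states(mat)
        assert dend.nested in ((("A", "B"), "C"), ("C", ("A", "B")))

    def test_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mat = pd.DataFrame(
                rng.random((20, 4)), columns=["w", "x", "y", "z"]
            )
            dend = analysis.cluster_dmr_states(mat)
            dist = analysis._pairwise_complete_euclidean(
                mat[sorted(mat.columns)].to_numpy().T
            )
            oracle = brute_force_average_linkage(dist.tolist(), dend.labels)
            assert merge_sets(dend, dend.labels) == oracle

    def test_missing_values_use_pairwise_complete_scaling(self):
        mat = pd.DataFrame(
            {"A": [0.0, 1.0, np.nan, 0.5], "B": [0.0, 0.0, 0.2, np.nan]}
        )
        dend = analysis.cluster_dmr_states(mat)
        # entries 0 and 1 are complete in both: d = sqrt(1 * 4/2)
        assert dend.linkage[0, 2] == pytest.approx(np.sqrt(2.0))

    def test_all_missing_line_rejected(self):
        mat = pd.DataFrame({"A": [0.1, 0.2], "B": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="all-missing"):
            analysis.cluster_dmr_states(mat)


# ---------------------------------------------------------------------------
# SNP distances


def snp(pos, calls, chrom="c1"):
    return SNPRecord(chrom, pos, calls)


class TestSnpDistanceMatrix:
    def test_identical_lines(self):
        snps = [snp(i, {"a": "alternate", "b": "alternate"}) for i in range(1, 11)]
        d = analysis.snp_distance_matrix(snps, ["a", "b"])
        assert d.loc["a", "b"] == 0.0

    def test_complementary_lines(self):
        snps = [snp(i, {"a": "reference", "b": "alternate"}) for i in range(1, 11)]
        d = analysis.snp_distance_matrix(snps, ["a", "b"])
        assert d.loc["a", "b"] == 1.0

    def test_mismatch_proportion(self):
        calls = ["alternate"] * 3 + ["reference"] * 9
        snps = [
            snp(i + 1, {"a": "reference", "b": c}) for i, c in enumerate(calls)
        ]
        d = analysis.snp_distance_matrix(snps, ["a", "b"])
        assert d.loc["a", "b"] == pytest.approx(0.25)

    def test_sites_with_missing_calls_excluded(self):
        snps = [
            snp(1, {"a": "reference", "b": "alternate"}),
            snp(2, {"a": "missing", "b": "alternate"}),  # dropped
        ]
        d = analysis.snp_distance_matrix(snps, ["a", "b"])
        assert d.loc["a", "b"] == 1.0

    def test_no_usable_sites(self):
        snps = [snp(1, {"a": "missing", "b": "alternate"})]
        with pytest.raises(ValueError):
            analysis.snp_distance_matrix(snps, ["a", "b"])


# ---------------------------------------------------------------------------
# neighbor joining


def path_distances(tree):
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # quartet ((A:1,B:2):5,(C:3,D:4)); the spec'd branch lengths
        labels = ["A", "B", "C", "D"]
        d = pd.DataFrame(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
            index=labels, columns=labels, dtype=float,
        )
        tree = analysis.neighbor_joining(d)
        got = path_distances(tree).loc[labels, labels]
        assert np.allclose(got.to_numpy(), d.to_numpy())
        # topology: A,B adjacent (3-edge path), A,C not
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].parent is tips["B"].parent
        assert tips["A"].parent is not tips["C"].parent

    def test_three_taxa_closed_form(self):
        labels = ["x", "y", "z"]
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=labels, columns=labels,
            dtype=float,
        )
        tree = analysis.neighbor_joining(d)
        lens = {t.name: t.length for t in tree.tips()}
        assert lens == pytest.approx({"x": 1.0, "y": 2.0, "z": 3.0})

    def test_random_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(11)
        for n in (4, 5, 6, 7, 8):
            for _ in range(4):
                _, d = analysis.random_additive_tree(n, rng)
                tree = analysis.neighbor_joining(d)
                got = path_distances(tree).loc[d.index, d.columns]
                assert np.allclose(got.to_numpy(), d.to_numpy(), atol=1e-9)

    def test_matches_reference_nj_topology(self):
        """Cross-check against scikit-bio's independent NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(5)
        for _ in range(5):
            _, d = analysis.random_additive_tree(6, rng)
            ours = analysis.neighbor_joining(d)
            ref = nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
            assert ours.compare_rfd(ref) == 0.0

    def test_tie_break_deterministic(self):
        labels = list("abcd")
        d = pd.DataFrame(1.0, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        t1 = analysis.neighbor_joining(d)
        t2 = analysis.neighbor_joining(d)
        assert str(t1) == str(t2)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            analysis.neighbor_joining(d)


# ---------------------------------------------------------------------------
# density correlation


def mk_dmr(start, end, chrom="c1", direction="higher", pair=("r", "a")):
    return DMR(chrom, start, end, "CG", direction, pair)


class TestDensityCorrelation:
    def test_perfect_proportionality(self):
        dmrs, snps = [], []
        for b, n in enumerate([1, 2, 3, 4, 5]):
            for i in range(n):
                snps.append(snp(b * 1000 + 10 * i + 1, {"a": "alternate"}))
            for i in range(2 * n):
                start = b * 1000 + 20 * i
                dmrs.append(mk_dmr(start, start + 10))
        bins, r2 = analysis.density_correlation(dmrs, snps, bin_size=1000)
        assert r2 == pytest.approx(1.0)
        assert (bins.dmr_count == 2 * bins.snp_count).all()

    def test_constant_dmr_count_gives_zero(self):
        snps = []
        for b in range(5):
            for i in range(b + 1):
                snps.append(snp(b * 1000 + i + 1, {"a": "alternate"}))
        dmrs = [mk_dmr(b * 1000, b * 1000 + 10) for b in range(5)]
        _, r2 = analysis.density_correlation(dmrs, snps, bin_size=1000)
        assert r2 == 0.0

    def test_midpoint_bin_assignment(self):
        # DMR [900, 1300) has midpoint 1100 -> second bin
        dmrs = [mk_dmr(900, 1300)]
        snps = [snp(p, {"a": "alternate"}) for p in (100, 1100, 2100)]
        bins, _ = analysis.density_correlation(dmrs, snps, bin_size=1000)
        assert bins.loc[1, "dmr_count"] == 1 and bins.loc[0, "dmr_count"] == 0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            analysis.density_correlation(
                [mk_dmr(0, 100)], [snp(1, {"a": "alternate"})], bin_size=10_000
            )

    def test_recovers_generating_correlation(self):
        """Counts sampled around correlated rates recover the rate correlation."""
        rng = np.random.default_rng(2024)
        n_bins = 50
        base = rng.gamma(5.0, 1.0, size=n_bins)
        snp_rate = 400 * base
        dmr_rate = 30 * base * np.exp(rng.normal(0, 0.15, size=n_bins))
        generating_r2 = np.corrcoef(snp_rate, dmr_rate)[0, 1] ** 2
        snps, dmrs = [], []
        for b in range(n_bins):
            for i in range(rng.poisson(snp_rate[b])):
                snps.append(snp(b * 100_000 + i + 1, {"a": "alternate"}))
            for i in range(rng.poisson(dmr_rate[b])):
                start = b * 100_000 + 50 * i
                dmrs.append(mk_dmr(start, start + 20))
        _, r2 = analysis.density_correlation(dmrs, snps, bin_size=100_000)
        assert abs(r2 - generating_r2) <= 0.1

    def test_r2_in_unit_interval_and_order_invariant(self):
        rng = np.random.default_rng(3)
        snps = [snp(int(p) + 1, {"a": "alternate"})
                for p in rng.integers(0, 10_000, 200)]
        dmrs = [mk_dmr(int(s), int(s) + 50) for s in rng.integers(0, 9_900, 40)]
        _, r2 = analysis.density_correlation(dmrs, snps, bin_size=1000)
        _, r2_shuffled = analysis.density_correlation(
            dmrs[::-1], snps[::-1], bin_size=1000
        )
        assert 0.0 <= r2 <= 1.0 and r2 == pytest.approx(r2_shuffled)


# ---------------------------------------------------------------------------
# TE proximity


def te(start, end, type_="insertion", lines=("a",), chrom="c1", family="DTT"):
    return TEPolymorphism(chrom, start, end, type_, family, frozenset(lines))


class TestTeDmrProximity:
    def test_within_window_is_near(self):
        res = analysis.te_dmr_proximity(
            [mk_dmr(1000, 1200)], [te(1500, 1500)], window=500
        )
        assert res.near_insertion == 1 and res.near_any == 1

    def test_just_beyond_window_is_not_near(self):
        res = analysis.te_dmr_proximity(
            [mk_dmr(1000, 1200)], [te(1701, 1701)], window=500
        )
        assert res.near_insertion == 0

    def test_interval_distance_symmetric(self):
        assert analysis.interval_distance(0, 10, 20, 30) == analysis.interval_distance(
            20, 30, 0, 10
        ) == 10
        assert analysis.interval_distance(0, 10, 5, 30) == 0

    def test_direction_tallies_restricted_to_carrier(self):
        dmrs = [mk_dmr(1000, 1200, pair=("r", "a"), direction="higher")]
        near_but_other_line = [te(1300, 1300, lines=("b",))]
        res = analysis.te_dmr_proximity(dmrs, near_but_other_line, window=500)
        assert res.hyper_near_insertion == 0
        res2 = analysis.te_dmr_proximity(dmrs, [te(1300, 1300, lines=("a",))],
                                         window=500)
        assert res2.hyper_near_insertion == 1

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            analysis.te_dmr_proximity([], [], window=-1)

    def test_permutation_p_in_unit_interval(self):
        rng = np.random.default_rng(9)
        dmrs = [mk_dmr(int(s), int(s) + 200) for s in rng.integers(0, 90_000, 20)]
        tes = [te(int(p), int(p), lines=("a",)) for p in rng.integers(0, 90_000, 15)]
        res = analysis.te_dmr_proximity(
            dmrs, tes, window=500, n_perm=99,
            chrom_lengths={"c1": 100_000}, seed=1,
        )
        for p in (res.p_insertion, res.p_deletion, res.p_any):
            assert 0.0 < p <= 1.0

    def test_seeded_permutations_reproducible(self):
        dmrs = [mk_dmr(5_000, 5_200), mk_dmr(20_000, 20_300)]
        tes = [te(6_000, 6_000), te(50_000, 50_400, "deletion")]
        kwargs = dict(window=500, n_perm=50, chrom_lengths={"c1": 60_000}, seed=7)
        r1 = analysis.te_dmr_proximity(dmrs, tes, **kwargs)
        r2 = analysis.te_dmr_proximity(dmrs, tes, **kwargs)
        assert (r1.p_insertion, r1.p_deletion) == (r2.p_insertion, r2.p_deletion)


# ---------------------------------------------------------------------------
# replicate correlation


def cx_frame(levels, depth, rng, context="CHH"):
    n = len(levels)
    d = rng.poisson(depth, size=n)
    m = rng.binomial(d, levels)
    return pd.DataFrame(
        {
            "chrom": "c1",
            "pos": np.arange(1, n + 1),
            "strand": "+",
            "count_meth": m,
            "count_unmeth": d - m,
            "context": context,
            "trinucleotide": "CAT",
        }
    )


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        rng = np.random.default_rng(0)
        a = cx_frame(rng.beta(1, 6, 500), 10, rng)
        a = a[a.count_meth + a.count_unmeth > 0]
        r2, n = analysis.replicate_correlation(a, a.copy(), "CHH")
        assert r2 == pytest.approx(1.0)
        assert n == len(a)

    def test_anticorrelated_replicates_have_r2_one(self):
        rng = np.random.default_rng(1)
        a = cx_frame(rng.beta(2, 2, 300), 50, rng)
        b = a.copy()
        b["count_meth"], b["count_unmeth"] = a["count_unmeth"], a["count_meth"]
        keep = (a.count_meth + a.count_unmeth) > 0
        r2, _ = analysis.replicate_correlation(a[keep], b[keep], "CHH")
        assert r2 == pytest.approx(1.0)

    def test_site_count_monotone_in_depth_filter(self):
        rng = np.random.default_rng(2)
        means = rng.beta(1, 6, 2000)
        a = cx_frame(means, 8, rng)
        b = cx_frame(means, 8, rng)
        counts = [
            analysis.replicate_correlation(a, b, "CHH", min_depth=k)[1]
            for k in (1, 5, 10)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_r2_improves_with_depth_filter_on_noisy_replicates(self):
        """Beta-binomial replicates: deeper sites estimate the common
        per-site mean better, so r^2 should trend upward with min_depth."""
        rng = np.random.default_rng(3)
        n = 6000
        means = rng.beta(0.8, 5.0, n)
        frames = []
        for _ in range(2):
            noisy = rng.beta(means * 12, (1 - means) * 12)
            frames.append(cx_frame(noisy, 9, rng))
        r2_lo, _ = analysis.replicate_correlation(frames[0], frames[1], "CHH", 1)
        r2_hi, _ = analysis.replicate_correlation(frames[0], frames[1], "CHH", 12)
        assert r2_hi > r2_lo

    def test_no_qualifying_sites(self):
        rng = np.random.default_rng(4)
        a = cx_frame(rng.beta(1, 6, 10), 2, rng)
        b = cx_frame(rng.beta(1, 6, 10), 2, rng)
        with pytest.raises(ValueError):
            analysis.replicate_correlation(a, b, "CHH", min_depth=100)

    def test_zero_variance_returns_undefined(self):
        df = pd.DataFrame(
            {
                "chrom": "c1", "pos": [1, 2, 3], "strand": "+",
                "count_meth": [0, 0, 0], "count_unmeth": [5, 5, 5],
                "context": "CG", "trinucleotide": "CGA",
            }
        )
        r2, n = analysis.replicate_correlation(df, df.copy(), "CG")
        assert r2 is None and n == 3
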