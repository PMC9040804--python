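"""Superset clustering, matrix statistics, rank-sum tests, positional KDE."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import termends as te
from termends.annotate import NormalizedPeak
from termends.compare import (PeakMatrix, _permutation_ranksum_p, venn_frame)
from termends.peaks import Peak, CvTrack


def _npeak(coord, strand="+", height=20.0, gene="g1", norm=1.0):
    return NormalizedPeak(Peak(coord, strand, height), gene, "cds", norm)


def brute_force_single_linkage(coords, tol):
    """Union-find over all coordinate pairs with |a-b| <= tol."""
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(coords)), 2):
        if abs(coords[i] - coords[j]) <= tol:
            parent[find(i)] = find(j)
    groups = {}
    for i, c in enumerate(coords):
        groups.setdefault(find(i), []).append(c)
    return sorted(sorted(g) for g in groups.values())


class TestBuildSuperset:
    def test_within_five_nt_is_one_end(self):
        clusters = te.build_superset(
            {"A": [_npeak(100)], "B": [_npeak(104)]}, tol=5)
        assert len(clusters) == 1
        assert set(clusters[0].members) == {"A", "B"}

    def test_beyond_five_nt_is_two_ends(self):
        clusters = te.build_superset(
            {"A": [_npeak(100)], "B": [_npeak(106)]}, tol=5)
        assert len(clusters) == 2

    def test_representative_is_max_cv_tie_three_prime(self):
        clusters = te.build_superset(
            {"A": [_npeak(100, height=30)], "B": [_npeak(103, height=30)]})
        assert clusters[0].representative == 103  # tie -> 3'-most on +
        clusters = te.build_superset(
            {"A": [_npeak(100, strand="-", height=30)],
             "B": [_npeak(103, strand="-", height=30)]})
        assert clusters[0].representative == 100  # 3'-most on -

    def test_partition_matches_brute_force_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            coords = sorted(set(rng.integers(1, 200, size=10).tolist()))
            heights = {c: float(rng.integers(10, 99)) for c in coords}
            peaks = {f"S{i}": [_npeak(c, height=heights[c])]
                     for i, c in enumerate(coords)}
            clusters = te.build_superset(peaks, tol=5)
            got = sorted(sorted(p.coordinate for p in c.members.values())
                         for c in clusters)
            assert got == brute_force_single_linkage(coords, 5)

    def test_idempotent_on_representatives(self):
        rng = np.random.default_rng(43)
        coords = sorted(set(rng.integers(1, 500, size=30).tolist()))
        clusters = te.build_superset({"A": [_npeak(c) for c in coords]}, tol=5)
        reps = [_npeak(c.representative) for c in clusters]
        again = te.build_superset({"A": reps}, tol=5)
        # chaining means representatives of distinct clusters are > tol apart
        assert len(again) == len(clusters)

    def test_chain_span_reported(self):
        clusters = te.build_superset(
            {"A": [_npeak(100)], "B": [_npeak(105)], "C": [_npeak(110)]}, tol=5)
        assert len(clusters) == 1 and clusters[0].span == 10


def toy_matrix(entries, strains=("WT", "M1", "M2")):
    clusters = [te.PeakCluster(100 + 10 * i, "+", "g1") for i in range(len(entries))]
    values = pd.DataFrame(entries, columns=list(strains),
                          index=[c.cluster_id for c in clusters])
    return PeakMatrix(clusters=clusters, values=values)


class TestFillMatrix:
    def test_hand_computed_three_cluster_toy(self):
        n = 400
        cv_vals = {"A": np.zeros(n), "B": np.zeros(n)}
        cv_vals["A"][[99, 199, 299]] = [40, 0, 12]
        cv_vals["B"][[101, 201, 299]] = [20, 35, 0]
        cv = {s: {"+": CvTrack("+", v)} for s, v in cv_vals.items()}
        rna = {s: {"+": te.CoverageTrack("+", np.full(n, 100), assay="rnaseq")}
               for s in ("A", "B")}
        clusters = [te.PeakCluster(100, "+", "g1"), te.PeakCluster(200, "+", "g1"),
                    te.PeakCluster(300, "+", "g1")]
        m = te.fill_matrix(clusters, cv, rna, tol=5)
        # denominator log10(100) = 2 everywhere
        expected = pd.DataFrame({"A": [20.0, 0.001, 6.0],
                                 "B": [10.0, 17.5, 0.001]},
                                index=m.values.index)
        pd.testing.assert_frame_equal(m.values, expected)

    def test_entry_floor_when_no_signal(self):
        n = 100
        cv = {"A": {"+": CvTrack("+", np.zeros(n))}}
        rna = {"A": {"+": te.CoverageTrack("+", np.full(n, 50), assay="rnaseq")}}
        m = te.fill_matrix([te.PeakCluster(50, "+", "g")], cv, rna)
        assert m.values.iloc[0, 0] == 0.001


class TestSharedSets:
    def test_qualifying_subset_boundary(self):
        m = toy_matrix([[0.6, 0.53, 0.1]], strains=("A", "B", "C"))
        regions = te.shared_sets(m, min_norm=0.53)
        assert regions == {frozenset({"A", "B"}): 1}

    def test_all_floor_counts_nowhere(self):
        m = toy_matrix([[0.001, 0.001, 0.001]])
        assert te.shared_sets(m) == {}

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(51)
        strains = ("A", "B", "C", "D")
        for _ in range(100):
            vals = rng.uniform(0.001, 1.2, size=(12, 4))
            m = toy_matrix(vals.tolist(), strains=strains)
            regions = te.shared_sets(m, min_norm=0.53)
            expected = {}
            for row in vals:
                sub = frozenset(s for s, v in zip(strains, row) if v >= 0.53)
                if sub:
                    expected[sub] = expected.get(sub, 0) + 1
            assert regions == expected
            assert sum(regions.values()) == sum(
                1 for row in vals if (row >= 0.53).any())

    def test_region_counts_invariant_to_strain_order(self):
        vals = [[0.6, 0.2, 0.9], [0.7, 0.7, 0.1]]
        m1 = toy_matrix(vals, strains=("A", "B", "C"))
        m2 = toy_matrix([[r[2], r[0], r[1]] for r in vals],
                        strains=("C", "A", "B"))
        assert te.shared_sets(m1) == te.shared_sets(m2)


class TestFoldChangeSets:
    def test_boundary_64_fold_included(self):
        m = toy_matrix([[0.1, 6.4, 0.2]], strains=("WT", "M1", "M2"))
        sets, regions = te.fold_change_sets(m, "WT", fc_threshold=64)
        assert len(sets["M1"]) == 1 and len(sets["M2"]) == 0

    def test_no_change_excluded(self):
        m = toy_matrix([[0.001, 0.001, 0.001]])
        sets, regions = te.fold_change_sets(m, "WT")
        assert not regions

    def test_matches_exhaustive_check(self):
        rng = np.random.default_rng(52)
        strains = ("WT", "M1", "M2", "M3")
        for _ in range(100):
            vals = np.exp(rng.uniform(np.log(0.001), np.log(100), size=(10, 4)))
            m = toy_matrix(vals.tolist(), strains=strains)
            sets, regions = te.fold_change_sets(m, "WT", fc_threshold=64)
            for i, row in enumerate(vals):
                cid = m.clusters[i].cluster_id
                for j, s in enumerate(strains[1:], start=1):
                    assert (cid in sets[s]) == (row[j] / row[0] >= 64)
            assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            te.fold_change_sets(toy_matrix([[1, 1, 1]]), "nope")


class TestLog2FoldChanges:
    def test_antisymmetric_under_pair_swap(self):
        rng = np.random.default_rng(53)
        vals = np.exp(rng.uniform(-3, 3, size=(20, 3)))
        m = toy_matrix(vals.tolist())
        ab = te.log2_fold_changes(m, "M1", "WT")
        ba = te.log2_fold_changes(m, "WT", "M1")
        np.testing.assert_allclose(ab.values, -ba.values)


def brute_force_ranksum_p(a, b, alternative):
    """Exhaustive enumeration over all C(n_a+n_b, n_a) group assignments of
    the pooled values (assumes no ties)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    observed = sum(stats.rankdata(pooled)[:n_a])
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ranks = stats.rankdata(pooled)
        stat = sum(ranks[list(idx)])
        total += 1
        if alternative == "greater" and stat >= observed - 1e-9:
            count += 1
        elif alternative == "less" and stat <= observed + 1e-9:
            count += 1
    return count / total


class TestDistributionTest:
    def test_fully_separated_three_vs_three(self):
        assert te.distribution_test([1, 2, 3], [4, 5, 6], "less") == \
            pytest.approx(1 / 20)
        assert te.distribution_test([4, 5, 6], [1, 2, 3], "greater") == \
            pytest.approx(1 / 20)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            a = rng.normal(size=4).tolist()
            b = rng.normal(size=4).tolist()
            for alt in ("greater", "less"):
                assert te.distribution_test(a, b, alt) == \
                    pytest.approx(brute_force_ranksum_p(a, b, alt))

    def test_identical_samples_give_large_p(self):
        rng = np.random.default_rng(62)
        x = rng.normal(size=8).tolist()
        assert te.distribution_test(x, list(x), "greater") >= 0.4

    def test_degenerate_constant_data_warns_p_one(self):
        with pytest.warns(UserWarning):
            p = te.distribution_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_large_sample_approximation_close_to_exact(self):
        rng = np.random.default_rng(63)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 8)
        exact = float(stats.mannwhitneyu(a, b, alternative="greater",
                                         method="exact").pvalue)
        approx = float(stats.mannwhitneyu(a, b, alternative="greater",
                                          method="asymptotic").pvalue)
        assert abs(exact - approx) < 1e-2
        assert te.distribution_test(a, b, "greater") == pytest.approx(exact)

    def test_tied_data_uses_seeded_permutation(self):
        a = [1.0, 1.0, 2.0, 3.0]
        b = [1.0, 2.0, 2.0, 0.5]
        p1 = te.distribution_test(a, b, "greater")
        p2 = te.distribution_test(a, b, "greater")
        assert p1 == p2  # fixed seed -> reproducible
        assert 0 < p1 <= 1

    def test_permutation_p_close_to_exact_on_tie_free_data(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        p = _permutation_ranksum_p(a, b, "less", n_perm=40_000)
        assert p == pytest.approx(1 / 20, rel=0.15)


class TestRelativePositions:
    def test_endpoints_and_interior(self, micro_annotation):
        peaks = [_npeak(101, gene="geneA"), _npeak(400, gene="geneA"),
                 _npeak(161, gene="geneA")]
        pos = te.relative_positions(peaks, micro_annotation)
        assert pos[0] == 0.0 and pos[1] == 1.0
        assert pos[2] == pytest.approx(60 / 299)

    def test_minus_strand_positions_are_transcript_sense(self, micro_annotation):
        peaks = [_npeak(940, strand="-", gene="geneB"),
                 _npeak(641, strand="-", gene="geneB")]
        pos = te.relative_positions(peaks, micro_annotation)
        assert pos.tolist() == [0.0, 1.0]


class TestPositionDensity:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(71)
        positions = rng.beta(2, 4, size=200)
        grid, density = te.position_density(positions)
        area = integrate.trapezoid(density, grid)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_boundary_reflection_preserves_edge_mass(self):
        positions = np.concatenate([np.full(50, 0.02), [0.5, 0.6]])
        grid, density = te.position_density(positions)
        area = integrate.trapezoid(density, grid)
        assert area == pytest.approx(1.0, abs=5e-3)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            te.position_density([0.5])


def test_venn_frame_round_trip():
    regions = {frozenset({"A"}): 3, frozenset({"A", "B"}): 2}
    frame = venn_frame(regions)
    assert set(frame["region"]) == {"A", "A&B"}
    assert frame["count"].sum() == 5
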