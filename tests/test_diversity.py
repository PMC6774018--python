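"""Richness, Bray-Curtis/Sorensen, PCoA and average genome size."""

import numpy as np
import pandas as pd
import pytest

from coreacc import (
    DistanceMatrix,
    GeneAbundanceTable,
    average_genome_size,
    bray_curtis,
    call_presence,
    pcoa,
    presence_dissimilarity,
    richness,
)
from coreacc.partition import PresenceMatrix


def brute_bray_curtis(u, v):
    """Direct evaluation of 1 - 2*sum(min)/(sum+sum)."""
    return 1.0 - 2.0 * np.minimum(u, v).sum() / (u.sum() + v.sum())


class TestRichness:
    def test_counts_presence_columns(self, toy_table):
        pres = call_presence(toy_table, 0.0)
        r = richness(pres)
        assert r.tolist() == [3, 3, 3, 3]
        np.testing.assert_array_equal(r.to_numpy(), pres.presence.sum(axis=0))

    def test_all_absent_sample(self):
        pres = PresenceMatrix(
            ["g1", "g2"], ["s1", "s2"],
            np.array([[True, False], [True, False]]), 0.0,
        )
        assert richness(pres).tolist() == [2, 0]


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = GeneAbundanceTable(["a", "b"], ["s1", "s2"], np.array([[3, 3], [5, 5]]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        t = GeneAbundanceTable(["a", "b"], ["s1", "s2"], np.array([[3, 0], [0, 5]]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # p_i = (1,0,3)/4, p_j = (0,2,1)/3 -> 1 - 2(1/3)/2 = 2/3
        t = GeneAbundanceTable(
            ["a", "b", "c"], ["s1", "s2"], np.array([[1, 0], [0, 2], [3, 1]])
        )
        assert bray_curtis(t).values[0, 1] == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            counts = rng.integers(0, 40, size=(12, 5))
            counts[0] += 1
            t = GeneAbundanceTable(
                [f"g{i}" for i in range(12)], [f"s{j}" for j in range(5)], counts
            )
            d = bray_curtis(t).values
            rel = counts / counts.sum(axis=0)
            for i in range(5):
                for j in range(i + 1, 5):
                    assert d[i, j] == pytest.approx(
                        brute_bray_curtis(rel[:, i], rel[:, j]), abs=1e-12
                    )

    def test_subset_restriction(self, toy_table):
        d = bray_curtis(toy_table, subset={"gA", "gD"})
        rel = toy_table.relative_abundance()
        idx = [0, 3]
        expect = brute_bray_curtis(rel[idx, 0], rel[idx, 1])
        assert d.values[0, 1] == pytest.approx(expect)
        with pytest.raises(ValueError, match="disjoint"):
            bray_curtis(toy_table, subset={"nope"})


class TestPresenceDissimilarity:
    def test_hand_worked_sets(self):
        # {g1,g2} vs {g2,g3}: a=1, b=1, c=1 -> 0.5
        pres = PresenceMatrix(
            ["g1", "g2", "g3"], ["s1", "s2"],
            np.array([[True, False], [True, True], [False, True]]), 0.0,
        )
        assert presence_dissimilarity(pres).values[0, 1] == pytest.approx(0.5)

    def test_identical_sets_zero(self):
        pres = PresenceMatrix(
            ["g1", "g2"], ["s1", "s2"], np.ones((2, 2), dtype=bool), 0.0
        )
        assert presence_dissimilarity(pres).values[0, 1] == 0.0

    def test_empty_sample_flagged_as_one(self):
        pres = PresenceMatrix(
            ["g1"], ["s1", "s2", "s3"],
            np.array([[True, False, True]]), 0.0,
        )
        d = presence_dissimilarity(pres).values
        assert d[0, 1] == 1.0 and d[1, 2] == 1.0 and d[0, 2] == 0.0

    def test_equals_bray_curtis_on_binary_counts(self):
        # Sorensen is Bray-Curtis applied to the raw 0/1 vectors (counts,
        # not per-sample relative abundances, which would rescale by richness)
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(7)
        for _ in range(20):
            mat = rng.random((10, 4)) < 0.5
            mat[:, mat.sum(axis=0) == 0] = True  # avoid empty columns
            pres = PresenceMatrix(
                [f"g{i}" for i in range(10)], [f"s{j}" for j in range(4)], mat, 0.0
            )
            expected = squareform(pdist(mat.T.astype(float), metric="braycurtis"))
            np.testing.assert_allclose(
                presence_dissimilarity(pres).values, expected, atol=1e-12
            )


class TestPcoa:
    def test_three_equidistant_points(self):
        d = DistanceMatrix(["a", "b", "c"], 1.0 - np.eye(3), "unit")
        res = pcoa(d, n_axes=2)
        np.testing.assert_allclose(res.explained_fraction, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-12)

    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = DistanceMatrix(["a", "b", "c", "d"], np.abs(x[:, None] - x[None, :]), "line")
        res = pcoa(d, n_axes=3)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_reconstructs_euclidean_configuration(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(9, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(9)], d, "euclid"), n_axes=2)
        rec = res.coordinates
        dr = np.linalg.norm(rec[:, None] - rec[None, :], axis=-1)
        assert np.abs(dr - d).max() < 1e-8

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 5))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d, "e"), n_axes=5)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_matches_skbio_on_euclidean_input(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        import skbio

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d, "e"), n_axes=3)
        theirs = skbio_ord.pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            ours.explained_fraction,
            theirs.proportion_explained.to_numpy()[:3],
            atol=1e-8,
        )

    def test_bad_axis_counts(self):
        d = DistanceMatrix(["a", "b", "c"], 1.0 - np.eye(3), "u")
        with pytest.raises(ValueError):
            pcoa(d, n_axes=0)
        with pytest.raises(ValueError):
            pcoa(d, n_axes=3)


class TestAverageGenomeSize:
    def test_single_taxon(self):
        rel = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["t1"])
        sizes = pd.Series({"t1": 5e6})
        assert average_genome_size(rel, sizes).tolist() == [5e6, 5e6]

    def test_two_taxa_mean(self):
        rel = pd.DataFrame({"s1": [0.5, 0.5]}, index=["t1", "t2"])
        rel["s2"] = [0.25, 0.75]
        sizes = pd.Series({"t1": 2e6, "t2": 6e6})
        out = average_genome_size(rel, sizes)
        assert out["s1"] == pytest.approx(4e6)
        assert out["s2"] == pytest.approx(5e6)

    def test_small_genome_bloom_decreases_ags(self):
        sizes = pd.Series({"small": 2e6, "big": 6e6})
        prev = np.inf
        for frac in (0.1, 0.3, 0.6):
            rel = pd.DataFrame({"s": [frac, 1 - frac]}, index=["small", "big"])
            val = average_genome_size(rel, sizes)["s"]
            assert val < prev
            prev = val

    def test_invariances(self):
        rel = pd.DataFrame({"s1": [0.3, 0.7, 0.0]}, index=["a", "b", "zero"])
        sizes = pd.Series({"a": 3e6, "b": 5e6, "zero": 9e6})
        base = average_genome_size(rel, sizes)["s1"]
        perm = average_genome_size(rel.loc[["zero", "b", "a"]], sizes)["s1"]
        no_zero = average_genome_size(rel.loc[["a", "b"]], sizes)["s1"]
        assert base == pytest.approx(perm) == pytest.approx(no_zero)

    def test_errors(self):
        rel = pd.DataFrame({"s1": [0.6, 0.3]}, index=["a", "b"])
        with pytest.raises(ValueError, match="sum to 1"):
            average_genome_size(rel, pd.Series({"a": 1e6, "b": 1e6}))
        rel = pd.DataFrame({"s1": [0.5, 0.5]}, index=["a", "b"])
        with pytest.raises(KeyError, match="missing genome sizes"):
            average_genome_size(rel, pd.Series({"a": 1e6}))
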