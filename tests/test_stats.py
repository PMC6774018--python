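"""Split-plot ANOVA, PERMANOVA and Mantel against independent oracles."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from coreacc import DistanceMatrix, MantelTest, Permanova, SplitPlotAnova
from tests.conftest import random_design


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------
def projection_anova_oracle(y, design):
    """Balanced split-plot SS via explicit projection matrices."""
    n = len(y)
    blocks = design.blocks
    bidx = np.array([blocks.index(x) for x in design.block])
    nvec = np.array(design.n_treatment, dtype=int)
    wvec = np.array(design.w_treatment, dtype=int)

    def proj(cols):
        X = np.column_stack(cols).astype(float)
        return X @ np.linalg.pinv(X)

    one = [np.ones(n)]
    p0 = proj(one)
    pb = proj([bidx == i for i in range(len(blocks))])
    pn = proj([nvec == v for v in (0, 1)])
    pw = proj([wvec == v for v in (0, 1)])
    pbn = proj([(bidx == i) & (nvec == v) for i in range(len(blocks)) for v in (0, 1)])
    pnw = proj([(nvec == a) & (wvec == b) for a in (0, 1) for b in (0, 1)])

    def q(p):
        return float(y @ p @ y)

    ss = {
        "Block": q(pb - p0),
        "N": q(pn - p0),
        "Block x N": q(pbn - pb - pn + p0),
        "W": q(pw - p0),
        "N x W": q(pnw - pn - pw + p0),
    }
    ss["Residual"] = q(np.eye(n) - p0) - sum(ss.values())
    b = len(blocks)
    df = {"Block": b - 1, "N": 1, "Block x N": b - 1, "W": 1, "N x W": 1,
          "Residual": 2 * (b - 1)}
    ms = {k: ss[k] / df[k] for k in ss}
    f = {
        "Block": ms["Block"] / ms["Block x N"],
        "N": ms["N"] / ms["Block x N"],
        "W": ms["W"] / ms["Residual"],
        "N x W": ms["N x W"] / ms["Residual"],
    }
    return ss, f


def brute_pseudo_f(d, grouping):
    """PERMANOVA pseudo-F by direct loops over pairs."""
    n = len(grouping)
    ss_total = sum(d[i, j] ** 2 for i, j in combinations(range(n), 2)) / n
    ss_within = 0.0
    for g in set(grouping):
        idx = [i for i in range(n) if grouping[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i, j in combinations(idx, 2)
        ) / len(idx)
    a = len(set(grouping))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def brute_mantel_r(d1, d2):
    """Pearson r on upper-triangle vectors, from the definition."""
    n = d1.shape[0]
    v1 = np.array([d1[i, j] for i, j in combinations(range(n), 2)])
    v2 = np.array([d2[i, j] for i, j in combinations(range(n), 2)])
    v1c, v2c = v1 - v1.mean(), v2 - v2.mean()
    return float((v1c * v2c).sum() / np.sqrt((v1c**2).sum() * (v2c**2).sum()))


def random_distance_matrix(rng, n, dim=3):
    pts = rng.normal(size=(n, dim))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return DistanceMatrix([f"s{i}" for i in range(n)], d, "euclid")


# ----------------------------------------------------------------------
# split-plot ANOVA
# ----------------------------------------------------------------------
class TestSplitPlotAnova:
    def test_constant_response_flagged_nan(self, design_2x2):
        res = SplitPlotAnova(np.ones(16), design_2x2).fit()
        assert res.degenerate
        assert np.allclose(res.table["sum_sq"], 0.0)
        assert np.isnan(res.table.loc["W", "F"])

    def test_pure_w_contrast(self, design_2x2):
        delta = 0.7
        y = np.array([delta if w else 0.0 for w in design_2x2.w_treatment])
        res = SplitPlotAnova(y, design_2x2).fit()
        t = res.table
        assert t.loc["W", "sum_sq"] == pytest.approx(16 * delta**2 / 4)
        assert np.isinf(t.loc["W", "F"]) and t.loc["W", "p"] == 0.0
        for term in ("Block", "N", "Block x N", "N x W"):
            assert t.loc[term, "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_blocks", [3, 4, 5])
    def test_matches_projection_oracle(self, n_blocks):
        rng = np.random.default_rng(100 + n_blocks)
        design = random_design(rng, n_blocks)
        for _ in range(40):
            y = rng.normal(size=design.n_samples)
            res = SplitPlotAnova(y, design).fit().table
            ss, f = projection_anova_oracle(y, design)
            for term, val in ss.items():
                assert res.loc[term, "sum_sq"] == pytest.approx(val, abs=1e-8)
            for term, val in f.items():
                assert res.loc[term, "F"] == pytest.approx(val, abs=1e-8)

    def test_df_and_ss_partition(self, design_2x2):
        rng = np.random.default_rng(0)
        y = rng.normal(size=16)
        t = SplitPlotAnova(y, design_2x2).fit().table
        assert t["df"].sum() == 15
        assert t["sum_sq"].sum() == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-9)
        assert (t["sum_sq"] >= -1e-12).all()

    def test_null_p_values_uniform(self, design_2x2):
        rng = np.random.default_rng(2024)
        pw = [
            SplitPlotAnova(rng.normal(size=16), design_2x2).fit().table.loc["W", "p"]
            for _ in range(200)
        ]
        assert sps.kstest(pw, "uniform").pvalue > 0.01

    def test_incomplete_design_rejected(self, design_2x2):
        from coreacc import ExperimentalDesign

        sub = ExperimentalDesign(
            design_2x2.sample_ids[:15], design_2x2.block[:15],
            design_2x2.n_treatment[:15], design_2x2.w_treatment[:15],
        )
        with pytest.raises(ValueError, match="complete balanced"):
            SplitPlotAnova(np.zeros(15), sub)


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------
class TestPermanova:
    def test_pseudo_f_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            dm = random_distance_matrix(rng, 8)
            grouping = np.array(["a"] * 4 + ["b"] * 4)
            res = Permanova(dm, grouping).fit(99, seed=0)
            assert res.pseudo_F == pytest.approx(
                brute_pseudo_f(dm.values, grouping), abs=1e-10
            )

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(2)
        dm = random_distance_matrix(rng, 9)
        grouping = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ours = Permanova(dm, np.array(grouping)).fit(99, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(dm.values, dm.sample_ids),
                              grouping, permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        dm = random_distance_matrix(rng, 8)
        grouping = np.array(["a", "b"] * 4)
        f1 = Permanova(dm, grouping).fit(99, seed=0).pseudo_F
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(
            [dm.sample_ids[i] for i in perm], dm.values[np.ix_(perm, perm)], "p"
        )
        f2 = Permanova(dm2, grouping[perm]).fit(99, seed=0).pseudo_F
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_monte_carlo_p_matches_enumeration(self):
        rng = np.random.default_rng(4)
        dm = random_distance_matrix(rng, 8)
        grouping = np.array(["a"] * 4 + ["b"] * 4)
        f_obs = brute_pseudo_f(dm.values, grouping)
        # exact permutation distribution over all 70 equal-split partitions
        f_all = []
        for idx in combinations(range(8), 4):
            lab = np.array(["b"] * 8, dtype=object)
            lab[list(idx)] = "a"
            f_all.append(brute_pseudo_f(dm.values, lab))
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_all])
        n_perm = 999
        res = Permanova(dm, grouping).fit(n_perm, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p_value - p_exact) <= 3 * se + 2 / n_perm

    def test_strata_confined_permutations(self, design_2x2):
        # grouping constant within each block: within-block shuffles can
        # never change the labelling, so every permuted F equals the observed
        rng = np.random.default_rng(6)
        dm = random_distance_matrix(rng, 16)
        dm = DistanceMatrix(design_2x2.sample_ids, dm.values, "e")
        grouping = np.array(design_2x2.block)
        res = Permanova(dm, np.where(np.isin(grouping, ["block1", "block2"]), "g1", "g2"),
                        strata=grouping).fit(199, seed=0)
        assert res.p_value == 1.0
        assert res.permutation_scheme == "within-block"

    def test_seed_determinism_and_errors(self):
        rng = np.random.default_rng(8)
        dm = random_distance_matrix(rng, 6)
        g = np.array(["a"] * 3 + ["b"] * 3)
        p1 = Permanova(dm, g).fit(199, seed=11).p_value
        p2 = Permanova(dm, g).fit(199, seed=11).p_value
        assert p1 == p2
        with pytest.raises(ValueError, match="singleton"):
            Permanova(dm, np.array(["a"] * 5 + ["b"]))
        with pytest.raises(ValueError, match="2 levels"):
            Permanova(dm, np.array(["a"] * 6))


# ----------------------------------------------------------------------
# Mantel
# ----------------------------------------------------------------------
class TestMantel:
    def test_affine_relation_gives_r_one(self):
        rng = np.random.default_rng(9)
        d1 = random_distance_matrix(rng, 6)
        vals = 2.5 * d1.values + 0.3
        np.fill_diagonal(vals, 0.0)
        d2 = DistanceMatrix(d1.sample_ids, vals, "affine")
        res = MantelTest(d1, d2).fit(99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_r_matches_direct_formula(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            d1 = random_distance_matrix(rng, 5)
            d2 = random_distance_matrix(rng, 5)
            res = MantelTest(d1, d2).fit(99, seed=0)
            assert res.r == pytest.approx(
                brute_mantel_r(d1.values, d2.values), abs=1e-12
            )

    def test_matches_skbio(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel
        import skbio

        rng = np.random.default_rng(12)
        d1 = random_distance_matrix(rng, 7)
        d2 = random_distance_matrix(rng, 7)
        ours = MantelTest(d1, d2).fit(999, seed=1)
        r_sk, p_sk, _ = sk_mantel(
            skbio.DistanceMatrix(d1.values, d1.sample_ids),
            skbio.DistanceMatrix(d2.values, d2.sample_ids),
            permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(r_sk, abs=1e-10)
        assert abs(ours.p_value - p_sk) < 0.05

    def test_constant_matrix_flagged(self):
        d1 = DistanceMatrix(["s0", "s1", "s2"], 1.0 - np.eye(3), "const")
        rng = np.random.default_rng(13)
        d2 = random_distance_matrix(rng, 3)
        with pytest.warns(UserWarning, match="constant"):
            res = MantelTest(d1, d2).fit(99, seed=0)
        assert res.degenerate and np.isnan(res.r)

    def test_independent_matrices_p_not_extreme(self):
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(50):
            d1 = random_distance_matrix(rng, 8)
            d2 = random_distance_matrix(rng, 8)
            ps.append(MantelTest(d1, d2).fit(99, seed=0).p_value)
        # under independence p should be roughly uniform
        assert 0.2 < np.mean(ps) < 0.8
        assert sps.kstest(ps, "uniform").pvalue > 0.01
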