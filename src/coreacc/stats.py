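"""Inferential machinery: split-plot ANOVA, PERMANOVA and the Mantel test.

All three follow the statsmodels model/results convention. The split-plot
ANOVA is the exact balanced-design decomposition for b blocks x 2 (N,
whole-plot) x 2 (W, subplot) with one observation per cell: Block and N are
tested against the Block x N stratum (the whole-plot error), W and N x W
against the subplot residual. PERMANOVA partitions squared dissimilarities
among groups with a permutation p-value (optionally restricted within
blocks); the Mantel test correlates two distance matrices with a
simultaneous row/column permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import DistanceMatrix
from .tables import ExperimentalDesign

__all__ = [
    "SplitPlotAnova",
    "SplitPlotAnovaResults",
    "Permanova",
    "PermanovaResults",
    "MantelTest",
    "MantelResults",
    "split_plot_anova",
    "permanova",
    "mantel",
]


# ----------------------------------------------------------------------
# Split-plot ANOVA
# ----------------------------------------------------------------------
class SplitPlotAnova:
    """Split-plot ANOVA of a per-sample response on a blocked 2x2 design.

    Parameters
    ----------
    response : pandas Series (indexed by sample id) or array aligned with
        ``design.sample_ids``.
    design : ExperimentalDesign
        Must be a complete balanced layout: b blocks, each containing the
        four N x W combinations exactly once.
    """

    #: error stratum used as the F denominator for each tested term
    ERROR_TERMS = {
        "Block": "Block x N",
        "N": "Block x N",
        "W": "Residual",
        "N x W": "Residual",
    }

    def __init__(self, response, design: ExperimentalDesign):
        if not design.is_complete:
            raise ValueError(
                "split-plot ANOVA requires a complete balanced design "
                "(every block containing all four N x W cells exactly once)"
            )
        if isinstance(response, pd.Series):
            y = response.reindex(design.sample_ids)
            if y.isna().any():
                raise ValueError("response missing for some design samples")
            y = y.to_numpy(dtype=float)
        else:
            y = np.asarray(response, dtype=float)
            if y.shape != (design.n_samples,):
                raise ValueError("response length does not match design")
        if not np.all(np.isfinite(y)):
            raise ValueError("response must be finite")
        self.response = y
        self.design = design

    def fit(self) -> "SplitPlotAnovaResults":
        d = self.design
        blocks = d.blocks
        b = len(blocks)
        bidx = np.array([blocks.index(x) for x in d.block])
        nmask = np.array(d.n_treatment)
        wmask = np.array(d.w_treatment)
        y = self.response
        mu = y.mean()

        def level_mean(mask):
            return y[mask].mean()

        ss_total = float(((y - mu) ** 2).sum())
        # main effects (balanced means decomposition)
        block_means = np.array([y[bidx == i].mean() for i in range(b)])
        ss_block = 4.0 * float(((block_means - mu) ** 2).sum())
        n_means = np.array([level_mean(~nmask), level_mean(nmask)])
        ss_n = 2.0 * b * float(((n_means - mu) ** 2).sum())
        w_means = np.array([level_mean(~wmask), level_mean(wmask)])
        ss_w = 2.0 * b * float(((w_means - mu) ** 2).sum())
        # block x N interaction (whole-plot error)
        ss_bn = 0.0
        for i in range(b):
            for nv, nm in ((False, n_means[0]), (True, n_means[1])):
                cell = y[(bidx == i) & (nmask == nv)].mean()
                ss_bn += 2.0 * (cell - block_means[i] - nm + mu) ** 2
        # N x W interaction
        ss_nw = 0.0
        for nv, nm in ((False, n_means[0]), (True, n_means[1])):
            for wv, wm in ((False, w_means[0]), (True, w_means[1])):
                cell = y[(nmask == nv) & (wmask == wv)].mean()
                ss_nw += b * (cell - nm - wm + mu) ** 2
        ss_resid = ss_total - (ss_block + ss_n + ss_bn + ss_w + ss_nw)
        ss_resid = max(ss_resid, 0.0)

        rows = {
            "Block": (b - 1, ss_block),
            "N": (1, ss_n),
            "Block x N": (b - 1, ss_bn),
            "W": (1, ss_w),
            "N x W": (1, ss_nw),
            "Residual": (2 * (b - 1), ss_resid),
        }
        ms = {k: (ss / df if df > 0 else np.nan) for k, (df, ss) in rows.items()}
        table = []
        degenerate = False
        for term, (df, ss) in rows.items():
            f = p = np.nan
            if term in self.ERROR_TERMS:
                err = self.ERROR_TERMS[term]
                denom = ms[err]
                num = ms[term]
                with np.errstate(divide="ignore", invalid="ignore"):
                    if denom == 0 and num == 0:
                        f, p, degenerate = np.nan, np.nan, True
                    elif denom == 0:
                        f, p = np.inf, 0.0
                    else:
                        f = num / denom
                        p = float(sps.f.sf(f, df, rows[err][0]))
            table.append((term, df, ss, ms[term], f, p))
        frame = pd.DataFrame(
            table, columns=["term", "df", "sum_sq", "mean_sq", "F", "p"]
        ).set_index("term")
        return SplitPlotAnovaResults(self, frame, degenerate)


@dataclass
class SplitPlotAnovaResults:
    model: SplitPlotAnova
    table: pd.DataFrame
    degenerate: bool = False

    @property
    def p_values(self) -> pd.Series:
        return self.table["F"].index.to_series().map(self.table["p"]).dropna()

    def summary(self) -> str:
        head = "Split-plot ANOVA (whole-plot factor N, subplot factor W)\n"
        if self.degenerate:
            head += "note: zero-variance stratum; F reported as NaN where 0/0\n"
        err = ", ".join(f"{k} ~ {v}" for k, v in SplitPlotAnova.ERROR_TERMS.items())
        return (
            head
            + f"error strata: {err}\n"
            + self.table.to_string(float_format=lambda x: f"{x:.6g}")
        )


def split_plot_anova(response, design: ExperimentalDesign) -> SplitPlotAnovaResults:
    """Functional facade over :class:`SplitPlotAnova`."""
    return SplitPlotAnova(response, design).fit()


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------
class Permanova:
    """One-factor PERMANOVA on a distance matrix.

    pseudo-F = (SS_between / (a - 1)) / (SS_within / (n - a)) where
    SS_total = sum_{i<j} d_ij^2 / n and SS_within sums the analogous
    quantity per group. The p-value permutes group labels freely or, when
    ``strata`` is given, only within strata (samples never swap blocks).
    """

    def __init__(self, d: DistanceMatrix, grouping, strata=None):
        self.d = d
        grouping = self._align(grouping)
        levels, counts = np.unique(grouping, return_counts=True)
        if len(levels) < 2:
            raise ValueError("grouping must have at least 2 levels")
        if counts.min() < 2:
            bad = levels[counts < 2].tolist()
            raise ValueError(f"singleton group(s): {bad}")
        self.grouping = grouping
        self.strata = None if strata is None else self._align(strata)

    def _align(self, labels) -> np.ndarray:
        if isinstance(labels, pd.Series):
            labels = labels.reindex(self.d.sample_ids).to_numpy()
        labels = np.asarray(labels, dtype=object)
        if labels.shape != (self.d.n_samples,):
            raise ValueError("one label required per sample")
        return labels

    @staticmethod
    def _pseudo_f(d2: np.ndarray, grouping: np.ndarray) -> tuple[float, float]:
        n = d2.shape[0]
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        levels = np.unique(grouping)
        for g in levels:
            idx = np.where(grouping == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        a = len(levels)
        ss_between = ss_total - ss_within
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        r2 = ss_between / ss_total if ss_total > 0 else np.nan
        return float(f), float(r2)

    def fit(self, n_permutations: int = 999, seed: int | None = None) -> "PermanovaResults":
        if n_permutations < 99:
            warnings.warn("fewer than 99 permutations gives a coarse p-value")
        d2 = self.d.values**2
        f_obs, r2 = self._pseudo_f(d2, self.grouping)
        rng = np.random.default_rng(seed)
        n = self.d.n_samples
        count_ge = 0
        strata_idx = None
        if self.strata is not None:
            strata_idx = [np.where(self.strata == s)[0] for s in np.unique(self.strata)]
        for _ in range(n_permutations):
            perm = np.arange(n)
            if strata_idx is None:
                rng.shuffle(perm)
            else:
                for idx in strata_idx:
                    perm[idx] = idx[rng.permutation(len(idx))]
            f_perm, _ = self._pseudo_f(d2, self.grouping[perm])
            if f_perm >= f_obs:
                count_ge += 1
        p = (count_ge + 1) / (n_permutations + 1)
        scheme = "free" if self.strata is None else "within-block"
        return PermanovaResults(self, f_obs, r2, float(p), n_permutations, scheme)


@dataclass
class PermanovaResults:
    model: Permanova
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    permutation_scheme: str

    def summary(self) -> str:
        return (
            f"PERMANOVA ({self.permutation_scheme} permutations, "
            f"n={self.n_permutations})\n"
            f"pseudo-F = {self.pseudo_F:.4f}  R^2 = {self.r_squared:.4f}  "
            f"p = {self.p_value:.4g}"
        )


def permanova(d, grouping, n_perm: int = 999, seed: int | None = None, strata=None):
    """Functional facade over :class:`Permanova`."""
    return Permanova(d, grouping, strata=strata).fit(n_perm, seed)


# ----------------------------------------------------------------------
# Mantel test
# ----------------------------------------------------------------------
class MantelTest:
    """Mantel correlation between two distance matrices on the same samples."""

    def __init__(self, d1: DistanceMatrix, d2: DistanceMatrix):
        if d1.sample_ids != d2.sample_ids:
            raise ValueError("distance matrices must share sample ids and order")
        if d1.n_samples < 3:
            raise ValueError("Mantel test needs at least 3 samples")
        self.d1 = d1
        self.d2 = d2

    def fit(
        self,
        n_permutations: int = 999,
        seed: int | None = None,
        tail: str = "greater",
    ) -> "MantelResults":
        if tail not in ("greater", "two-sided"):
            raise ValueError("tail must be 'greater' or 'two-sided'")
        v1 = self.d1.condensed()
        v2 = self.d2.condensed()
        degenerate = v1.std() == 0 or v2.std() == 0
        if degenerate:
            warnings.warn("constant distance vector: Mantel r undefined")
            return MantelResults(self, np.nan, np.nan, n_permutations, tail, True)
        r_obs = float(np.corrcoef(v1, v2)[0, 1])
        rng = np.random.default_rng(seed)
        n = self.d1.n_samples
        m2 = self.d2.values
        extreme = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            v2p = m2[np.ix_(perm, perm)][np.triu_indices(n, 1)]
            r_perm = np.corrcoef(v1, v2p)[0, 1]
            if tail == "greater":
                if r_perm >= r_obs:
                    extreme += 1
            else:
                if abs(r_perm) >= abs(r_obs):
                    extreme += 1
        p = (extreme + 1) / (n_permutations + 1)
        return MantelResults(self, r_obs, float(p), n_permutations, tail, False)


@dataclass
class MantelResults:
    model: MantelTest
    r: float
    p_value: float
    n_permutations: int
    tail: str
    degenerate: bool = False

    def summary(self) -> str:
        return (
            f"Mantel test ({self.tail}, n={self.n_permutations} permutations)\n"
            f"r = {self.r:.4f}  p = {self.p_value:.4g}"
        )


def mantel(d1, d2, n_perm: int = 999, seed: int | None = None, tail: str = "greater"):
    """Functional facade over :class:`MantelTest`."""
    return MantelTest(d1, d2).fit(n_perm, seed, tail)
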