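"""Component-aware alpha and beta diversity.

Richness counts presence calls per sample. Beta diversity uses Bray-Curtis
dissimilarity on relative abundances (full-total denominator, optionally
restricted to a gene subset such as the core set) and its presence/absence
special case, which coincides with the Sorensen dissimilarity
1 - 2a/(2a + b + c). Ordination is classical PCoA. Average genome size is
the cell-abundance-weighted mean genome length of the community's taxa —
the statistic that drops when a small-genome guild such as ammonia-oxidizing
bacteria blooms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .partition import PresenceMatrix
from .tables import GeneAbundanceTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "richness",
    "bray_curtis",
    "presence_dissimilarity",
    "pcoa",
    "average_genome_size",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValueError("negative dissimilarity")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA sample coordinates and per-axis explained fractions."""

    sample_ids: list[str]
    coordinates: np.ndarray
    explained_fraction: np.ndarray
    eigenvalues: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def richness(presence: PresenceMatrix) -> pd.Series:
    """Per-sample gene richness: column sums of the presence matrix."""
    counts = presence.presence.sum(axis=0).astype(int)
    return pd.Series(counts, index=presence.sample_ids, name="richness")


def _subset_rel(table: GeneAbundanceTable, subset) -> np.ndarray:
    rel = table.relative_abundance()
    if subset is None:
        return rel
    subset = list(subset)
    present = [g for g in table.gene_ids if g in set(subset)]
    if not present:
        raise ValueError("gene subset is disjoint from the table")
    return rel[table.gene_index(present)]


def bray_curtis(
    table: GeneAbundanceTable, subset=None, renormalize: bool = False
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    d(i, j) = 1 - 2 * sum_g min(p_gi, p_gj) / (sum_g p_gi + sum_g p_gj),
    with p the relative abundances over the *full* sample totals, restricted
    to ``subset`` when given. ``renormalize=True`` rescales the subset
    profiles to sum to one first (numerically minor for a ~99.8%-mass core
    set, but the choice is explicit).
    """
    rel = _subset_rel(table, subset)
    if renormalize:
        colsum = rel.sum(axis=0)
        if np.any(colsum == 0):
            raise ValueError("cannot renormalize a sample with zero subset mass")
        rel = rel / colsum
    d = _bray_curtis_columns(rel)
    label = "bray-curtis" + ("" if subset is None else "-subset")
    return DistanceMatrix(list(table.sample_ids), d, label)


def _bray_curtis_columns(profile: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis between the columns of a non-negative matrix.

    Columns with zero mass get dissimilarity 1 to everything (0 to another
    empty column would be 0/0; 1 is the flagged convention here).
    """
    cols = profile.T
    mass = cols.sum(axis=1)
    empty = mass == 0
    n = cols.shape[0]
    d = np.zeros((n, n))
    ok = ~empty
    if ok.sum() >= 2:
        sub = cols[ok]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d_ok = squareform(pdist(sub, metric="braycurtis"))
        d[np.ix_(ok, ok)] = d_ok
    if empty.any():
        d[empty, :] = 1.0
        d[:, empty] = 1.0
        np.fill_diagonal(d, 0.0)
        logger.warning(
            "%d sample(s) with zero mass in the requested subset; their "
            "pairwise dissimilarities are defined as 1",
            int(empty.sum()),
        )
    return d


def presence_dissimilarity(presence: PresenceMatrix, subset=None) -> DistanceMatrix:
    """Bray-Curtis on 0/1 presence data, i.e. Sorensen dissimilarity.

    1 - 2a/(2a + b + c) with a the shared presences and b, c the presences
    unique to either sample. A sample with no presences in the subset gets
    dissimilarity 1 to every other sample (flagged in the log).
    """
    mat = presence.presence
    if subset is not None:
        keep = set(subset)
        idx = [i for i, g in enumerate(presence.gene_ids) if g in keep]
        if not idx:
            raise ValueError("gene subset is disjoint from the presence matrix")
        mat = mat[np.array(idx, dtype=int)]
    d = _bray_curtis_columns(mat.astype(float))
    return DistanceMatrix(list(presence.sample_ids), d, "sorensen")


def pcoa(
    d: DistanceMatrix, n_axes: int | None = None, correction: str | None = None
) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their eigenvalues. Negative eigenvalues (common for
    Bray-Curtis, which is not Euclidean-embeddable) are dropped from both
    the coordinates and the explained-variance denominator, with their total
    magnitude logged; ``correction='lingoes'`` instead adds the constant
    -2*lambda_min to all squared off-diagonal distances, which makes the
    matrix embeddable.
    """
    n = d.n_samples
    if n_axes is None:
        n_axes = n - 1
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    if n_axes > n - 1:
        raise ValueError("n_axes cannot exceed n_samples - 1")

    def _eigen(sq):
        centerer = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * centerer @ sq @ centerer
        b = (b + b.T) / 2.0
        vals, vecs = np.linalg.eigh(b)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    sq = d.values**2
    vals, vecs = _eigen(sq)
    if correction == "lingoes" and vals[-1] < -1e-12:
        c = -vals[-1]
        sq = sq + 2.0 * c
        np.fill_diagonal(sq, 0.0)
        vals, vecs = _eigen(sq)
    elif correction not in (None, "lingoes"):
        raise ValueError("correction must be None or 'lingoes'")

    tol = max(1e-12, 1e-10 * max(abs(vals[0]), 1.0))
    neg = vals < -tol
    if neg.any():
        logger.warning(
            "PCoA: dropping %d negative eigenvalue(s), total magnitude %.3g "
            "(%.2f%% of positive total)",
            int(neg.sum()),
            float(-vals[neg].sum()),
            100.0 * -vals[neg].sum() / vals[vals > tol].sum(),
        )
    pos = np.where(vals > tol)[0]
    pos_vals = vals[pos]
    k = min(n_axes, len(pos))
    coords = vecs[:, pos[:k]] * np.sqrt(pos_vals[:k])
    explained = pos_vals[:k] / pos_vals.sum() if len(pos) else np.zeros(0)
    return OrdinationResult(
        list(d.sample_ids), coords, explained, pos_vals[:k]
    )


def average_genome_size(
    taxon_relabund: pd.DataFrame, genome_sizes: pd.Series
) -> pd.Series:
    """Cell-abundance-weighted average genome size per sample.

    ``taxon_relabund`` is taxon x sample with columns summing to 1;
    ``genome_sizes`` maps taxon -> genome length in bases. Weighting is by
    cell (taxon) relative abundance: AGS[s] = sum_t p_ts * g_t.
    """
    colsums = taxon_relabund.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-9):
        bad = colsums.index[np.abs(colsums - 1.0) > 1e-9].tolist()
        raise ValueError(f"taxon relative abundances must sum to 1; bad samples: {bad}")
    missing = [t for t in taxon_relabund.index if t not in genome_sizes.index]
    if missing:
        raise KeyError(f"missing genome sizes for taxa: {missing[:5]}")
    sizes = genome_sizes.loc[taxon_relabund.index].astype(float)
    ags = taxon_relabund.mul(sizes, axis=0).sum(axis=0)
    ags.name = "average_genome_size"
    return ags
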