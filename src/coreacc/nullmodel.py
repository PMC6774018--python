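"""Raup-Crick-style null model for community assembly.

The question the model answers: are samples within a treatment group more
similar in gene content than expected if each sample assembled its observed
number of genes at random from the regional pool? Randomized assemblages
conserve each sample's richness exactly and draw genes without replacement
with probability proportional to their occupancy across samples (how many
samples each gene occupies), or uniformly. The standardized effect size

    SES = (observed mean within-group similarity - null mean) / null SD

is positive when ecological filtering (deterministic, shared selection)
makes co-treated communities converge, and near zero under stochastic
assembly. Similarity is 1 - Sorensen dissimilarity on presence/absence by
default; an abundance variant reassigns each sample's positive counts to
its randomized gene set and scores 1 - Bray-Curtis.

The model class follows the statsmodels convention: construct from data,
``fit()`` returns a results object with estimates and ``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition import PresenceMatrix
from .tables import GeneAbundanceTable

__all__ = [
    "NullModelConfig",
    "SESResult",
    "RaupCrickModel",
    "RaupCrickResults",
    "randomize_assemblage",
    "ses_similarity",
    "compare_ses_between_factors",
]

logger = logging.getLogger(__name__)


@dataclass
class NullModelConfig:
    """Knobs of the null model.

    n_randomizations : size of the Monte-Carlo null distribution (>= 99).
    similarity_basis : 'presence' (Sorensen) or 'abundance' (Bray-Curtis on
        counts reassigned to the randomized gene sets).
    occupancy_weighting : draw genes with probability proportional to the
        number of samples they occupy (True) or uniformly (False).
    """

    n_randomizations: int = 999
    seed: int | None = None
    similarity_basis: str = "presence"
    occupancy_weighting: bool = True

    def __post_init__(self) -> None:
        if self.n_randomizations < 99:
            raise ValueError("n_randomizations must be >= 99")
        if self.similarity_basis not in ("presence", "abundance"):
            raise ValueError("similarity_basis must be 'presence' or 'abundance'")


@dataclass
class SESResult:
    """Observed vs null within-group similarity for one sample group."""

    group_label: str
    observed_mean_similarity: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_randomizations: int
    degenerate: bool = False


def _weighted_subset_draws(
    weights: np.ndarray, richness: np.ndarray, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Fixed-richness draws without replacement, weight-proportional.

    Uses exponential sort keys (Efraimidis-Spirakis): the ``k`` items with
    the smallest Exp(1)/w key form a without-replacement sample with
    inclusion proportional to ``w``. Returns a boolean array of shape
    (n_reps, n_samples, n_genes).
    """
    n_samples = len(richness)
    n_genes = len(weights)
    with np.errstate(divide="ignore"):
        keys = rng.exponential(size=(n_reps, n_samples, n_genes)) / weights
    out = np.zeros((n_reps, n_samples, n_genes), dtype=bool)
    for s in range(n_samples):
        k = int(richness[s])
        if k == 0:
            continue
        if k == n_genes:
            out[:, s, :] = True
            continue
        idx = np.argpartition(keys[:, s, :], k - 1, axis=1)[:, :k]
        np.put_along_axis(out[:, s, :], idx, True, axis=1)
    return out


def _pool_weights(presence: PresenceMatrix, occupancy_weighting: bool) -> np.ndarray:
    """Sampling weight per gene of the supplied matrix.

    Every row of the matrix belongs to the pool. Under occupancy weighting a
    gene's weight is the number of samples it occupies (zero-occupancy rows
    are then never drawn); under uniform weighting all rows weigh equally.
    """
    occ = presence.presence.sum(axis=1)
    return occ.astype(float) if occupancy_weighting else np.ones(len(occ))


def randomize_assemblage(
    presence: PresenceMatrix,
    rng: np.random.Generator,
    occupancy_weighting: bool = True,
) -> PresenceMatrix:
    """One randomized assemblage conserving per-sample richness exactly."""
    weights = _pool_weights(presence, occupancy_weighting)
    richness = presence.presence.sum(axis=0)
    if np.any(richness > (weights > 0).sum()):
        raise ValueError("a sample's richness exceeds the gene pool size")
    draws = _weighted_subset_draws(weights, richness, 1, rng)[0]
    return PresenceMatrix(
        list(presence.gene_ids), list(presence.sample_ids), draws.T,
        presence.threshold_used,
    )


def _sorensen_similarity_pairs(mat: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """1 - Sorensen for the given (i, j) sample pairs; mat is samples x genes."""
    a = np.einsum("ig,jg->ij", mat.astype(np.float64), mat.astype(np.float64))
    r = mat.sum(axis=1).astype(float)
    i, j = pairs[:, 0], pairs[:, 1]
    denom = r[i] + r[j]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * a[i, j] / denom, 0.0)
    return sim


def _bray_similarity_pairs(cols: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """1 - Bray-Curtis for given sample pairs; cols is samples x genes counts."""
    i, j = pairs[:, 0], pairs[:, 1]
    mins = np.minimum(cols[i], cols[j]).sum(axis=1)
    sums = cols[i].sum(axis=1) + cols[j].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, 2.0 * mins / sums, 0.0)


def _rank_p_two_sided(observed: float, null: np.ndarray) -> float:
    n = len(null)
    ge = int(np.sum(null >= observed))
    le = int(np.sum(null <= observed))
    p = 2.0 * min(ge + 1, le + 1) / (n + 1)
    return min(1.0, p)


class RaupCrickModel:
    """Null-model comparison of within-group similarity against random assembly.

    Parameters
    ----------
    presence : PresenceMatrix
        Gene x sample presence calls (typically the post-filter matrix or
        its accessory-gene restriction).
    groups : mapping, pandas Series or list
        Group label per sample (aligned with ``presence.sample_ids`` when a
        list; keyed by sample id otherwise).
    config : NullModelConfig
    table : GeneAbundanceTable, optional
        Required for ``similarity_basis='abundance'``.
    """

    def __init__(self, presence, groups, config=None, table: GeneAbundanceTable | None = None):
        self.presence = presence
        self.config = config or NullModelConfig()
        if isinstance(groups, pd.Series):
            groups = groups.reindex(presence.sample_ids).tolist()
        elif isinstance(groups, dict):
            groups = [groups[s] for s in presence.sample_ids]
        else:
            groups = list(groups)
        if len(groups) != presence.n_samples:
            raise ValueError("one group label required per sample")
        self.groups = [str(g) for g in groups]
        self.table = table
        if self.config.similarity_basis == "abundance" and table is None:
            raise ValueError("abundance similarity basis requires the count table")

    # ------------------------------------------------------------------
    def _group_pairs(self):
        order = list(dict.fromkeys(self.groups))
        idx = {g: [i for i, lbl in enumerate(self.groups) if lbl == g] for g in order}
        kept, pairs = [], []
        for g in order:
            members = idx[g]
            if len(members) < 2:
                warnings.warn(f"group {g!r} has fewer than 2 samples; skipped")
                continue
            kept.append(g)
            pairs.append(
                np.array([(i, j) for k, i in enumerate(members) for j in members[k + 1:]])
            )
        if not kept:
            raise ValueError("no group with >= 2 samples")
        return kept, idx, pairs

    def _observed_matrix(self) -> np.ndarray:
        return self.presence.presence.T  # samples x genes

    def _similarity(self, mat: np.ndarray, pairs: np.ndarray, counts=None) -> np.ndarray:
        if self.config.similarity_basis == "presence":
            return _sorensen_similarity_pairs(mat, pairs)
        return _bray_similarity_pairs(counts, pairs)

    def _null_counts(self, draws: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Reassign each sample's positive counts to its randomized genes."""
        obs_counts = self.table.counts.T  # samples x genes
        null = np.zeros_like(draws, dtype=float)
        for rep in range(draws.shape[0]):
            for s in range(draws.shape[1]):
                vals = obs_counts[s][obs_counts[s] > 0]
                slots = np.where(draws[rep, s])[0]
                null[rep, s, slots] = rng.permutation(vals)[: len(slots)]
        return null

    def fit(self) -> "RaupCrickResults":
        cfg = self.config
        weights = _pool_weights(self.presence, cfg.occupancy_weighting)
        n_pool = int((weights > 0).sum())
        obs = self._observed_matrix()
        richness = obs.sum(axis=1)
        if np.any(richness > n_pool):
            raise ValueError("a sample's richness exceeds the gene pool size")
        kept, group_idx, group_pairs = self._group_pairs()
        all_pairs = np.vstack(group_pairs)
        pair_group = np.concatenate(
            [np.full(len(p), gi) for gi, p in enumerate(group_pairs)]
        )

        counts_obs = None
        if cfg.similarity_basis == "abundance":
            counts_obs = self.table.counts.T.astype(float)
        obs_pair_sim = self._similarity(obs, all_pairs, counts_obs)

        rng = np.random.default_rng(cfg.seed)
        n_reps = cfg.n_randomizations
        null_pair_sim = np.empty((n_reps, len(all_pairs)))
        # chunk the randomizations to bound the (reps, samples, genes) array
        chunk = max(1, int(2.0e7 // max(1, obs.shape[0] * len(weights))))
        done = 0
        while done < n_reps:
            m = min(chunk, n_reps - done)
            draws = _weighted_subset_draws(weights, richness, m, rng)
            if cfg.similarity_basis == "abundance":
                null_counts = self._null_counts(draws, rng)
                for r in range(m):
                    null_pair_sim[done + r] = _bray_similarity_pairs(
                        null_counts[r], all_pairs
                    )
            else:
                for r in range(m):
                    null_pair_sim[done + r] = _sorensen_similarity_pairs(
                        draws[r], all_pairs
                    )
            done += m

        group_results = []
        for gi, g in enumerate(kept):
            sel = pair_group == gi
            obs_mean = float(obs_pair_sim[sel].mean())
            null_means = null_pair_sim[:, sel].mean(axis=1)
            mu, sd = float(null_means.mean()), float(null_means.std(ddof=1))
            degenerate = sd == 0.0
            ses = np.nan if degenerate else (obs_mean - mu) / sd
            p = 1.0 if degenerate else _rank_p_two_sided(obs_mean, null_means)
            if degenerate:
                logger.warning("null distribution for group %r is degenerate", g)
            group_results.append(
                SESResult(g, obs_mean, mu, sd, float(ses), float(p), n_reps, degenerate)
            )

        # per-sample SES: mean similarity of a sample to its group mates
        sample_ids = self.presence.sample_ids
        per_sample = {}
        for gi, g in enumerate(kept):
            for s in group_idx[g]:
                sel = (pair_group == gi) & ((all_pairs[:, 0] == s) | (all_pairs[:, 1] == s))
                obs_s = obs_pair_sim[sel].mean()
                null_s = null_pair_sim[:, sel].mean(axis=1)
                sd = null_s.std(ddof=1)
                per_sample[sample_ids[s]] = (
                    np.nan if sd == 0 else (obs_s - null_s.mean()) / sd
                )
        per_sample_ses = pd.Series(per_sample, name="ses").reindex(
            [s for g in kept for s in (sample_ids[i] for i in group_idx[g])]
        )

        # per-pair SES against each pair's own null distribution
        sd_pairs = null_pair_sim.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_pair_ses = np.where(
                sd_pairs > 0,
                (obs_pair_sim - null_pair_sim.mean(axis=0)) / sd_pairs,
                np.nan,
            )
        pair_frame = pd.DataFrame(
            {
                "sample_i": [sample_ids[i] for i, _ in all_pairs],
                "sample_j": [sample_ids[j] for _, j in all_pairs],
                "group": [kept[gi] for gi in pair_group],
                "observed_similarity": obs_pair_sim,
                "ses": per_pair_ses,
            }
        )
        return RaupCrickResults(self, group_results, per_sample_ses, pair_frame)


@dataclass
class RaupCrickResults:
    """Fitted null-model results: per-group SES, per-sample and per-pair SES."""

    model: RaupCrickModel
    group_results: list[SESResult]
    per_sample_ses: pd.Series
    per_pair: pd.DataFrame = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": r.group_label,
                    "observed_similarity": r.observed_mean_similarity,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "ses": r.ses,
                    "p_value": r.p_value,
                }
                for r in self.group_results
            ]
        ).set_index("group")

    def summary(self) -> str:
        cfg = self.model.config
        head = (
            "Raup-Crick null model "
            f"({cfg.n_randomizations} randomizations, "
            f"{'occupancy' if cfg.occupancy_weighting else 'uniform'} weighting, "
            f"{cfg.similarity_basis} similarity)\n"
        )
        return head + self.summary_frame().to_string(float_format=lambda x: f"{x:.4f}")


def ses_similarity(presence, groups, cfg: NullModelConfig | None = None, table=None):
    """Functional facade over :class:`RaupCrickModel` -> list of SESResult."""
    res = RaupCrickModel(presence, groups, cfg, table).fit()
    return res


def compare_ses_between_factors(results: RaupCrickResults, design):
    """Split-plot ANOVA on per-sample SES values across the 2x2 design.

    Uses sample-level SES (one value per subplot) rather than pair-level
    values, which would pseudo-replicate: pairs within a group share samples
    and are not independent.
    """
    from .stats import SplitPlotAnova

    ses = results.per_sample_ses.reindex(design.sample_ids)
    if ses.isna().any():
        missing = ses.index[ses.isna()].tolist()
        raise ValueError(f"no SES value for samples: {missing[:5]}")
    return SplitPlotAnova(ses, design).fit()
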