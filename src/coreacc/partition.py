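"""Rare-gene presence filtering and the core/accessory partition.

A gene family is called present in a sample when its relative abundance
(count over the full per-sample annotation total) reaches the detection
threshold. With shotgun annotation totals above 2e6 per sample, the default
threshold of 5e-7 amounts to "at least one confident hit" — roughly one read
at that depth. Core genes are those present in *every* sample of the set;
accessory genes are present in at least one but not all samples. Richness is
then dominated by accessory genes while nearly all annotation mass
(~99.8% in the grassland soils this package models) sits in the core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import GeneAbundanceTable

__all__ = [
    "PresenceMatrix",
    "PartitionResult",
    "call_presence",
    "partition_core_accessory",
    "component_tables",
    "DEFAULT_GENE_THRESHOLD",
    "OTU_THRESHOLD",
]

#: Detection threshold for functional-gene tables (~1 read at 2e6 annotations).
DEFAULT_GENE_THRESHOLD = 5.0e-7
#: Equivalent threshold used for 16S OTU tables (1 fragment in the smallest
#: sample, which carried 892 assigned fragments). Same operation, different value.
OTU_THRESHOLD = 1.0 / 892.0


@dataclass
class PresenceMatrix:
    """Boolean gene x sample presence calls plus the threshold that made them."""

    gene_ids: list[str]
    sample_ids: list[str]
    presence: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("presence shape does not match ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, genes) -> "PresenceMatrix":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([lookup[g] for g in genes], dtype=int)
        return PresenceMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.presence[idx],
            self.threshold_used,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence.astype(int), index=self.gene_ids, columns=self.sample_ids
        )


@dataclass
class PartitionResult:
    """Core/accessory/absent gene sets with per-sample component summaries.

    Component relative abundances are computed against each sample's full
    annotation total, so mass removed by the rare-gene filter still counts in
    the denominator (core + accessory collective abundance can fall slightly
    short of 1).
    """

    core_genes: set
    accessory_genes: set
    absent_genes: set
    sample_ids: list[str]
    per_sample_core_relabund: np.ndarray
    per_sample_accessory_relabund: np.ndarray
    per_sample_accessory_count: np.ndarray
    threshold_used: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "core_relabund": self.per_sample_core_relabund,
                "accessory_relabund": self.per_sample_accessory_relabund,
                "accessory_count": self.per_sample_accessory_count,
            },
            index=self.sample_ids,
        )

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold_used,
            "n_core": len(self.core_genes),
            "n_accessory": len(self.accessory_genes),
            "n_absent": len(self.absent_genes),
            "core_genes": sorted(self.core_genes),
            "accessory_genes": sorted(self.accessory_genes),
            "absent_genes": sorted(self.absent_genes),
            "sample_ids": list(self.sample_ids),
            "per_sample_core_relabund": self.per_sample_core_relabund.tolist(),
            "per_sample_accessory_relabund": self.per_sample_accessory_relabund.tolist(),
            "per_sample_accessory_count": self.per_sample_accessory_count.tolist(),
        }


def call_presence(
    table: GeneAbundanceTable,
    threshold: float = DEFAULT_GENE_THRESHOLD,
    scope: str = "per-sample",
) -> PresenceMatrix:
    """Call gene presence per sample from relative abundance.

    presence[g, s] = counts[g, s] / total[s] >= threshold and counts[g, s] > 0.
    The comparison is inclusive so the one-read-at-depth boundary counts as
    present. ``scope='global'`` instead drops a gene everywhere unless it
    reaches the threshold in at least one sample (richness calls then ignore
    sub-threshold occurrences only for genes that never clear it).
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    if scope not in ("per-sample", "global"):
        raise ValueError("scope must be 'per-sample' or 'global'")
    rel = table.relative_abundance()
    presence = (rel >= threshold) & (table.counts > 0)
    if scope == "global":
        keep = presence.any(axis=1)
        presence = (table.counts > 0) & keep[:, None]
    return PresenceMatrix(
        list(table.gene_ids), list(table.sample_ids), presence, threshold
    )


def partition_core_accessory(
    presence: PresenceMatrix, table: GeneAbundanceTable
) -> PartitionResult:
    """Split genes into core (present everywhere), accessory and absent sets.

    Requires >= 2 samples; with a single sample the core/accessory contrast
    is undefined. Component relative abundances use the unfiltered per-sample
    totals as denominator.
    """
    if presence.gene_ids != table.gene_ids or presence.sample_ids != table.sample_ids:
        raise ValueError("presence matrix and table must share gene and sample ids")
    if presence.n_samples < 2:
        raise ValueError("core/accessory partition requires at least 2 samples")
    occupancy = presence.presence.sum(axis=1)
    n = presence.n_samples
    gene_arr = np.asarray(presence.gene_ids, dtype=object)
    core_mask = occupancy == n
    absent_mask = occupancy == 0
    accessory_mask = ~core_mask & ~absent_mask
    rel = table.relative_abundance()
    core_rel = rel[core_mask].sum(axis=0)
    # accessory mass counts only where the gene is actually called present
    acc_rel = (rel[accessory_mask] * presence.presence[accessory_mask]).sum(axis=0)
    acc_count = presence.presence[accessory_mask].sum(axis=0)
    return PartitionResult(
        core_genes=set(gene_arr[core_mask]),
        accessory_genes=set(gene_arr[accessory_mask]),
        absent_genes=set(gene_arr[absent_mask]),
        sample_ids=list(table.sample_ids),
        per_sample_core_relabund=core_rel,
        per_sample_accessory_relabund=acc_rel,
        per_sample_accessory_count=acc_count.astype(int),
        threshold_used=presence.threshold_used,
    )


def component_tables(
    table: GeneAbundanceTable,
    partition: PartitionResult,
    presence: PresenceMatrix,
) -> tuple[GeneAbundanceTable, PresenceMatrix]:
    """Return (core abundance subtable, accessory presence submatrix).

    The core subtable keeps raw counts (relative abundances stay defined
    against the full totals); the accessory submatrix is the boolean presence
    restricted to accessory genes. An empty accessory set yields a 0-row
    submatrix, which downstream dissimilarities must tolerate; an empty core
    set is an error because every abundance-based analysis downstream would
    be empty — the presence threshold is likely set too high.
    """
    if not partition.core_genes:
        raise ValueError(
            "empty core gene set: review the presence threshold before "
            "requesting component tables"
        )
    core_sorted = [g for g in table.gene_ids if g in partition.core_genes]
    acc_sorted = [g for g in table.gene_ids if g in partition.accessory_genes]
    core_table = table.subset_genes(core_sorted)
    acc_presence = PresenceMatrix(
        acc_sorted,
        list(presence.sample_ids),
        presence.presence[presence_index(presence, acc_sorted)]
        if acc_sorted
        else np.zeros((0, presence.n_samples), dtype=bool),
        presence.threshold_used,
    )
    return core_table, acc_presence


def presence_index(presence: PresenceMatrix, genes) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(presence.gene_ids)}
    return np.array([lookup[g] for g in genes], dtype=int)
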