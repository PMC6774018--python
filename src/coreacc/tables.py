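"""Core data containers: gene abundance tables, experimental designs, covariates.

The gene table stores raw integer annotation counts only; relative abundances
are always derived on demand against the per-sample annotation total, so there
is a single source of truth for the denominator used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneAbundanceTable",
    "ExperimentalDesign",
    "CovariateTable",
    "TableFormatError",
]


class TableFormatError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise TableFormatError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class GeneAbundanceTable:
    """Gene-family x sample matrix of integer annotation counts.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene-family identifiers (e.g. COG or KO accessions), row order.
    sample_ids : list of str
        Unique sample identifiers, column order.
    counts : ndarray of int, shape (n_genes, n_samples)
        Non-negative annotation counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 1:
            raise TableFormatError("no genes")
        if len(self.sample_ids) < 2:
            raise TableFormatError("at least 2 samples required")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            rounded = np.rint(as_int)
            if not np.all(np.isfinite(as_int)) or np.any(rounded != as_int):
                raise TableFormatError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        """Per-sample annotation totals (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Counts divided by the full per-sample annotation total.

        The denominator is always the unfiltered column sum, so component
        subtables keep the community-wide scale.
        """
        totals = self.sample_totals.astype(float)
        if np.any(totals == 0):
            raise TableFormatError("sample with zero total annotations")
        return self.counts / totals

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of the given gene ids (order preserved)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in table: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes) -> "GeneAbundanceTable":
        idx = self.gene_index(genes)
        return GeneAbundanceTable(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneAbundanceTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())


_TRUTHY = {"1", "true", "yes", "t", "y"}
_FALSY = {"0", "false", "no", "f", "n"}


def parse_bool(value) -> bool:
    """Parse the boolean-like treatment codes found in field metadata."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise TableFormatError(f"cannot parse boolean value {value!r}")


@dataclass
class ExperimentalDesign:
    """Sample -> block / N / W assignment of a split-plot field layout.

    N addition is the whole-plot factor (applied to large plots within
    blocks), W addition the subplot factor.
    """

    sample_ids: list[str]
    block: list[str]
    n_treatment: list[bool]
    w_treatment: list[bool]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.block) == len(self.n_treatment) == len(self.w_treatment) == n):
            raise TableFormatError("design columns have unequal lengths")
        _check_unique(self.sample_ids, "sample ids")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.block = [str(b) for b in self.block]
        self.n_treatment = [parse_bool(v) for v in self.n_treatment]
        self.w_treatment = [parse_bool(v) for v in self.w_treatment]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def blocks(self) -> list[str]:
        return sorted(set(self.block))

    @property
    def is_complete(self) -> bool:
        """True when every block contains all four N x W cells exactly once."""
        cells: dict[tuple, int] = {}
        for b, n, w in zip(self.block, self.n_treatment, self.w_treatment):
            cells[(b, n, w)] = cells.get((b, n, w), 0) + 1
        expected = {(b, n, w) for b in self.blocks for n in (False, True) for w in (False, True)}
        return set(cells) == expected and all(v == 1 for v in cells.values())

    def treatment_labels(self) -> list[str]:
        """Four-level treatment label per sample: control / N / W / NW."""
        out = []
        for n, w in zip(self.n_treatment, self.w_treatment):
            out.append("NW" if (n and w) else "N" if n else "W" if w else "control")
        return out

    def reorder(self, sample_ids) -> "ExperimentalDesign":
        """Design restricted/reordered to the given samples."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise TableFormatError(f"samples missing from design: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return ExperimentalDesign(
            [self.sample_ids[i] for i in idx],
            [self.block[i] for i in idx],
            [self.n_treatment[i] for i in idx],
            [self.w_treatment[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "block": self.block,
                "N": np.array(self.n_treatment, dtype=int),
                "W": np.array(self.w_treatment, dtype=int),
            }
        )


@dataclass
class CovariateTable:
    """Per-sample numeric covariates (soil, plant and microbial indices)."""

    data: pd.DataFrame = field()

    def __post_init__(self) -> None:
        if "sample_id" in self.data.columns:
            self.data = self.data.set_index("sample_id")
        _check_unique(list(self.data.index), "sample ids")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise TableFormatError(f"missing values in covariates: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def covariates(self) -> list[str]:
        return list(self.data.columns)
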