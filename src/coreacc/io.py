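"""Reading and writing of gene tables, designs, covariates and result bundles.

All formats are plain text: TSV/CSV matrices with a header row and row labels
in the first column, square labeled TSV for distance matrices, and flat JSON
for scalar statistics. Result bundles come with a manifest carrying a SHA-256
checksum per file so reruns can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CovariateTable, ExperimentalDesign, GeneAbundanceTable, TableFormatError

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_design",
    "write_design",
    "read_covariates",
    "ResultBundle",
    "write_results",
]

_SEPS = {"tsv": "\t", "csv": ","}


def _read_matrix(path, dialect: str) -> pd.DataFrame:
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}")
    df = pd.read_csv(path, sep=_SEPS[dialect], index_col=0, dtype={0: str})
    return df


def read_gene_table(path, dialect: str = "tsv") -> GeneAbundanceTable:
    """Read a gene x sample count matrix.

    First column holds gene ids, the header row sample ids, the body integer
    counts. Missing cells, negative or non-numeric values and duplicated ids
    are all hard errors — silent zero-filling would corrupt presence calls.
    """
    df = _read_matrix(path, dialect)
    if df.shape[0] == 0:
        raise TableFormatError(f"{path}: no genes")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise TableFormatError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            gene = df.index[vals.isna()][0]
            raise TableFormatError(
                f"{path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
        if (vals < 0).any():
            gene = df.index[vals < 0][0]
            raise TableFormatError(
                f"{path}: negative count at gene {gene!r}, sample {col!r}"
            )
        if (np.rint(vals) != vals).any():
            gene = df.index[np.rint(vals) != vals][0]
            raise TableFormatError(
                f"{path}: non-integer count at gene {gene!r}, sample {col!r}"
            )
        df[col] = vals.astype(np.int64)
    return GeneAbundanceTable(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


def write_gene_table(table: GeneAbundanceTable, path, dialect: str = "tsv") -> None:
    table.to_dataframe().to_csv(path, sep=_SEPS[dialect], index_label="gene_id")


def read_design(path, dialect: str = "tsv") -> ExperimentalDesign:
    """Read a sample -> block/N/W design table.

    Expects columns ``sample_id``, ``block``, ``N``, ``W``; N/W accept
    {0,1,true,false,yes,no} case-insensitively. Completeness of the balanced
    split-plot layout is reported by ``ExperimentalDesign.is_complete``, not
    enforced (an incomplete design is data, not an error).
    """
    df = pd.read_csv(path, sep=_SEPS[dialect], dtype=str)
    required = ["sample_id", "block", "N", "W"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing design columns {missing}")
    return ExperimentalDesign(
        list(df["sample_id"]), list(df["block"]), list(df["N"]), list(df["W"])
    )


def write_design(design: ExperimentalDesign, path, dialect: str = "tsv") -> None:
    design.to_dataframe().to_csv(path, sep=_SEPS[dialect], index=False)


def read_covariates(path, dialect: str = "tsv") -> CovariateTable:
    df = pd.read_csv(path, sep=_SEPS[dialect], dtype={0: str})
    return CovariateTable(df)


@dataclass
class ResultBundle:
    """Collection of analysis outputs destined for disk.

    distance_matrices map a name to a ``DistanceMatrix``; tables map a name
    to a DataFrame; scalars is a flat key -> number/string mapping.
    """

    distance_matrices: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    scalars: dict = field(default_factory=dict)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def write_results(bundle: ResultBundle, out_dir) -> dict:
    """Write a result bundle and return its manifest.

    Distance matrices become square labeled TSVs, tables plain TSVs and
    scalars one flat ``scalars.json``. The manifest (also written as
    ``manifest.json``) lists every file with its SHA-256 checksum; identical
    inputs therefore yield identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, dm in sorted(bundle.distance_matrices.items()):
        path = out / f"{name}.distance.tsv"
        df = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids)
        df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")
        written.append(path)
    for name, df in sorted(bundle.tables.items()):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", float_format="%.12g")
        written.append(path)
    if bundle.scalars:
        path = out / "scalars.json"
        write_json(bundle.scalars, path)
        written.append(path)
    manifest = {
        "files": [
            {"path": p.name, "sha256": sha256_file(p)} for p in sorted(written)
        ]
    }
    write_json(manifest, out / "manifest.json")
    return manifest
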