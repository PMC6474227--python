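"""Readers and writers for the TSV/MTX interchange formats.

Canonical on-disk layout: tab-delimited UTF-8 tables with a header row.
Count matrices have genes as rows (first column ``gene_id``) and one
column per sample. Matrix Market (.mtx) coordinate integer matrices are
supported for sparse inputs, with companion plain-text gene and sample
index files (one id per line).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .containers import CountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "read_traits",
    "write_table",
    "write_manifest",
]

SCHEMA_VERSION = "1"


def read_count_matrix(
    path,
    format: str | None = None,
    organism: str = "host",
    genes_path=None,
    samples_path=None,
) -> CountMatrix:
    """Read a gene x sample count matrix from TSV or Matrix Market.

    For ``mtx``, companion index files default to
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` next to the matrix.
    Entries must be non-negative integers; duplicate gene ids raise.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        gene_col = df.columns[0]
        df = df.set_index(gene_col)
        df.index.name = "gene_id"
        mat = df
    elif format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.with_suffix("").with_suffix(".genes.txt")
        samples_path = (
            Path(samples_path) if samples_path else path.with_suffix("").with_suffix(".samples.txt")
        )
        genes = [ln.strip() for ln in genes_path.read_text().splitlines() if ln.strip()]
        samples = [ln.strip() for ln in samples_path.read_text().splitlines() if ln.strip()]
        m = mmread(str(path)).toarray()
        mat = pd.DataFrame(m, index=pd.Index(genes, name="gene_id"), columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")

    arr = mat.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.argwhere(~np.char.isnumeric(arr.astype(str)))
        r, c = (bad[0] if len(bad) else (0, 0))
        raise ValueError(
            f"non-numeric entry at row {mat.index[r]!r}, column {mat.columns[c]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"non-integer count at row {mat.index[r]!r}, column {mat.columns[c]!r}"
        )
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at row {mat.index[r]!r}, column {mat.columns[c]!r}"
        )
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"duplicated gene id {dup!r}")
    return CountMatrix(mat.astype(np.int64), organism=organism)


def write_count_matrix(cm: CountMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df = cm.counts.copy()
        df.insert(0, "gene_id", df.index)
        df.to_csv(path, sep="\t", index=False)
    elif format == "mtx":
        mmwrite(str(path), csr_matrix(cm.counts.to_numpy()), field="integer")
        path.with_suffix("").with_suffix(".genes.txt").write_text(
            "\n".join(map(str, cm.gene_ids)) + "\n"
        )
        path.with_suffix("").with_suffix(".samples.txt").write_text(
            "\n".join(map(str, cm.sample_ids)) + "\n"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cultivar", "fungal_treatment"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    return meta.set_index("sample_id", drop=False)


def read_traits(path) -> pd.DataFrame:
    traits = pd.read_csv(path, sep="\t")
    return traits.set_index("sample_id")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def config_hash(config_dict: dict) -> str:
    """Hash of the analysis-relevant configuration.

    The output directory does not influence any computed value and is
    excluded, so reruns into different directories share a hash.
    """
    relevant = {k: v for k, v in config_dict.items() if k != "outdir"}
    canon = json.dumps(relevant, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(path, config_dict: dict, seed: int, outputs: dict) -> dict:
    from . import __version__

    manifest = {
        "package": "mycorrnet",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": config_hash(config_dict),
        "config": config_dict,
        "outputs": sorted(outputs),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
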