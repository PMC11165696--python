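"""Readers and writers for the pipeline's plain-text artifacts.

Count tables and metadata travel as TSV (samples as rows, first column the
sample id, header row of genus / variable names); fitted models and audits
as JSON. Integer tables round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a sample x genus integer count table from TSV.

    Raises informative errors on duplicated sample ids, negative counts
    (named by row and column) and non-integer values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in count table: {exc}") from exc
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at sample {df.index[i]!r}, genus {df.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(
            f"non-integer count at sample {df.index[i]!r}, genus {df.columns[j]!r}"
        )
    out = df.astype(np.int64)
    out.index.name = "sample_id"
    return out


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata table (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids: {dups}")
    df.index.name = "sample_id"
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_model(bundle: dict, path: str | Path) -> None:
    """Serialise a model bundle (measurement submodel + risk model) as JSON."""
    write_json(bundle, path)


def read_model(path: str | Path) -> dict:
    return read_json(path)
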