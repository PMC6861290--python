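"""TSV and BIOM readers/writers for the pipeline's tables.

All tabular artefacts are plain TSV: count tables (features as rows, first
column the feature id), seven-rank taxonomy tables, sample metadata, SV
attributes, square distance matrices, and edge lists. A minimal BIOM 1.0
(JSON) export/import is provided for interop with other microbiome tools.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RANKS, CountTable, DistanceMatrix, SampleMetadata, SVAttributes, TaxonomyTable


def write_count_table(table: CountTable, path) -> None:
    df = table.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_count_table(path, axis_rank: str = "SV") -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return CountTable(df.astype(np.int64), axis_rank)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    for rank in RANKS:
        if rank not in df.columns:
            raise ValueError(f"taxonomy file missing rank column {rank!r}")
    return TaxonomyTable(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    return SampleMetadata(df)


def write_sv_attributes(attrs: SVAttributes, path) -> None:
    df = attrs.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_sv_attributes(path) -> SVAttributes:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df["length"] = df["length"].astype(int)
    df["is_control"] = df["is_control"].astype(bool)
    return SVAttributes(df)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = dm.to_dataframe()
    df.index.name = dm.metric or "sample_id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path, metric: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    label = metric or (df.index.name if df.index.name not in (None, "sample_id") else "")
    return DistanceMatrix(df.to_numpy(), list(df.columns), label)


def write_biom(table: CountTable, path, generated_by: str = "rhizonet") -> None:
    """Write a BIOM 1.0 (sparse JSON) OTU table."""
    values = table.values
    rows, cols = np.nonzero(values)
    data = [[int(r), int(c), int(values[r, c])] for r, c in zip(rows, cols)]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": generated_by,
        "date": datetime.now(timezone.utc).isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(table.feature_ids), len(table.sample_ids)],
        "rows": [{"id": fid, "metadata": None} for fid in table.feature_ids],
        "columns": [{"id": sid, "metadata": None} for sid in table.sample_ids],
        "data": data,
    }
    Path(path).write_text(json.dumps(doc))


def read_biom(path, axis_rank: str = "SV") -> CountTable:
    doc = json.loads(Path(path).read_text())
    n_rows, n_cols = doc["shape"]
    values = np.zeros((n_rows, n_cols), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            values[r, c] = v
    else:
        values[:] = np.asarray(doc["data"], dtype=np.int64)
    df = pd.DataFrame(
        values,
        index=[row["id"] for row in doc["rows"]],
        columns=[col["id"] for col in doc["columns"]],
    )
    return CountTable(df, axis_rank)
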