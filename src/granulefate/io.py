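"""Reading and writing the pipeline's delimited tables.

All tables are comma-separated UTF-8 with a header row. Count matrices are
written as ZOTU-rows x sample-columns with a sidecar sample-metadata table.
Floats are serialized with a fixed general format so identical data always
produces identical bytes (the pipeline manifest hashes file contents).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .active_community import CountMatrix
from .errors import DataError

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_counts(matrix: CountMatrix, counts_path, meta_path=None) -> Path:
    counts_path = Path(counts_path)
    counts_path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.counts.copy()
    out.index.name = "zotu_id"
    out.to_csv(counts_path)
    if meta_path is not None and len(matrix.sample_meta):
        meta = matrix.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path)
    return counts_path


def read_counts(counts_path, library_type: str, meta_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, index_col=0)
    if counts.index.has_duplicates:
        raise DataError(f"duplicate ZOTU ids in {counts_path}")
    meta = pd.DataFrame()
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0)
    return CountMatrix(counts, library_type, meta)


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path)
    if "zotu_id" not in tax.columns or "family" not in tax.columns:
        raise DataError("taxonomy table needs zotu_id and family columns")
    return tax
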