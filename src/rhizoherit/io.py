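"""Plain-text readers and writers for the pipeline's tabular artifacts.

All tables are TSV: count matrices with samples in rows and ASV ids in the
header, metadata keyed by sample id, square distance matrices with an id
header, and PERMANOVA / heritability result tables. Sidecar information
(per-ASV shifts and smoothing parameters, simulation truth, run summaries)
is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import DistanceMatrix
from .preprocess import CountMatrix

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_metadata_tsv", "write_metadata_tsv",
    "read_distance_tsv", "write_distance_tsv",
    "write_json", "read_json",
]


def read_counts_tsv(path: str | Path, state: str = "raw", depth: int | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if state != "sqrt":
        df = df.astype(np.int64)
    return CountMatrix(df, state=state, depth=depth)


def write_counts_tsv(counts: CountMatrix | pd.DataFrame, path: str | Path) -> None:
    df = getattr(counts, "data", counts)
    df.to_csv(path, sep="\t", index_label=df.index.name or "sample_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label=meta.index.name or "sample_id")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(float))


def write_distance_tsv(dist: DistanceMatrix, path: str | Path) -> None:
    dist.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
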