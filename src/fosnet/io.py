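"""Delimited-text readers and writers for tables and matrices."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .connectivity import BinaryAdjacency, METADATA_COLUMNS
from .errors import SchemaError
from .quantify import SECTION_COLUMNS

FLOAT_FORMAT = "%.10g"  # stable text form -> byte-identical reruns


def read_region_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing metadata columns {missing}")
    regions = [c for c in table.columns if c not in METADATA_COLUMNS]
    if len(regions) < 2:
        raise SchemaError(f"{path}: needs at least two region density columns")
    return table


def read_section_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in SECTION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return table


def write_table(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_matrix(frame: pd.DataFrame, path) -> Path:
    """Square labelled matrix with an explicit 'region' index header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=True, index_label="region", float_format=FLOAT_FORMAT)
    return path


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="region")


def write_adjacency(adjacency: BinaryAdjacency, path) -> Path:
    return write_matrix(adjacency.to_frame(), path)


def read_adjacency(path) -> BinaryAdjacency:
    return BinaryAdjacency.from_frame(read_matrix(path))
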