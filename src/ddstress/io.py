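"""Strict readers/writers for the pipeline's interchange formats.

TSV for matrices and tables, CSV for flow events, GMT for gene sets, JSON
for summaries.  Readers validate schemas up front so that malformed inputs
fail before any compute.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dge import DesignError, validate_design


class ValidationError(ValueError):
    pass


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix (TSV, first column = gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicated gene IDs")
    if df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicated sample IDs")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError(f"{path}: counts must be integers")
        df = df.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative counts")
    df.index.name = "gene"
    return df


def read_metadata(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    try:
        validate_design(meta)
    except DesignError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample IDs")
    if counts is not None and set(meta["sample_id"]) != set(counts.columns):
        raise ValidationError(f"{path}: samples do not match the count matrix")
    return meta


def read_flow_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"construct", "timepoint_min", "channel", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: flow events missing columns {sorted(missing)}")
    if (df["intensity"] < 0).any():
        raise ValidationError(f"{path}: negative intensities")
    return df


def read_cell_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"dna", "edu"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: cell events missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=index)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
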