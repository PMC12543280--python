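"""CSV/TSV and TIFF interchange for trace tables, labels, and image stacks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "frame_columns",
    "split_trace_table",
    "read_traces",
    "write_traces",
    "read_labels",
    "write_labels",
    "load_class_manifest",
    "write_stack",
    "read_stack",
]

META_COLUMNS = ("spot_id", "channel", "bio_rep", "tech_rep")


def frame_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("frame_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def split_trace_table(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a trace table into metadata and an (n, L) value matrix."""
    cols = frame_columns(df)
    meta = df[[c for c in META_COLUMNS if c in df.columns]].copy()
    return meta, df[cols].to_numpy(dtype=np.float32)


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read a trace table CSV/TSV (spot_id, channel, bio_rep, tech_rep, frame_*)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if not frame_columns(df):
        raise ValueError(f"{path}: no frame_* columns found")
    return df


def write_traces(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    """Write a per-trace label manifest (spot_id, channel, label, ...)."""
    labels.to_csv(path, sep=_sep_for(path), index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    return df


def load_class_manifest(source) -> dict[str, int]:
    """Load a {class: count} manifest from a CSV path or mapping.

    The CSV needs ``class`` and ``count`` columns.  Counts must be
    non-negative integers.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep=_sep_for(source))
        if not {"class", "count"} <= set(df.columns):
            raise ValueError("manifest needs 'class' and 'count' columns")
        items = zip(df["class"], df["count"])
    else:
        items = source.items()
    out = {}
    for cls, n in items:
        n = int(n)
        if n < 0:
            raise ValueError("counts must be >= 0")
        out[str(cls)] = n
    return out


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write an image stack (frames, H, W) as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
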