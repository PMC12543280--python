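"""End-to-end classification of a two-channel trace table into pair records.

Implements the analysis sequence applied to each colocalized spot: Z-score
normalize the far-red and green traces, classify each channel (with the
trained CNNs, or with the deterministic step-counting rubric as a reference
path), then keep only pairs whose green trace shows exactly one
photobleaching event and whose far-red trace is not rejected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnn import TrainedClassifier, classify
from .io import split_trace_table
from .stepcount import annotate_trace
from .traces import zscore_values

__all__ = ["classify_pairs_cnn", "classify_pairs_oracle", "label_table"]


def _zscore_matrix(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return ((values - mean) / sd).astype(np.float32)


def _merge_pairs(meta: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    df = meta.copy()
    df["label"] = labels
    wide = df.pivot_table(
        index=["spot_id", "bio_rep", "tech_rep"],
        columns="channel",
        values="label",
        aggfunc="first",
    ).reset_index()
    wide = wide.rename(columns={"green": "green_class", "farred": "farred_class"})
    # spots missing a channel (e.g. unlabeled bait) cannot be analyzed
    for col in ("green_class", "farred_class"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide = wide.dropna(subset=["green_class", "farred_class"])
    return wide[["spot_id", "green_class", "farred_class", "bio_rep", "tech_rep"]].reset_index(
        drop=True
    )


def classify_pairs_cnn(
    traces: pd.DataFrame,
    green_model: TrainedClassifier,
    farred_model: TrainedClassifier,
) -> pd.DataFrame:
    """Classify every trace with the channel's CNN; return the pair table.

    ``traces`` is a tidy trace table (spot_id, channel, bio_rep, tech_rep,
    frame_*).  Raw traces are Z-scored before inference.  Returns one row
    per spot with both channels present: spot_id, green_class,
    farred_class, bio_rep, tech_rep.
    """
    meta, values = split_trace_table(traces)
    Z = _zscore_matrix(values)
    labels = np.empty(len(meta), dtype=object)
    for channel, model in (("green", green_model), ("farred", farred_model)):
        idx = np.flatnonzero(meta["channel"].to_numpy() == channel)
        if len(idx):
            labels[idx], _ = classify(model, Z[idx])
    return _merge_pairs(meta, labels)


def label_table(traces: pd.DataFrame) -> pd.DataFrame:
    """Label every trace with the deterministic step rubric (raw counts).

    Returns the per-trace manifest: spot_id, channel, bio_rep, tech_rep,
    label, n_steps, stopped_early, reject_reason.
    """
    meta, values = split_trace_table(traces)
    rows = []
    channels = meta["channel"].to_numpy()
    for i in range(len(meta)):
        ann, cls = annotate_trace(values[i].astype(float), channels[i])
        rows.append(
            {
                **{k: meta.iloc[i][k] for k in meta.columns},
                "label": cls.label,
                "n_steps": ann.n_steps,
                "stopped_early": ann.stopped_early,
                "reject_reason": ann.reject_reason or "",
            }
        )
    return pd.DataFrame(rows)


def classify_pairs_oracle(traces: pd.DataFrame) -> pd.DataFrame:
    """Pair table from the step-counting rubric instead of the CNNs."""
    manifest = label_table(traces)
    meta = manifest[["spot_id", "channel", "bio_rep", "tech_rep"]]
    return _merge_pairs(meta, manifest["label"].to_numpy())
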