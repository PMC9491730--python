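"""Plain-text readers and writers.

Recording CSV dialect: an optional block of ``# key=value`` comment lines
(sampling_rate_hz, trial_id, label), then a header row ``time_s,<ch>,...``
and one row per sample.  Labels live in a sidecar TSV ``trial_id\tlabel``.
Feature tables are TSV with ``sample_id``, ``label``, then one column per
named feature.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .preprocess import Recording


def write_recording_csv(recording: Recording, path: str | os.PathLike) -> None:
    fs = recording.sampling_rate_hz
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={fs!r}\n")
        if recording.trial_id is not None:
            fh.write(f"# trial_id={recording.trial_id}\n")
        if recording.label is not None:
            fh.write(f"# label={recording.label}\n")
        fh.write("time_s," + ",".join(recording.channel_names) + "\n")
        t = np.arange(recording.n_samples) / fs + recording.window_start_s
        for i in range(recording.n_samples):
            row = ",".join(repr(float(v)) for v in recording.samples[:, i])
            fh.write(f"{float(t[i])!r},{row}\n")


def read_recording_csv(path: str | os.PathLike) -> Recording:
    meta: dict[str, str] = {}
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=n_comments, float_precision="round_trip")
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s', "
                         f"got {df.columns[0]!r}")
    if "sampling_rate_hz" in meta:
        fs = float(meta["sampling_rate_hz"])
    else:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    return Recording(
        channel_names=list(df.columns[1:]),
        samples=df.iloc[:, 1:].to_numpy().T,
        sampling_rate_hz=fs,
        trial_id=meta.get("trial_id"),
        label=meta.get("label"),
        window_start_s=float(df["time_s"].iloc[0]),
    )


def write_labels_table(entries, path: str | os.PathLike) -> None:
    """Write (trial_id, label) pairs as a two-column TSV."""
    pd.DataFrame(entries, columns=["trial_id", "label"]).to_csv(
        path, sep="\t", index=False)


def read_labels_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_feature_table(features: pd.DataFrame, labels,
                        path: str | os.PathLike) -> None:
    """Write a sample x feature matrix with labels as TSV."""
    out = features.copy()
    out.insert(0, "label", list(labels))
    out.insert(0, "sample_id", features.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = df.pop("label")
    df = df.set_index("sample_id")
    return df, labels
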