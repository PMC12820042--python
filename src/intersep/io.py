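"""Epoch-container I/O.

The native container is an HDF5 file holding the float epoch array plus a
JSON metadata attribute and the trial table (stored as JSON records), so a
write/read round trip is lossless at the stored dtype.  EDF and
BrainVision recordings can be ingested through MNE's readers; their
annotations become the trial table where present.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import EpochSet

REQUIRED_TRIAL_COLUMNS = ("participant", "movie_id", "role", "repetition")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {missing}")


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write the native container: HDF5 with the raw array, JSON metadata
    and the trial table."""
    _check_table(epochs.trial_table)
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["meta"] = json.dumps(
            {
                "sample_rate_hz": epochs.sample_rate_hz,
                "t_start_s": epochs.t_start_s,
                "channel_names": list(epochs.channel_names),
            }
        )
        f.attrs["trial_table"] = epochs.trial_table.to_json(orient="table")
    return path


def read_epochs(path: str | Path, fmt: str = "container") -> EpochSet:
    """Read epochs from the native container, or ingest an EDF /
    BrainVision recording via MNE (``fmt`` in {"container", "edf",
    "brainvision"})."""
    path = Path(path)
    if fmt == "container":
        return _read_container(path)
    if fmt in ("edf", "brainvision"):
        return _read_mne(path, fmt)
    raise ValueError(f"unknown format {fmt!r}")


def _read_container(path: Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        try:
            meta = json.loads(f.attrs["meta"])
            table = pd.read_json(_io.StringIO(f.attrs["trial_table"]), orient="table")
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed container metadata in {path}: {exc}") from exc
    for key in ("sample_rate_hz", "t_start_s", "channel_names"):
        if key not in meta:
            raise ValueError(f"container metadata missing field 'meta.{key}'")
    _check_table(table)
    return EpochSet(
        data=data,
        sample_rate_hz=meta["sample_rate_hz"],
        t_start_s=meta["t_start_s"],
        channel_names=meta["channel_names"],
        trial_table=table.reset_index(drop=True),
    )


def _read_mne(path: Path, fmt: str) -> EpochSet:
    import mne

    if fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data = raw.get_data()[None, ...]  # single continuous "trial"
    ann = raw.annotations
    table = pd.DataFrame(
        {
            "participant": 0,
            "movie_id": list(ann.description) if len(ann) else ["continuous"],
            "role": "NA",
            "repetition": 0,
            "onset_s": list(ann.onset) if len(ann) else [0.0],
        }
    )
    return EpochSet(
        data=data,
        sample_rate_hz=float(raw.info["sfreq"]),
        t_start_s=0.0,
        channel_names=list(raw.ch_names),
        trial_table=table,
    )
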