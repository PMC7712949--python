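"""Reading recordings from disk: delimited matrices and EDF.

The native plain-text format is a tab-separated channels x samples
matrix with the channel name leading each row (as written by
``synth.write_cohort``).  EDF files are read through MNE when it is
available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecord

__all__ = ["read_delimited_record", "read_edf_record", "read_recording", "write_feature_table", "read_feature_table"]


def read_delimited_record(
    path: str | Path,
    fs: float,
    subject_id: str | None = None,
    label: str | None = None,
    delimiter: str = "\t",
) -> EEGRecord:
    """Read a channels x samples delimited matrix.

    Rows may begin with a channel name; purely numeric matrices get
    channel names ``ch1..chC``.
    """
    path = Path(path)
    names: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split(delimiter)
            if not parts or parts == [""]:
                continue
            try:
                float(parts[0])
                names.append(f"ch{i + 1}")
                rows.append(np.array(parts, dtype=float))
            except ValueError:
                names.append(parts[0])
                rows.append(np.array(parts[1:], dtype=float))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    return EEGRecord(
        data=np.vstack(rows),
        fs=fs,
        channel_names=names,
        subject_id=subject_id or path.stem,
        label=label,
    )


def read_edf_record(path: str | Path, subject_id: str | None = None, label: str | None = None) -> EEGRecord:
    """Read an EDF recording via MNE (amplitudes converted to microvolts)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF files requires the 'mne' package") from exc
    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecord(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=subject_id or path.stem,
        label=label,
    )


def read_recording(path: str | Path, fs: float | None = None, **kwargs) -> EEGRecord:
    """Dispatch on extension: ``.edf`` via MNE, anything else as a
    delimited matrix (which requires ``fs``)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf_record(path, **kwargs)
    if fs is None:
        raise ValueError("fs is required for delimited recordings")
    return read_delimited_record(path, fs=fs, **kwargs)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
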