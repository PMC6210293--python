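"""Epoch-level count file I/O, re-integration, vector magnitude, and the
direct-observation inclusion filter.

File layout mirrors ActiLife-style epoch exports: one file per
child x wrist, a two-line metadata header (device id; start timestamp and
epoch length), then a column-header row ``epoch_index,axis1,axis2,axis3``
and one row per epoch.  The activity schedule (which epochs belong to which
activity) and the observation log travel in separate tab-separated files.
Comma and tab delimiters are both accepted; the delimiter is sniffed from
the header.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "read_epochs",
    "write_epochs",
    "read_epoch_dir",
    "write_epoch_dir",
    "read_observation_log",
    "write_observation_log",
    "reintegrate",
    "vector_magnitude",
    "add_vector_magnitude",
    "apply_observation_filter",
]

EPOCH_SECONDS = 5
_COLUMNS = ["epoch_index", "axis1", "axis2", "axis3"]
_TABLE_COLUMNS = [
    "child_id", "wrist", "activity", "posture",
    "epoch_index", "axis1", "axis2", "axis3",
]


class ParseError(ValueError):
    """Malformed epoch file; message carries the offending line number."""


def vector_magnitude(axis1, axis2, axis3):
    """Euclidean norm of the three axis counts; kept real-valued."""
    a1, a2, a3 = (np.asarray(a, dtype=float) for a in (axis1, axis2, axis3))
    if np.any(a1 < 0) or np.any(a2 < 0) or np.any(a3 < 0):
        raise ValueError("axis counts must be non-negative")
    return np.sqrt(a1 * a1 + a2 * a2 + a3 * a3)


def add_vector_magnitude(epochs: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``vm`` column derived from the three axes."""
    out = epochs.copy()
    out["vm"] = vector_magnitude(out["axis1"], out["axis2"], out["axis3"])
    return out


def reintegrate(series, factor: int) -> np.ndarray:
    """Sum consecutive runs of ``factor`` epochs into longer epochs.

    A trailing remainder shorter than ``factor`` is dropped with a warning;
    total counts are otherwise conserved.  Used to ingest e.g. 1-s exports
    at the 5-s epoch length the analysis assumes.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = np.asarray(series)
    n_keep = (len(arr) // factor) * factor
    if n_keep < len(arr):
        warnings.warn(
            f"dropping {len(arr) - n_keep} trailing epoch(s) not filling a "
            f"full window of {factor}",
            stacklevel=2,
        )
    if n_keep == 0:
        return arr[:0].copy()
    return arr[:n_keep].reshape(-1, factor).sum(axis=1)


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def write_epochs(
    series: pd.DataFrame,
    path: str | Path,
    *,
    device_id: str = "SYN-0000",
    start: str = "2018-07-02T09:00:00",
    epoch_seconds: int = EPOCH_SECONDS,
    delimiter: str = ",",
) -> None:
    """Write one child x wrist epoch series (epoch_index + three axes)."""
    path = Path(path)
    df = series[_COLUMNS].reset_index(drop=True)
    d = delimiter
    with path.open("w", newline="") as fh:
        fh.write(f"device{d}{device_id}\n")
        fh.write(f"start{d}{start}{d}epoch_seconds{d}{epoch_seconds}\n")
        fh.write(d.join(_COLUMNS) + "\n")
        np.savetxt(fh, df.to_numpy(dtype=np.int64), fmt="%d", delimiter=d)


def read_epochs(path: str | Path) -> pd.DataFrame:
    """Read one epoch series file; returns epoch_index + axis columns.

    Device id, start timestamp and epoch length are attached via
    ``DataFrame.attrs``.  Malformed headers, negative counts and
    non-contiguous epoch indices raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: line 1: missing metadata header")
    d = _sniff_delimiter(lines[0])
    meta1 = lines[0].split(d)
    if len(meta1) != 2 or meta1[0] != "device":
        raise ParseError(f"{path}: line 1: expected 'device{d}<id>'")
    meta2 = lines[1].split(d)
    if len(meta2) != 4 or meta2[0] != "start" or meta2[2] != "epoch_seconds":
        raise ParseError(
            f"{path}: line 2: expected 'start{d}<ts>{d}epoch_seconds{d}<n>'"
        )
    try:
        epoch_seconds = int(meta2[3])
    except ValueError:
        raise ParseError(f"{path}: line 2: epoch_seconds not an integer") from None
    header = lines[2].split(_sniff_delimiter(lines[2]))
    if header != _COLUMNS:
        raise ParseError(f"{path}: line 3: expected columns {','.join(_COLUMNS)}")

    rows = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split(_sniff_delimiter(line))
        if len(parts) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 fields")
        try:
            vals = [int(p) for p in parts]
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-integer count"
            ) from None
        if any(v < 0 for v in vals[1:]):
            raise ParseError(f"{path}: line {lineno}: negative count")
        rows.append(vals)

    df = pd.DataFrame(rows, columns=_COLUMNS, dtype=np.int64)
    if len(df):
        expected = np.arange(len(df))
        if not np.array_equal(df["epoch_index"].to_numpy(), expected):
            bad = int(np.flatnonzero(df["epoch_index"].to_numpy() != expected)[0])
            raise ParseError(
                f"{path}: line {bad + 4}: epoch_index not contiguous from 0"
            )
    df.attrs.update(
        device_id=meta1[1], start=meta2[1], epoch_seconds=epoch_seconds
    )
    return df


def _series_filename(child_id: str, wrist: str) -> str:
    return f"{child_id}_{wrist}.csv"


def write_epoch_dir(epochs: pd.DataFrame, directory: str | Path) -> None:
    """Write a labeled epoch table as one file per child x wrist plus a
    schedule TSV recording which global epochs belong to which activity."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schedule_rows = []
    for (child, wrist), grp in epochs.groupby(["child_id", "wrist"], sort=True):
        pieces = []
        offset = 0
        # preserve activity order of first appearance within the series
        for activity in grp["activity"].drop_duplicates():
            block = grp[grp["activity"] == activity].sort_values("epoch_index")
            schedule_rows.append(
                {
                    "child_id": child,
                    "wrist": wrist,
                    "activity": activity,
                    "posture": block["posture"].iloc[0],
                    "start_epoch": offset,
                    "n_epochs": len(block),
                }
            )
            pieces.append(block[["axis1", "axis2", "axis3"]])
            offset += len(block)
        series = pd.concat(pieces, ignore_index=True)
        series.insert(0, "epoch_index", np.arange(len(series)))
        write_epochs(
            series,
            directory / _series_filename(child, wrist),
            device_id=f"SYN-{child}-{wrist}",
        )
    pd.DataFrame(schedule_rows).to_csv(
        directory / "schedule.tsv", sep="\t", index=False
    )


def read_epoch_dir(directory: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_epoch_dir`; reconstructs the labeled table."""
    directory = Path(directory)
    schedule = pd.read_csv(directory / "schedule.tsv", sep="\t")
    frames = []
    for (child, wrist), sched in schedule.groupby(["child_id", "wrist"], sort=True):
        series = read_epochs(directory / _series_filename(child, wrist))
        for row in sched.itertuples(index=False):
            block = series.iloc[row.start_epoch : row.start_epoch + row.n_epochs]
            frames.append(
                pd.DataFrame(
                    {
                        "child_id": child,
                        "wrist": wrist,
                        "activity": row.activity,
                        "posture": row.posture,
                        "epoch_index": np.arange(row.n_epochs),
                        "axis1": block["axis1"].to_numpy(),
                        "axis2": block["axis2"].to_numpy(),
                        "axis3": block["axis3"].to_numpy(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[_TABLE_COLUMNS]


def write_observation_log(log: pd.DataFrame, path: str | Path) -> None:
    log[["child_id", "activity", "seated_verified", "completed"]].to_csv(
        path, sep="\t", index=False
    )


def read_observation_log(path: str | Path) -> pd.DataFrame:
    log = pd.read_csv(path, sep="\t")
    for col in ("seated_verified", "completed"):
        log[col] = log[col].astype(bool)
    return log


def apply_observation_filter(
    epochs: pd.DataFrame, log: pd.DataFrame
) -> pd.DataFrame:
    """Apply the direct-observation inclusion rules.

    A child x activity is dropped when its log entry has completed=False,
    or — for seated activities only — seated_verified=False (the child
    stood up and stepped during the session).  Other activities of the same
    child are retained, and walking is retained regardless of the seated
    flag.  Every epoch series must have a log entry.
    """
    if "posture" not in epochs.columns:
        raise ValueError("epoch table must carry a 'posture' column")
    keys = epochs[["child_id", "activity"]].drop_duplicates()
    log_keys = log.set_index(["child_id", "activity"])
    missing = [
        (c, a)
        for c, a in keys.itertuples(index=False)
        if (c, a) not in log_keys.index
    ]
    if missing:
        raise ValueError(f"epoch series without observation log entry: {missing[:5]}")

    merged = epochs.merge(log, on=["child_id", "activity"], how="left")
    seated = merged["posture"] == "seated"
    drop = ~merged["completed"] | (seated & ~merged["seated_verified"])
    return epochs.loc[~drop.to_numpy()].reset_index(drop=True)
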