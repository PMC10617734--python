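"""Reading and writing Trikinetics-style activity-monitor files.

The DAM/LAM family of monitors emits one tab-delimited row per reading:
a running index, date, time and status columns, a block of firmware
metadata, then one integer count column per channel (32 on a standard
board).  Column offsets vary by firmware, so the dialect is configurable.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import ActivityRecord


class MalformedFileError(ValueError):
    """Structural problem in a monitor file (bad rows, gaps, duplicates)."""


class DataError(ValueError):
    """A count value is negative or non-integral."""


class LookupError_(KeyError):
    """A mapped channel or animal is missing."""


@dataclass
class MonitorDialect:
    """Column layout of a tab-delimited monitor file.

    Defaults follow the common DAMSystem3 layout: index, date, time,
    status, six firmware fields, then 32 count columns.
    """

    index_col: int = 0
    date_col: int = 1
    time_col: int = 2
    status_col: int = 3
    counts_start: int = 10
    n_channels: int = 32
    status_ok: str = "1"


@dataclass
class CohortMetadata:
    """Cohort annotation: animal assignments and per-collection tide tables.

    ``animals`` maps animal_id -> dict(channel, knockdown, collection,
    lighting, start_ct); ``tides`` maps collection -> strictly increasing
    high-tide times in hours on the recording CT axis.
    """

    animals: Dict[str, dict] = field(default_factory=dict)
    tides: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for coll, times in list(self.tides.items()):
            t = np.asarray(times, dtype=float)
            if t.size >= 2:
                dt = np.diff(t)
                if np.any(dt <= 0):
                    raise ValueError(f"tide times for {coll!r} must be strictly increasing")
                if np.any((dt < 10) | (dt > 15)):
                    raise ValueError(
                        f"tide intervals for {coll!r} fall outside 10-15 h: {dt}"
                    )
            self.tides[coll] = t

    @classmethod
    def from_csv(cls, animals_csv, tides_csv=None) -> "CohortMetadata":
        """Load from the interchange CSVs.

        ``animals_csv`` columns: animal_id, channel, knockdown, collection,
        lighting, start_ct.  ``tides_csv`` columns: collection, tide_ct_h.
        """
        df = pd.read_csv(animals_csv)
        required = {"animal_id", "channel", "knockdown", "collection", "lighting", "start_ct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
        animals = {
            str(row.animal_id): dict(
                channel=int(row.channel),
                knockdown=str(row.knockdown),
                collection=str(row.collection),
                lighting=str(row.lighting),
                start_ct=float(row.start_ct),
            )
            for row in df.itertuples()
        }
        tides: Dict[str, np.ndarray] = {}
        if tides_csv is not None:
            tdf = pd.read_csv(tides_csv)
            for coll, grp in tdf.groupby("collection"):
                tides[str(coll)] = np.sort(grp["tide_ct_h"].to_numpy(dtype=float))
        return cls(animals=animals, tides=tides)

    def channel_map(self, collection: Optional[str] = None) -> Dict[int, str]:
        """channel -> animal_id, optionally restricted to one collection."""
        out = {}
        for aid, meta in self.animals.items():
            if collection is None or meta["collection"] == collection:
                out[meta["channel"]] = aid
        return out


def read_monitor_file(
    path,
    channel_map: Mapping[int, str],
    metadata: Optional[CohortMetadata] = None,
    dialect: MonitorDialect = MonitorDialect(),
    bin_width_h: float = 0.5,
    allow_status: bool = False,
) -> List[ActivityRecord]:
    """Parse a tab-delimited monitor file into per-animal records.

    ``channel_map`` maps 1-based channel numbers to animal ids.  Rows must
    be in timestamp order and contiguous at ``bin_width_h``; duplicated or
    skipped timestamps raise :class:`MalformedFileError`.  When
    ``metadata`` is given, every mapped animal must appear in it and its
    annotations (knockdown, collection, lighting, start_ct) are attached.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MalformedFileError(f"{path}: empty monitor file")

    times = []
    rows = []
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) < dialect.counts_start + 1:
            raise MalformedFileError(f"{path}: row with too few columns: {ln[:60]!r}")
        stamp = (parts[dialect.date_col].strip(), parts[dialect.time_col].strip())
        status = parts[dialect.status_col].strip()
        if status != dialect.status_ok and not allow_status:
            raise MalformedFileError(
                f"{path}: non-OK status {status!r} at {stamp}; pass allow_status=True to accept"
            )
        times.append(stamp)
        rows.append(parts[dialect.counts_start:])

    # contiguity / duplication checks on the timestamp column
    parsed = pd.to_datetime(
        [f"{d} {t}" for d, t in times], format="%d %b %y %H:%M:%S", errors="coerce"
    )
    if parsed.isna().any():
        raise MalformedFileError(f"{path}: unparseable timestamp(s)")
    deltas = np.diff(parsed.view("int64")) / 3.6e12  # hours
    if len(deltas) and np.any(deltas <= 0):
        raise MalformedFileError(f"{path}: duplicate or out-of-order timestamps")
    if len(deltas) and np.any(np.abs(deltas - bin_width_h) > 1e-6):
        raise MalformedFileError(f"{path}: non-contiguous timestamps (expected {bin_width_h} h steps)")

    n_channels = max(len(r) for r in rows)
    if min(len(r) for r in rows) != n_channels:
        raise MalformedFileError(f"{path}: ragged count columns")

    counts = np.empty((len(rows), n_channels), dtype=np.int64)
    for i, r in enumerate(rows):
        for j, v in enumerate(r):
            v = v.strip()
            try:
                fv = float(v)
            except ValueError as exc:
                raise DataError(f"{path}: non-numeric count {v!r}") from exc
            if fv < 0 or fv != int(fv):
                raise DataError(f"{path}: negative or non-integer count {v!r}")
            counts[i, j] = int(fv)

    records = []
    for channel, animal_id in sorted(channel_map.items()):
        if not (1 <= channel <= n_channels):
            raise LookupError_(f"channel {channel} not present in {path} ({n_channels} channels)")
        meta = dict(knockdown="control", collection="c0", lighting="DD", start_ct=0.0)
        if metadata is not None:
            if animal_id not in metadata.animals:
                raise LookupError_(f"animal {animal_id!r} missing from cohort metadata")
            meta.update(metadata.animals[animal_id])
        records.append(
            ActivityRecord(
                animal_id=animal_id,
                counts=counts[:, channel - 1],
                start_ct=meta["start_ct"],
                bin_width_h=bin_width_h,
                knockdown=meta["knockdown"],
                collection_id=meta["collection"],
                lighting=meta["lighting"],
            )
        )
    return records


def write_record_csv(record: ActivityRecord, path) -> None:
    """Write the canonical per-animal CSV (bin_start_ct, count).

    Metadata travels in ``#`` header comments so a record round-trips
    bit-exactly through :func:`read_record_csv`.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# animal_id={record.animal_id}\n")
        fh.write(f"# knockdown={record.knockdown}\n")
        fh.write(f"# collection={record.collection_id}\n")
        fh.write(f"# lighting={record.lighting}\n")
        fh.write(f"# bin_width_h={record.bin_width_h!r}\n")
        fh.write("bin_start_ct,count\n")
        for t, c in zip(record.ct, record.counts):
            fh.write(f"{float(t)!r},{c}\n")


def read_record_csv(path) -> ActivityRecord:
    path = Path(path)
    meta = {}
    body = []
    for ln in path.read_text().splitlines():
        if ln.startswith("#"):
            k, _, v = ln[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
        elif ln.strip():
            body.append(ln)
    df = pd.read_csv(io.StringIO("\n".join(body)))
    ct = df["bin_start_ct"].to_numpy(dtype=float)
    return ActivityRecord(
        animal_id=meta["animal_id"],
        counts=df["count"].to_numpy(),
        start_ct=float(ct[0]),
        bin_width_h=float(meta.get("bin_width_h", 0.5)),
        knockdown=meta.get("knockdown", "control"),
        collection_id=meta.get("collection", "c0"),
        lighting=meta.get("lighting", "DD"),
    )
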