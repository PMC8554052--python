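"""Reading and writing tube-recording data.

Position tables are per-second, one-dimensional coordinates of individual
flies confined to glass tubes (0 px at the cotton end, increasing toward the
food end).  This module parses those tables into :class:`PositionTrace`
objects, applies the stuck-fly sanitation rule (a fly-day whose first sample
of ZT 0 reads exactly 0 was parked at the cotton plug by the tracker and is
excluded), extracts traces from raw grayscale frame stacks with a minimal
centroid tracker, and writes/reads the three standard output tables:

* ``Activity.csv``   — FAEn (visit counts) per fly-day per hour,
* ``Feeding.csv``    — FAErt (residence seconds) per fly-day per hour,
* ``FeedingPDF.csv`` — one row per individual food-approaching event.

Every writer has a matching reader; write∘read is the identity on valid data.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("flyfae")

#: seconds per recording day (1 sample per second)
DAY_S: int = 86_400
#: maximum number of tubes on one recording plate
PLATE_CAPACITY: int = 18
#: default body length in pixels, by sex, at the standard optics
BODY_LENGTH_PX: Mapping[str, float] = {"male": 11.0, "female": 12.0}
#: hour column labels used in all wide tables
HOUR_COLUMNS: tuple[str, ...] = tuple(f"ZT{h:02d}" for h in range(24))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionTrace:
    """One fly's per-second 1-D coordinate series, time origin at ZT 0.

    Missing samples (tracking dropouts, unparseable cells) are carried in
    ``missing_mask`` and as NaN in ``positions``; they are never interpolated
    at ingest — downstream event segmentation decides their semantics.
    """

    fly_id: str
    positions: np.ndarray            # float64, NaN where missing
    start_zt: int = 0                # seconds offset of first sample from ZT 0
    sample_rate: int = 1             # samples per second; 1 for regular recording
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    excluded_days: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.missing_mask is None:
            object.__setattr__(self, "missing_mask", np.isnan(pos))
        else:
            mask = np.asarray(self.missing_mask, dtype=bool)
            object.__setattr__(self, "missing_mask", mask)
        if len(self.positions) != len(self.missing_mask):
            raise ValueError(
                f"fly {self.fly_id!r}: positions ({len(self.positions)}) and "
                f"missing_mask ({len(self.missing_mask)}) lengths differ"
            )
        if self.sample_rate != 1:
            raise ValueError(
                "regular-recording analysis requires sample_rate=1 "
                f"(got {self.sample_rate})"
            )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_days(self) -> int:
        """Number of recording days touched by this trace (ceil)."""
        total = self.start_zt + len(self.positions)
        return -(-total // DAY_S)

    def day_slice(self, day_index: int) -> slice:
        """Sample-index slice covering ``day_index`` (empty if out of range)."""
        lo = max(day_index * DAY_S - self.start_zt, 0)
        hi = min((day_index + 1) * DAY_S - self.start_zt, len(self.positions))
        return slice(lo, max(hi, lo))

    def day_positions(self, day_index: int) -> np.ndarray:
        return self.positions[self.day_slice(day_index)]

    def day_missing(self, day_index: int) -> np.ndarray:
        return self.missing_mask[self.day_slice(day_index)]


@dataclass(frozen=True)
class PlateRecording:
    """All traces from one recording plate (up to 18 tubes)."""

    traces: tuple[PositionTrace, ...]
    light_schedule: str = "LD"       # "LD" or "DD" (subjective ZT retained in DD)
    tube_length_px: float = 130.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "traces", tuple(self.traces))
        if len(self.traces) > PLATE_CAPACITY:
            raise ValueError(
                f"plate capacity exceeded: {len(self.traces)} traces "
                f"(maximum {PLATE_CAPACITY})"
            )
        if not self.traces:
            raise ValueError("a PlateRecording needs at least one trace")
        lengths = {len(t) for t in self.traces}
        starts = {t.start_zt for t in self.traces}
        if len(lengths) > 1 or len(starts) > 1:
            raise ValueError("all traces on a plate must share start_zt and duration")

    def __len__(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class TableDialect:
    """Layout of a position table.

    The default matches the common export convention: headerless CSV, one fly
    per column, one row per second, first row at ZT 0.
    """

    orientation: str = "columns"     # "columns": one fly per column; "rows": per row
    delimiter: str = ","
    header: bool = False             # header row (or column, per orientation) of fly ids
    time_column: int | None = None   # index of a time column to drop ("columns" only)

    def __post_init__(self) -> None:
        if self.orientation not in ("columns", "rows"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


# ---------------------------------------------------------------------------
# position-table reading
# ---------------------------------------------------------------------------

def read_position_table(
    path: str | Path,
    dialect: TableDialect = TableDialect(),
    *,
    start_zt: int = 0,
    light_schedule: str = "LD",
    tube_length_px: float = 130.0,
) -> PlateRecording:
    """Parse a per-second position table into a :class:`PlateRecording`.

    Non-numeric or absent cells become missing samples.  Ragged tables (flies
    with unequal sample counts) and tables with more than 18 flies are hard
    errors; the offending fly is named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter=dialect.delimiter) if row]
    if not rows:
        raise ValueError(f"{path}: empty position table")

    if dialect.orientation == "rows":
        ids = [r[0] for r in rows] if dialect.header else [f"fly{i+1:02d}" for i in range(len(rows))]
        data_rows = [r[1:] for r in rows] if dialect.header else rows
        lengths = {len(r) for r in data_rows}
        if len(lengths) > 1:
            expected = len(data_rows[0])
            for fid, r in zip(ids, data_rows):
                if len(r) != expected:
                    raise ValueError(
                        f"{path}: fly {fid!r} has {len(r)} samples, expected {expected}"
                    )
        series = dict(zip(ids, data_rows))
    else:
        header_row: list[str] | None = rows[0] if dialect.header else None
        body = rows[1:] if dialect.header else rows
        if not body:
            raise ValueError(f"{path}: no data rows")
        widths = {len(r) for r in body}
        n_cols = max(widths)
        if len(widths) > 1:
            # ragged columns-layout table: name the first short/long row's column
            for i, r in enumerate(body):
                if len(r) != n_cols:
                    raise ValueError(
                        f"{path}: row {i} has {len(r)} cells, expected {n_cols} "
                        "(unequal trace lengths)"
                    )
        keep = [j for j in range(n_cols) if j != dialect.time_column]
        if header_row is not None:
            ids = [header_row[j] for j in keep]
        else:
            ids = [f"fly{k+1:02d}" for k in range(len(keep))]
        series = {fid: [row[j] for row in body] for fid, j in zip(ids, keep)}

    if not series:
        raise ValueError(f"{path}: zero flies in position table")
    if len(series) > PLATE_CAPACITY:
        raise ValueError(
            f"{path}: {len(series)} flies exceed plate capacity ({PLATE_CAPACITY})"
        )

    traces = []
    for fid, cells in series.items():
        vals = pd.to_numeric(pd.Series(cells, dtype=object), errors="coerce").to_numpy(float)
        traces.append(PositionTrace(fly_id=str(fid), positions=vals, start_zt=start_zt))
    return PlateRecording(
        traces=tuple(traces),
        light_schedule=light_schedule,
        tube_length_px=tube_length_px,
    )


def write_position_table(plate: PlateRecording, path: str | Path,
                         dialect: TableDialect = TableDialect()) -> None:
    """Write a plate back to a position table (inverse of the reader)."""
    if dialect.orientation != "columns":
        raise NotImplementedError("only the columns orientation is written")
    df = pd.DataFrame({t.fly_id: t.positions for t in plate.traces})
    df.to_csv(path, index=False, header=dialect.header, sep=dialect.delimiter)


def drop_zeroed_day_traces(plate: PlateRecording) -> PlateRecording:
    """Exclude fly-days whose first ZT-0 sample reads exactly 0.

    The upstream tracker parks a fly that is not moving at the start of a day
    at coordinate 0 (the cotton side); such fly-days carry no usable movement
    track.  Exclusion is per fly-day: other days of the same fly are retained.
    """
    new_traces = []
    n_removed = 0
    for trace in plate.traces:
        excluded = set(trace.excluded_days)
        first_day = trace.start_zt // DAY_S
        for day in range(first_day, trace.n_days):
            day_start_abs = day * DAY_S
            i = day_start_abs - trace.start_zt
            if i < 0 or i >= len(trace.positions):
                continue  # recording does not cover the first second of this day
            if not trace.missing_mask[i] and trace.positions[i] == 0.0:
                excluded.add(day)
                n_removed += 1
        new_traces.append(replace(trace, excluded_days=frozenset(excluded)))
    if n_removed:
        logger.warning("drop_zeroed_day_traces: excluded %d fly-day(s)", n_removed)
    return replace(plate, traces=tuple(new_traces))


# ---------------------------------------------------------------------------
# minimal centroid tracker for grayscale frame stacks
# ---------------------------------------------------------------------------

def read_frame_stack(source: str | Path | Sequence[str | Path]) -> np.ndarray:
    """Load a grayscale frame stack from disk into an (n, H, W) array.

    ``source`` is either one multi-frame image file (e.g. a TIFF stack) or a
    sequence of single-frame files in temporal order.  Colour images are
    averaged to grayscale; frames must share dimensions.
    """
    import imageio.v3 as iio

    if isinstance(source, (str, Path)):
        stack = np.asarray(iio.imread(source))
        if stack.ndim == 2:
            stack = stack[None]
    else:
        frames = [np.asarray(iio.imread(p)) for p in source]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"frames differ in shape: {sorted(shapes)}")
        stack = np.stack(frames)
    if stack.ndim == 4:  # colour -> grayscale
        stack = stack.mean(axis=-1)
    if stack.ndim != 3:
        raise ValueError(f"cannot interpret stack of shape {stack.shape}")
    return stack

def extract_positions_from_frames(
    frames: Sequence[np.ndarray] | np.ndarray,
    roi: tuple[int, int, int, int],
    axis: str = "x",
    *,
    fly_id: str = "fly01",
    threshold: float = 10.0,
    start_zt: int = 0,
) -> PositionTrace:
    """Track a single dark fly in a tube ROI by background subtraction.

    The background is the per-pixel temporal median of the stack, floored at
    the stack's global median so a fly that never moves still stands out as a
    dark deviation.  Each frame's foreground (background minus frame, clipped
    at 0) is thresholded; the position is the foreground-intensity-weighted
    centroid projected on the tube axis.  Frames with no above-threshold
    foreground yield missing samples.

    ``roi`` is ``(row_start, row_stop, col_start, col_stop)``; ``axis`` is
    ``"x"`` (along columns) or ``"y"`` (along rows).
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("frame stack must be a non-empty (n, H, W) array")
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= stack.shape[1] and 0 <= c0 < c1 <= stack.shape[2]):
        raise ValueError(f"roi {roi} outside frame bounds {stack.shape[1:]}")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")

    crop = stack[:, r0:r1, c0:c1]
    background = np.median(crop, axis=0)
    background = np.maximum(background, np.median(background))

    positions = np.full(len(crop), np.nan)
    coords = np.arange(c0, c1, dtype=float) if axis == "x" else np.arange(r0, r1, dtype=float)
    for i, frame in enumerate(crop):
        fg = np.clip(background - frame, 0.0, None)
        fg[fg <= threshold] = 0.0
        total = fg.sum()
        if total == 0.0:
            continue
        profile = fg.sum(axis=0) if axis == "x" else fg.sum(axis=1)
        positions[i] = float(profile @ coords / total)
    return PositionTrace(fly_id=fly_id, positions=positions, start_zt=start_zt)


# ---------------------------------------------------------------------------
# standard output tables
# ---------------------------------------------------------------------------

def _hourly_frame(summaries: Iterable, attr: str) -> pd.DataFrame:
    recs = []
    for s in summaries:
        row: dict = {"fly_id": s.fly_id, "day": s.day_index}
        row.update(dict(zip(HOUR_COLUMNS, getattr(s, attr))))
        recs.append(row)
    cols = ["fly_id", "day", *HOUR_COLUMNS]
    return pd.DataFrame(recs, columns=cols)


def write_activity_csv(summaries: Iterable, path: str | Path) -> None:
    """FAEn (event counts) per fly-day per hour; columns ZT00..ZT23."""
    df = _hourly_frame(summaries, "faen_by_hour")
    df[list(HOUR_COLUMNS)] = df[list(HOUR_COLUMNS)].astype(int)
    df.to_csv(path, index=False)


def write_feeding_csv(summaries: Iterable, path: str | Path) -> None:
    """FAErt (residence seconds) per fly-day per hour; columns ZT00..ZT23."""
    df = _hourly_frame(summaries, "faert_by_hour")
    df.to_csv(path, index=False)


def read_activity_csv(path: str | Path) -> list:
    return _read_hourly_csv(path, "faen")


def read_feeding_csv(path: str | Path) -> list:
    return _read_hourly_csv(path, "faert")


def _read_hourly_csv(path: str | Path, which: str) -> list:
    from .rhythm_summary import HourlySummary

    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        vec = row[list(HOUR_COLUMNS)].to_numpy(float)
        kwargs = dict(
            fly_id=str(row["fly_id"]),
            day_index=int(row["day"]),
            faen_by_hour=np.zeros(24, dtype=int),
            faert_by_hour=np.zeros(24),
        )
        if which == "faen":
            kwargs["faen_by_hour"] = vec.astype(int)
        else:
            kwargs["faert_by_hour"] = vec
        out.append(HourlySummary(**kwargs))
    return out


def write_feeding_pdf_csv(events: Iterable, path: str | Path) -> None:
    """One row per food-approaching event, retained and rejected alike.

    Keeping rejected events (with ``retained=False``) makes the unfiltered
    duration distribution recoverable from this single file.
    """
    recs = [
        {
            "fly_id": e.fly_id,
            "day": e.day_index,
            "onset_zt_s": e.onset_zt_s,
            "duration_s": e.duration_s,
            "label": e.label,
            "retained": e.retained,
        }
        for e in events
    ]
    cols = ["fly_id", "day", "onset_zt_s", "duration_s", "label", "retained"]
    pd.DataFrame(recs, columns=cols).to_csv(path, index=False)


def read_feeding_pdf_csv(path: str | Path) -> list:
    from .fae_core import ApproachEvent

    df = pd.read_csv(path)
    return [
        ApproachEvent(
            fly_id=str(r.fly_id),
            day_index=int(r.day),
            onset_zt_s=int(r.onset_zt_s),
            duration_s=int(r.duration_s),
            label=str(r.label),
            retained=bool(r.retained),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# annotation tables and key-value config
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a manual feeding/no-feeding annotation table.

    Required columns: ``fly_id, day, onset_zt_s, label`` with label in
    {feeding, no_feeding}.
    """
    df = pd.read_csv(path)
    required = {"fly_id", "day", "onset_zt_s", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {sorted(missing)}")
    bad = set(df["label"].unique()) - {"feeding", "no_feeding"}
    if bad:
        raise ValueError(f"{path}: unknown annotation labels {sorted(bad)}")
    df["fly_id"] = df["fly_id"].astype(str)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


#: recognised configuration keys with defaults
CONFIG_DEFAULTS: Mapping[str, object] = {
    "tube_length_px": 130.0,
    "body_length_px": 11.0,
    "zt0_offset_s": 0,
    "light_schedule": "LD",
    "low_cutoff_s": 7,
    "high_cutoff_s": 300,
}


def load_config(path: str | Path) -> dict:
    """Load a key-value (YAML) analysis config, filling documented defaults."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = dict(CONFIG_DEFAULTS)
    cfg.update(raw)
    return cfg
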