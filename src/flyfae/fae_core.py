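"""Food-approaching event (FAE) detection.

A fly in a one-food-end tube performs discrete visits to the food: it enters
the feeding zone — the region within one body length of the food surface —
stays for some seconds, and leaves.  Each maximal contiguous run of samples
inside the zone is one FAE; the run length in 1-fps samples is its residence
time (FAErt contribution) and each run counts 1 toward FAEn.

The food-surface coordinate is not known a priori (tubes are hand-filled), so
it is detected per fly-day from the trace itself: by definition the farthest
coordinate the fly reaches in a 24-h recording, with a histogram-peak variant
for traces carrying single-sample tracking glitches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .trace_io import DAY_S, PositionTrace

LABELS = ("feeding", "no_feeding", "unlabeled")


@dataclass(frozen=True)
class FoodGeometry:
    """Food-surface coordinate(s) and the derived feeding-zone boundary.

    ``food_surface_px`` is either a single coordinate or a mapping
    ``day_index -> coordinate`` (surfaces are detected per fly-day).
    The feeding zone is ``[surface - body_length, surface]``; a sample is in
    the zone iff its position >= the zone boundary (inclusive).
    """

    food_surface_px: float | Mapping[int, float]
    body_length_px: float = 11.0

    def __post_init__(self) -> None:
        if self.body_length_px <= 0:
            raise ValueError("body_length_px must be positive")

    def surface(self, day_index: int) -> float:
        if isinstance(self.food_surface_px, Mapping):
            try:
                return float(self.food_surface_px[day_index])
            except KeyError:
                raise KeyError(f"no food surface for day {day_index}") from None
        return float(self.food_surface_px)

    def zone_boundary(self, day_index: int) -> float:
        return self.surface(day_index) - self.body_length_px


@dataclass(frozen=True)
class ApproachEvent:
    """One food-approaching event.

    ``onset_zt_s`` is seconds from ZT 0 of the event's own day; durations are
    integer seconds (1-fps sampling).  ``retained`` is set by the duration
    band filter and defaults to True (unfiltered analysis uses all events).
    """

    fly_id: str
    day_index: int
    onset_zt_s: int
    duration_s: int
    label: str = "unlabeled"
    retained: bool = True

    def __post_init__(self) -> None:
        if self.duration_s < 1:
            raise ValueError("event duration must be >= 1 s")
        if not 0 <= self.onset_zt_s < DAY_S:
            raise ValueError("event onset must lie in [0, 86400) ZT seconds")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    def with_label(self, label: str) -> "ApproachEvent":
        return replace(self, label=label)

    def with_retained(self, retained: bool) -> "ApproachEvent":
        return replace(self, retained=retained)


# ---------------------------------------------------------------------------
# food-surface detection
# ---------------------------------------------------------------------------

def detect_food_surface(trace: PositionTrace, day_index: int,
                        method: str = "max") -> float:
    """Detect the food-surface coordinate for one fly-day.

    ``method="max"`` (default) returns the farthest (maximum) non-missing
    coordinate of that fly-day — the literal definition.  ``method="peak_mode"``
    returns the highest-coordinate local maximum of the 1-px position
    histogram, which is robust to single-sample tracking glitches: a fly
    visiting the food dwells there, so the surface shows up as a histogram
    peak, while a glitch contributes a lone count with no dwell.
    """
    pos = trace.day_positions(day_index)
    ok = ~trace.day_missing(day_index)
    vals = pos[ok]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(
            f"fly {trace.fly_id!r} day {day_index}: all samples missing, "
            "no food surface detectable"
        )
    if method == "max":
        return float(vals.max())
    if method == "peak_mode":
        from scipy.signal import find_peaks

        lo, hi = np.floor(vals.min()), np.ceil(vals.max())
        edges = np.arange(lo, hi + 2.0)  # 1-px bins
        counts, _ = np.histogram(vals, bins=edges)
        centers = edges[:-1] + 0.5
        # a dwell peak needs >= 2 samples: a single-sample glitch bin is not
        # a surface, which is what makes this variant robust
        peaks, _ = find_peaks(np.r_[-1.0, counts, -1.0], height=2)
        if peaks.size == 0:
            return float(vals.max())
        return float(centers[peaks - 1].max())
    raise ValueError(f"unknown method {method!r}")


def detect_geometry(trace: PositionTrace, body_length_px: float = 11.0,
                    method: str = "max") -> FoodGeometry:
    """Per-day food geometry for a whole trace (excluded days skipped)."""
    surfaces: dict[int, float] = {}
    for day in range(trace.start_zt // DAY_S, trace.n_days):
        if day in trace.excluded_days:
            continue
        vals = trace.day_positions(day)
        if vals.size == 0 or np.all(np.isnan(vals)):
            continue
        surfaces[day] = detect_food_surface(trace, day, method=method)
    if not surfaces:
        raise ValueError(f"fly {trace.fly_id!r}: no analysable day")
    return FoodGeometry(food_surface_px=surfaces, body_length_px=body_length_px)


# ---------------------------------------------------------------------------
# event segmentation
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs in a boolean array."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def segment_events(
    trace: PositionTrace,
    geometry: FoodGeometry,
    missing_policy: str = "break",
    bridge_k: int = 0,
) -> list[ApproachEvent]:
    """Segment a trace into food-approaching events.

    An event is a maximal run of consecutive samples with position >= the
    day's zone boundary.  Runs never span the ZT-0 day boundary (the food
    surface is a per-day quantity); a run crossing it would be split, each
    part assigned to its own day.  Days listed in ``trace.excluded_days``
    produce no events.

    ``missing_policy="break"`` (default) ends a run at any missing sample —
    presence in the zone is never invented.  ``missing_policy="bridge_k"``
    tolerates gaps of at most ``bridge_k`` consecutive missing samples whose
    flanking samples are both in the zone; bridged samples count toward the
    event duration.
    """
    if missing_policy not in ("break", "bridge_k"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    events: list[ApproachEvent] = []
    for day in range(trace.start_zt // DAY_S, trace.n_days):
        if day in trace.excluded_days:
            continue
        sl = trace.day_slice(day)
        pos = trace.positions[sl]
        missing = trace.day_missing(day)
        if pos.size == 0:
            continue
        try:
            boundary = geometry.zone_boundary(day)
        except KeyError:
            continue
        with np.errstate(invalid="ignore"):
            in_zone = np.where(missing, False, pos >= boundary)
        if missing_policy == "bridge_k" and bridge_k > 0:
            in_zone = in_zone.copy()
            for g0, g1 in _runs(missing):
                if (
                    g1 - g0 <= bridge_k
                    and g0 > 0
                    and g1 < len(in_zone)
                    and in_zone[g0 - 1]
                    and in_zone[g1]
                ):
                    in_zone[g0:g1] = True
        day_start_zt = sl.start + trace.start_zt - day * DAY_S
        for r0, r1 in _runs(in_zone):
            events.append(
                ApproachEvent(
                    fly_id=trace.fly_id,
                    day_index=day,
                    onset_zt_s=int(day_start_zt + r0),
                    duration_s=int(r1 - r0),
                )
            )
    return events


def segment_plate(plate, body_length_px: float = 11.0,
                  surface_method: str = "max",
                  missing_policy: str = "break", bridge_k: int = 0) -> list[ApproachEvent]:
    """Detect geometry and segment events for every trace on a plate."""
    events: list[ApproachEvent] = []
    for trace in plate.traces:
        if trace.excluded_days and len(trace.excluded_days) >= trace.n_days:
            continue
        try:
            geom = detect_geometry(trace, body_length_px, method=surface_method)
        except ValueError:
            continue  # fly with no analysable day contributes nothing
        events.extend(segment_events(trace, geom, missing_policy, bridge_k))
    return events


# ---------------------------------------------------------------------------
# the three indices
# ---------------------------------------------------------------------------

class Indices(NamedTuple):
    """FAEn / FAErt / FAErt-per-event over one interval.

    ``undefined`` flags the FAEn = 0 case, where the ratio is reported as 0
    by convention but is not a meaningful average.
    """

    faen: int
    faert_s: int
    faert_per_event: float
    undefined: bool


def compute_indices(events: Iterable[ApproachEvent],
                    interval: tuple[float, float] = (0, DAY_S),
                    retained_only: bool = False) -> Indices:
    """Compute FAEn, FAErt and FAErt/n for events with onset in ``interval``.

    ``interval`` is half-open ``[start, end)`` in ZT seconds; events are
    assigned to intervals by onset time so FAEn stays additive across bins.
    """
    start, end = interval
    sel = [
        e for e in events
        if start <= e.onset_zt_s < end and (e.retained or not retained_only)
    ]
    faen = len(sel)
    faert = sum(e.duration_s for e in sel)
    if faen == 0:
        return Indices(0, 0, 0.0, True)
    return Indices(faen, faert, faert / faen, False)
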