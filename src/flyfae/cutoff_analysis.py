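"""Duration-band filter calibration and application.

Short visits to the food are dominated by exploration without feeding, while
genuine feeding visits last longer; very long "visits" (>= 5 min of
quiescence at the food end) are sleep, not feeding.  A duration band filter
[low, high] (both edges inclusive, defaults 7 s and 300 s) therefore
separates feeding from non-feeding events.

Calibration uses manually annotated events (feeding = proboscis extended at
least twice during the visit, scored from high-magnification video): this
module merges those annotations onto detected events, tabulates per-duration-
bin feeding/no-feeding proportions, and sweeps candidate low cut-offs over a
grid (default 2-9 s) reporting, for each label, the fraction of events and
of residence time retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fae_core import ApproachEvent

#: default duration-bin edges for proportion tables, seconds (inclusive ranges)
DEFAULT_BINS: tuple[tuple[float, float], ...] = ((1, 3), (4, 6), (7, 9), (10, np.inf))
#: default low-cut-off sweep grid, seconds
DEFAULT_SWEEP_GRID: tuple[int, ...] = tuple(range(2, 10))


@dataclass(frozen=True)
class EventFilter:
    """Duration band filter: retain events with low <= duration <= high."""

    low_cutoff_s: float = 7
    high_cutoff_s: float = 300

    def __post_init__(self) -> None:
        if not 1 <= self.low_cutoff_s <= self.high_cutoff_s:
            raise ValueError(
                f"need 1 <= low ({self.low_cutoff_s}) <= high ({self.high_cutoff_s})"
            )

    def retains(self, duration_s: float) -> bool:
        return self.low_cutoff_s <= duration_s <= self.high_cutoff_s


@dataclass(frozen=True)
class SweepResult:
    """Retention fractions per candidate low cut-off, for labeled events."""

    thresholds: tuple[float, ...]
    feeding_event_retention: tuple[float, ...]
    no_feeding_event_retention: tuple[float, ...]
    feeding_rt_retention: tuple[float, ...]
    no_feeding_rt_retention: tuple[float, ...]
    n_feeding: int = 0
    n_no_feeding: int = 0
    feeding_rt_total_s: float = 0.0
    no_feeding_rt_total_s: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_s": self.thresholds,
                "feeding_event_retention": self.feeding_event_retention,
                "no_feeding_event_retention": self.no_feeding_event_retention,
                "feeding_rt_retention": self.feeding_rt_retention,
                "no_feeding_rt_retention": self.no_feeding_rt_retention,
                "feeding_event_elimination": 1 - np.asarray(self.feeding_event_retention),
                "no_feeding_event_elimination": 1 - np.asarray(self.no_feeding_event_retention),
                "feeding_rt_elimination": 1 - np.asarray(self.feeding_rt_retention),
                "no_feeding_rt_elimination": 1 - np.asarray(self.no_feeding_rt_retention),
            }
        )


def apply_band_filter(events: Iterable[ApproachEvent],
                      filt: EventFilter = EventFilter()) -> list[ApproachEvent]:
    """Set each event's ``retained`` flag per the band filter (idempotent)."""
    return [e.with_retained(filt.retains(e.duration_s)) for e in events]


def merge_annotations(
    events: Sequence[ApproachEvent],
    annotations: pd.DataFrame,
    tolerance_s: int = 1,
) -> tuple[list[ApproachEvent], pd.DataFrame]:
    """Attach manual feeding/no-feeding labels to detected events.

    An annotation matches the event of the same fly and day whose onset lies
    within ``tolerance_s`` seconds (default 1 s: the annotation videos run at
    a higher frame rate than the 1-fps recording, so onsets can disagree at
    the sub-second level); ties go to the closest onset.  Two annotations
    resolving to one event is a hard error.  Returns the labeled event list
    and a table of unmatched annotations.
    """
    required = {"fly_id", "day", "onset_zt_s", "label"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")

    labeled = list(events)
    index: dict[tuple[str, int], list[int]] = {}
    for i, e in enumerate(labeled):
        index.setdefault((e.fly_id, e.day_index), []).append(i)
    claimed: dict[int, tuple] = {}
    unmatched_rows = []
    for row in annotations.itertuples():
        key = (str(row.fly_id), int(row.day))
        best_i, best_d = None, None
        for i in index.get(key, ()):
            d = abs(labeled[i].onset_zt_s - row.onset_zt_s)
            if d <= tolerance_s and (best_d is None or d < best_d):
                best_i, best_d = i, d
        if best_i is None:
            unmatched_rows.append(row._asdict())
            continue
        if best_i in claimed:
            raise ValueError(
                f"duplicate annotation for event fly {key[0]!r} day {key[1]} "
                f"onset {labeled[best_i].onset_zt_s}: "
                f"{claimed[best_i]} and {(row.onset_zt_s, row.label)}"
            )
        claimed[best_i] = (row.onset_zt_s, row.label)
        labeled[best_i] = labeled[best_i].with_label(str(row.label))
    unmatched = pd.DataFrame(unmatched_rows).drop(columns=["Index"], errors="ignore")
    return labeled, unmatched


def _labeled_arrays(events: Iterable[ApproachEvent]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(e.label, e.duration_s) for e in events if e.label != "unlabeled"],
        columns=["label", "duration_s"],
    )
    return df


def proportion_table(
    labeled: Sequence[ApproachEvent],
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Per-duration-bin feeding/no-feeding shares of FAEn and FAErt.

    Shares are taken against the labeled grand totals, so they sum to 1 over
    all (bin, label) cells, separately for event counts and residence time.
    """
    df = _labeled_arrays(labeled)
    if df.empty:
        raise ValueError("proportion_table requires at least one labeled event")
    total_n = len(df)
    total_rt = df["duration_s"].sum()
    rows = []
    for lo, hi in bins:
        bin_label = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">={lo:g}"
        in_bin = df[(df["duration_s"] >= lo) & (df["duration_s"] <= hi)]
        for label in ("feeding", "no_feeding"):
            sub = in_bin[in_bin["label"] == label]
            rows.append(
                {
                    "bin": bin_label,
                    "label": label,
                    "n_events": len(sub),
                    "faert_s": int(sub["duration_s"].sum()),
                    "faen_share": len(sub) / total_n,
                    "faert_share": sub["duration_s"].sum() / total_rt,
                }
            )
    return pd.DataFrame(rows)


def sweep_thresholds(
    labeled: Sequence[ApproachEvent],
    thresholds: Sequence[float] = DEFAULT_SWEEP_GRID,
    high_cutoff_s: float = 300,
) -> SweepResult:
    """Retention fractions per candidate low cut-off.

    For each threshold t, an event is retained iff t <= duration <= high
    cut-off; retention is reported per label, for event counts and for
    residence time, against the labeled totals.
    """
    df = _labeled_arrays(labeled)
    by_label = {}
    for label in ("feeding", "no_feeding"):
        sub = df[df["label"] == label]
        if sub.empty:
            raise ValueError(f"sweep_thresholds: no events labeled {label!r}")
        by_label[label] = sub["duration_s"].to_numpy()

    def retention(durations: np.ndarray, t: float) -> tuple[float, float]:
        kept = durations[(durations >= t) & (durations <= high_cutoff_s)]
        return len(kept) / len(durations), kept.sum() / durations.sum()

    fe, nfe, frt, nfrt = [], [], [], []
    for t in thresholds:
        a, b = retention(by_label["feeding"], t)
        c, d = retention(by_label["no_feeding"], t)
        fe.append(a)
        frt.append(b)
        nfe.append(c)
        nfrt.append(d)
    return SweepResult(
        thresholds=tuple(float(t) for t in thresholds),
        feeding_event_retention=tuple(fe),
        no_feeding_event_retention=tuple(nfe),
        feeding_rt_retention=tuple(frt),
        no_feeding_rt_retention=tuple(nfrt),
        n_feeding=len(by_label["feeding"]),
        n_no_feeding=len(by_label["no_feeding"]),
        feeding_rt_total_s=float(by_label["feeding"].sum()),
        no_feeding_rt_total_s=float(by_label["no_feeding"].sum()),
    )
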