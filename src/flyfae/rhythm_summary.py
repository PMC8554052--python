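"""Circadian feeding-rhythm summaries and group comparisons.

Filtered events are binned into per-fly hourly curves of FAEn (visit counts),
FAErt (residence seconds) and FAErt/n (seconds per visit), summarised over
named ZT windows (canonically morning peak ZT 0-2, day time ZT 3-11, evening
peak ZT 12-14 and night time ZT 15-23), aggregated into group mean +/- SEM
curves, and compared with standard tests (t-test, one-/two-way ANOVA with
Tukey HSD).  Multi-day recordings are averaged within fly before any group
statistic, so each fly is one independent unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .fae_core import ApproachEvent
from .trace_io import DAY_S

HOUR_S = 3600

#: canonical ZT windows (half-open, seconds); they partition the day
CANONICAL_WINDOWS: Mapping[str, tuple[int, int]] = {
    "morning_peak": (0 * HOUR_S, 3 * HOUR_S),     # ZT 0-2
    "day_time": (3 * HOUR_S, 12 * HOUR_S),        # ZT 3-11
    "evening_peak": (12 * HOUR_S, 15 * HOUR_S),   # ZT 12-14
    "night_time": (15 * HOUR_S, 24 * HOUR_S),     # ZT 15-23
}

#: day/night split (ZT 0-11 vs 12-23; subjective under DD)
DAY_NIGHT_WINDOWS: Mapping[str, tuple[int, int]] = {
    "day": (0, 12 * HOUR_S),
    "night": (12 * HOUR_S, 24 * HOUR_S),
}

SIGNIFICANCE_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for level, stars in SIGNIFICANCE_LEVELS:
        if p < level:
            return stars
    return "n.s."


# ---------------------------------------------------------------------------
# hourly summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HourlySummary:
    """Per-fly, per-day hourly FAEn / FAErt / FAErt-per-event vectors."""

    fly_id: str
    day_index: int
    faen_by_hour: np.ndarray        # 24 non-negative ints
    faert_by_hour: np.ndarray       # 24 second-sums
    faert_per_event_by_hour: np.ndarray = None  # type: ignore[assignment]
    undefined_hours: np.ndarray = None          # type: ignore[assignment]

    def __post_init__(self) -> None:
        faen = np.asarray(self.faen_by_hour, dtype=int)
        faert = np.asarray(self.faert_by_hour, dtype=float)
        if faen.shape != (24,) or faert.shape != (24,):
            raise ValueError("hourly vectors must have 24 entries")
        if (faen < 0).any():
            raise ValueError("FAEn must be non-negative")
        if faert.sum() > DAY_S:
            raise ValueError("total FAErt exceeds one day of seconds")
        object.__setattr__(self, "faen_by_hour", faen)
        object.__setattr__(self, "faert_by_hour", faert)
        if self.faert_per_event_by_hour is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(faen > 0, faert / np.maximum(faen, 1), 0.0)
            object.__setattr__(self, "faert_per_event_by_hour", ratio)
        if self.undefined_hours is None:
            object.__setattr__(self, "undefined_hours", faen == 0)


def hourly_summarize(events: Iterable[ApproachEvent], fly_id: str,
                     day: int, retained_only: bool = True) -> HourlySummary:
    """Hourly FAEn/FAErt for one fly-day; hour h covers [3600h, 3600(h+1))."""
    faen = np.zeros(24, dtype=int)
    faert = np.zeros(24)
    for e in events:
        if e.fly_id != fly_id or e.day_index != day:
            continue
        if retained_only and not e.retained:
            continue
        h = e.onset_zt_s // HOUR_S
        faen[h] += 1
        faert[h] += e.duration_s
    return HourlySummary(fly_id=fly_id, day_index=day,
                         faen_by_hour=faen, faert_by_hour=faert)


def hourly_summaries(events: Sequence[ApproachEvent],
                     fly_days: Iterable[tuple[str, int]] | None = None,
                     retained_only: bool = True) -> list[HourlySummary]:
    """One :class:`HourlySummary` per fly-day.

    ``fly_days`` lists the (fly_id, day) units to summarise; when omitted it
    is inferred from the events themselves (note that a fly-day with zero
    events then produces no summary — pass ``fly_days`` explicitly to include
    silent fly-days as all-zero rows).
    """
    if fly_days is None:
        fly_days = sorted({(e.fly_id, e.day_index) for e in events})
    return [hourly_summarize(events, f, d, retained_only) for f, d in fly_days]


def average_across_days(summaries: Sequence[HourlySummary]) -> pd.DataFrame:
    """Per-fly hourly curves averaged over that fly's included days.

    Returns a tidy frame: fly_id, hour, faen, faert, n_days.
    """
    rows = []
    for s in summaries:
        for h in range(24):
            rows.append((s.fly_id, h, s.faen_by_hour[h], s.faert_by_hour[h]))
    df = pd.DataFrame(rows, columns=["fly_id", "hour", "faen", "faert"])
    out = df.groupby(["fly_id", "hour"], as_index=False).agg(
        faen=("faen", "mean"), faert=("faert", "mean"), n_days=("faen", "size")
    )
    return out


# ---------------------------------------------------------------------------
# window summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSummary:
    """Per-fly index totals within one named ZT window."""

    window: str
    start_s: int
    end_s: int
    per_fly: pd.DataFrame  # fly_id, faen, faert_s, faert_per_event, undefined


def window_summarize(
    events: Sequence[ApproachEvent],
    windows: Mapping[str, tuple[int, int]] = CANONICAL_WINDOWS,
    retained_only: bool = True,
    allow_overlap: bool = False,
) -> list[WindowSummary]:
    """Index totals per fly for each named half-open ZT window.

    Events are assigned by onset.  Overlapping windows are a hard error
    unless explicitly allowed.  Multi-day events for one fly accumulate into
    that fly's window total.
    """
    items = sorted(windows.items(), key=lambda kv: kv[1])
    if not allow_overlap:
        for (na, (a0, a1)), (nb, (b0, b1)) in zip(items, items[1:]):
            if b0 < a1:
                raise ValueError(f"windows {na!r} and {nb!r} overlap")
    flies = sorted({e.fly_id for e in events})
    out = []
    for name, (w0, w1) in windows.items():
        rows = []
        for fly in flies:
            sel = [
                e for e in events
                if e.fly_id == fly and w0 <= e.onset_zt_s < w1
                and (e.retained or not retained_only)
            ]
            faen = len(sel)
            faert = sum(e.duration_s for e in sel)
            rows.append(
                {
                    "fly_id": fly,
                    "faen": faen,
                    "faert_s": faert,
                    "faert_per_event": faert / faen if faen else 0.0,
                    "undefined": faen == 0,
                }
            )
        out.append(WindowSummary(window=name, start_s=w0, end_s=w1,
                                 per_fly=pd.DataFrame(rows)))
    return out


def window_summary_frame(summaries: Iterable[WindowSummary]) -> pd.DataFrame:
    frames = []
    for ws in summaries:
        df = ws.per_fly.copy()
        df.insert(0, "window", ws.window)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# group aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupCurve:
    """Group mean +/- SEM hourly curves (across flies; days pre-averaged)."""

    label: str
    n_flies: int
    faen_mean: np.ndarray
    faen_sem: np.ndarray
    faert_mean: np.ndarray
    faert_sem: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.label,
                "hour": np.arange(24),
                "faen_mean": self.faen_mean,
                "faen_sem": self.faen_sem,
                "faert_mean": self.faert_mean,
                "faert_sem": self.faert_sem,
                "n": self.n_flies,
            }
        )


def group_aggregate(
    summaries: Sequence[HourlySummary],
    groups: Mapping[str, str] | None = None,
) -> dict[str, GroupCurve]:
    """Aggregate hourly summaries into group mean +/- SEM curves.

    ``groups`` maps fly_id to a group label (default: all flies in one group
    "all").  Days are first averaged within fly, so n counts flies.  SEM is
    the sample standard deviation over flies divided by sqrt(n); with a
    single fly the SEM is reported as NaN (undefined), with zero flies the
    group is a hard error.
    """
    per_fly = average_across_days(summaries)
    if groups is None:
        groups = {f: "all" for f in per_fly["fly_id"].unique()}
    out: dict[str, GroupCurve] = {}
    for label in sorted(set(groups.values())):
        flies = sorted(f for f, g in groups.items() if g == label)
        sub = per_fly[per_fly["fly_id"].isin(flies)]
        n = sub["fly_id"].nunique()
        if n == 0:
            raise ValueError(f"group {label!r} has no flies")
        faen = sub.pivot(index="fly_id", columns="hour", values="faen").to_numpy()
        faert = sub.pivot(index="fly_id", columns="hour", values="faert").to_numpy()
        if n > 1:
            faen_sem = faen.std(axis=0, ddof=1) / np.sqrt(n)
            faert_sem = faert.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            faen_sem = np.full(24, np.nan)
            faert_sem = np.full(24, np.nan)
        out[label] = GroupCurve(
            label=label,
            n_flies=int(n),
            faen_mean=faen.mean(axis=0),
            faen_sem=faen_sem,
            faert_mean=faert.mean(axis=0),
            faert_sem=faert_sem,
        )
    return out


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonReport:
    """Result schema for group comparisons.

    ``table`` holds the test statistics (one row for a t-test, the ANOVA
    table for one-/two-way designs); ``pairwise`` the Tukey HSD table when
    applicable.
    """

    design: str
    statistic: float
    p_value: float
    stars: str
    table: pd.DataFrame
    pairwise: pd.DataFrame | None = None


def compare_groups(
    a: Sequence[float] | None = None,
    b: Sequence[float] | None = None,
    design: str = "two_sample",
    groups: Sequence[Sequence[float]] | None = None,
    labels: Sequence[str] | None = None,
    data: pd.DataFrame | None = None,
    value: str = "value",
    factors: tuple[str, str] = ("factor_a", "factor_b"),
    tukey: bool = True,
) -> ComparisonReport:
    """Standard group comparisons with the usual significance stars.

    * ``two_sample`` — two-tailed independent-samples t-test on ``a`` vs ``b``.
    * ``one_way``    — one-way ANOVA over ``groups`` plus Tukey HSD.
    * ``two_way``    — two-way ANOVA (with interaction) on tidy ``data`` with
      columns ``value`` and the two ``factors``, plus Tukey HSD on the cells;
      an empty cell in the design is a hard error.

    Numerics delegate to scipy/statsmodels; the report schema is this tool's
    contract.
    """
    if design == "two_sample":
        if a is None or b is None:
            raise ValueError("two_sample design needs samples a and b")
        a_arr, b_arr = np.asarray(a, float), np.asarray(b, float)
        if len(a_arr) < 2 or len(b_arr) < 2:
            raise ValueError("need >= 2 observations per group")
        res = sps.ttest_ind(a_arr, b_arr)
        df = len(a_arr) + len(b_arr) - 2
        t = float(res.statistic)
        p = float(res.pvalue)
        if np.isnan(t):  # zero pooled variance with equal means
            t, p = 0.0, 1.0
        table = pd.DataFrame(
            [{"test": "t_ind_two_tailed", "statistic": t, "df": df, "p_value": p}]
        )
        return ComparisonReport("two_sample", t, p, significance_stars(p), table)

    if design == "one_way":
        if groups is None or len(groups) < 2:
            raise ValueError("one_way design needs >= 2 groups")
        arrays = [np.asarray(g, float) for g in groups]
        if any(len(g) < 2 for g in arrays):
            raise ValueError("need >= 2 observations per group")
        f_res = sps.f_oneway(*arrays)
        f, p = float(f_res.statistic), float(f_res.pvalue)
        if labels is None:
            labels = [f"g{i}" for i in range(len(arrays))]
        table = pd.DataFrame(
            [
                {
                    "test": "one_way_anova",
                    "statistic": f,
                    "df_between": len(arrays) - 1,
                    "df_within": sum(len(g) for g in arrays) - len(arrays),
                    "p_value": p,
                }
            ]
        )
        pairwise = None
        if tukey:
            pairwise = _tukey(
                np.concatenate(arrays),
                np.concatenate([[l] * len(g) for l, g in zip(labels, arrays)]),
            )
        return ComparisonReport("one_way", f, p, significance_stars(p), table, pairwise)

    if design == "two_way":
        if data is None:
            raise ValueError("two_way design needs tidy data")
        fa, fb = factors
        for col in (value, fa, fb):
            if col not in data.columns:
                raise ValueError(f"two_way data missing column {col!r}")
        counts = data.groupby([fa, fb], observed=True).size()
        full = len(data[fa].unique()) * len(data[fb].unique())
        if len(counts) < full or (counts < 2).any():
            raise ValueError("two_way design has an empty or single-observation cell")
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        d = data.rename(columns={value: "y", fa: "A", fb: "B"})
        model = ols("y ~ C(A) * C(B)", data=d).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        p_inter = float(anova.loc["C(A):C(B)", "PR(>F)"])
        f_inter = float(anova.loc["C(A):C(B)", "F"])
        cells = (d["A"].astype(str) + ":" + d["B"].astype(str)).to_numpy()
        pairwise = _tukey(d["y"].to_numpy(float), cells)
        table = anova.reset_index(names="term")
        return ComparisonReport(
            "two_way", f_inter, p_inter, significance_stars(p_inter), table, pairwise
        )

    raise ValueError(f"unknown design {design!r}")


def _tukey(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    frame["stars"] = [significance_stars(p) for p in frame["p-adj"].astype(float)]
    return frame
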