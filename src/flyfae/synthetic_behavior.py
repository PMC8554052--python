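"""Synthetic tube-recording generator with ground truth.

Emulates 1-fps, one-dimensional tube traces of individually housed flies:
discrete visits to the food end are drawn from an inhomogeneous (per-hour)
Poisson profile — by default bimodal, peaking in the morning (ZT 0-1) and
evening (ZT 12-13) as wild-type flies do — and each visit is a feeding or a
non-feeding (exploration) visit with distinct duration distributions.
Feeding visits are log-normal with a 15-s median, capped at 250 s (the
longest annotated feeding visit observed); non-feeding visits are
geometric-like with a 2-s median and most mass at or below 6 s.  Between
visits the fly performs a bounded random walk strictly below the feeding
zone.  Everything is deterministic given the seed, and the programmed visits
are returned as ground truth in the annotation-table schema so the filter
calibration can consume them directly.

The generator emulates the *structure* of real recordings (visit process,
duration mixture, circadian modulation), not fly biomechanics: real traces
have autocorrelated locomotor bouts, sleep, and tracking noise that are not
modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .trace_io import DAY_S, PlateRecording, PositionTrace

#: guard gap (s) between programmed visits so detected runs never merge
VISIT_GAP_S = 2


def default_rate_profile() -> np.ndarray:
    """Bimodal visit intensity (visits/hour): morning and evening peaks.

    Baseline 2 visits/h with 8 visits/h at ZT 0-1 and ZT 12-13, a few-fold
    morning/evening elevation typical of entrained wild-type flies.
    """
    profile = np.full(24, 2.0)
    profile[[0, 1, 12, 13]] = 8.0
    return profile


@dataclass(frozen=True)
class LogNormalDuration:
    """Log-normal visit-duration distribution (integer seconds, capped)."""

    median_s: float = 15.0
    sigma: float = 0.8
    cap_s: int = 250

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raw = rng.lognormal(mean=np.log(self.median_s), sigma=self.sigma, size=n)
        return np.clip(np.rint(raw), 1, self.cap_s).astype(int)


@dataclass(frozen=True)
class GeometricDuration:
    """Geometric visit-duration distribution on {1, 2, ...} (capped)."""

    p: float = 1.0 / 3.0
    cap_s: int = 250

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raw = rng.geometric(self.p, size=n)
        return np.clip(raw, 1, self.cap_s).astype(int)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Geometry matches the standard optics: a 65-mm tube imaged at ~2 px/mm
    (130 px), food surface near the far end, male body length 11 px.
    ``feeding_fraction`` defaults to 0.36, the observed share of visits that
    involve feeding.  ``ld_mode="mutant_flat"`` replaces the rate profile
    with a constant rate equal to the bimodal profile's daily mean
    (arrhythmic clock-mutant mode).
    """

    seed: int = 0
    n_flies: int = 18
    n_days: int = 2
    tube_length_px: float = 130.0
    food_surface_px: float = 120.0
    body_length_px: float = 11.0
    rate_profile: np.ndarray = field(default_factory=default_rate_profile)
    feeding_fraction: float = 0.36
    feeding_duration_dist: LogNormalDuration = LogNormalDuration()
    no_feeding_duration_dist: GeometricDuration = GeometricDuration()
    away_step_px: float = 2.0
    ld_mode: str = "LD"

    def __post_init__(self) -> None:
        profile = np.asarray(self.rate_profile, dtype=float)
        object.__setattr__(self, "rate_profile", profile)
        if profile.shape != (24,) or (profile < 0).any():
            raise ValueError("rate_profile must be 24 non-negative entries")
        if self.ld_mode not in ("LD", "DD", "mutant_flat"):
            raise ValueError(f"unknown ld_mode {self.ld_mode!r}")
        if not 0 <= self.feeding_fraction <= 1:
            raise ValueError("feeding_fraction must lie in [0, 1]")
        if not 0 < self.food_surface_px <= self.tube_length_px:
            raise ValueError("food surface must lie inside the tube")

    @property
    def zone_boundary_px(self) -> float:
        return self.food_surface_px - self.body_length_px

    def effective_rate_profile(self) -> np.ndarray:
        if self.ld_mode == "mutant_flat":
            return np.full(24, float(self.rate_profile.mean()))
        return self.rate_profile


@dataclass(frozen=True)
class GroundTruth:
    """The programmed visits, exactly as placed."""

    frame: pd.DataFrame  # fly_id, day, onset_zt_s, duration_s, label

    def to_annotations(self) -> pd.DataFrame:
        """Annotation-table view (fly_id, day, onset_zt_s, label)."""
        return self.frame[["fly_id", "day", "onset_zt_s", "label"]].copy()

    def feeding_time_by_fly_day(self) -> pd.DataFrame:
        sub = self.frame[self.frame["label"] == "feeding"]
        return (
            sub.groupby(["fly_id", "day"], as_index=False)["duration_s"]
            .sum()
            .rename(columns={"duration_s": "feeding_s"})
        )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold an unbounded walk into [lo, hi] by reflection at both walls."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    return lo + np.where(y > width, 2.0 * width - y, y)


def _place_visits(
    rng: np.random.Generator,
    profile: np.ndarray,
    feeding_fraction: float,
    feeding_dist: LogNormalDuration,
    no_feeding_dist: GeometricDuration,
    max_tries: int = 200,
) -> list[tuple[int, int, str]]:
    """Draw one day's visits as (onset_s, duration_s, label), non-overlapping.

    Visit counts per hour are Poisson with the profile's intensity; onsets
    are uniform within their hour; collisions are resolved by re-drawing the
    onset within the hour (rejection).  Persistent failure to place a visit
    means the requested rate cannot fit and is a hard error.
    """
    occupied: list[tuple[int, int]] = []  # sorted (start, stop) with guard gap

    def fits(onset: int, dur: int) -> bool:
        lo, hi = onset - VISIT_GAP_S, onset + dur + VISIT_GAP_S
        return all(hi <= s or lo >= e for s, e in occupied)

    visits: list[tuple[int, int, str]] = []
    for hour in range(24):
        n = rng.poisson(profile[hour])
        for _ in range(n):
            label = "feeding" if rng.random() < feeding_fraction else "no_feeding"
            dist = feeding_dist if label == "feeding" else no_feeding_dist
            dur = int(dist.sample(rng, 1)[0])
            placed = False
            for _ in range(max_tries):
                onset = int(rng.integers(hour * 3600, (hour + 1) * 3600))
                if onset + dur > DAY_S:
                    continue
                if fits(onset, dur):
                    occupied.append((onset, onset + dur))
                    visits.append((onset, dur, label))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not place a visit without overlap; "
                    "lower the rate profile or shorten durations"
                )
    visits.sort()
    return visits


def simulate_cohort(config: SimulationConfig) -> tuple[PlateRecording, GroundTruth]:
    """Simulate a cohort of flies; returns traces plus programmed ground truth.

    Each visit appears in the trace as a contiguous in-zone run of exactly
    its drawn duration (positions within 2 px of the food surface); between
    visits the fly random-walks strictly below the zone boundary, so the
    event detector's recall of programmed visits is a pure measure of the
    detection chain, not of placement ambiguity.
    """
    if config.n_flies < 1 or config.n_flies > 18:
        raise ValueError("n_flies must be between 1 and 18")
    profile = config.effective_rate_profile()
    parent = np.random.default_rng(config.seed)
    fly_rngs = parent.spawn(config.n_flies)

    walk_lo = 5.0
    walk_hi = config.zone_boundary_px - 3.0
    if walk_hi <= walk_lo:
        raise ValueError("tube too short for the away-from-food walk")

    n_samples = config.n_days * DAY_S
    traces = []
    records = []
    for i, rng in enumerate(fly_rngs):
        fly_id = f"fly{i+1:02d}"
        steps = rng.normal(0.0, config.away_step_px, size=n_samples)
        steps[0] = 0.0
        walk = _reflect((walk_lo + walk_hi) / 2.0 + np.cumsum(steps), walk_lo, walk_hi)
        positions = walk
        for day in range(config.n_days):
            for onset, dur, label in _place_visits(
                rng, profile, config.feeding_fraction,
                config.feeding_duration_dist, config.no_feeding_duration_dist,
            ):
                a = day * DAY_S + onset
                positions[a:a + dur] = config.food_surface_px - rng.uniform(0.0, 2.0, dur)
                records.append(
                    {"fly_id": fly_id, "day": day, "onset_zt_s": onset,
                     "duration_s": dur, "label": label}
                )
        traces.append(PositionTrace(fly_id=fly_id, positions=positions))

    schedule = "DD" if config.ld_mode in ("DD", "mutant_flat") else "LD"
    plate = PlateRecording(
        traces=tuple(traces),
        light_schedule=schedule,
        tube_length_px=config.tube_length_px,
    )
    frame = pd.DataFrame(
        records, columns=["fly_id", "day", "onset_zt_s", "duration_s", "label"]
    ).sort_values(["fly_id", "day", "onset_zt_s"], ignore_index=True)
    return plate, GroundTruth(frame=frame)


def simulate_multi(config: SimulationConfig) -> tuple[list[PlateRecording], GroundTruth]:
    """Simulate a cohort larger than one plate (18 tubes) can hold.

    Flies are chunked onto successive plates; fly ids are globally unique and
    ground truth is pooled.  Plate k uses the child stream k of the config
    seed, so the first plate equals a plain :func:`simulate_cohort` run.
    """
    plates: list[PlateRecording] = []
    frames: list[pd.DataFrame] = []
    remaining = config.n_flies
    chunk_index = 0
    while remaining > 0:
        n = min(remaining, 18)
        chunk_seed = config.seed if chunk_index == 0 else (config.seed + 100_003 * chunk_index) % 2**31
        sub = replace(config, n_flies=n, seed=chunk_seed)
        plate, truth = simulate_cohort(sub)
        offset = chunk_index * 18
        if offset:
            renamed = []
            mapping = {}
            for t in plate.traces:
                old = t.fly_id
                new = f"fly{offset + int(old[3:]):02d}"
                mapping[old] = new
                renamed.append(replace(t, fly_id=new))
            plate = replace(plate, traces=tuple(renamed))
            tf = truth.frame.copy()
            tf["fly_id"] = tf["fly_id"].map(mapping)
            frames.append(tf)
        else:
            frames.append(truth.frame)
        plates.append(plate)
        remaining -= n
        chunk_index += 1
    pooled = pd.concat(frames, ignore_index=True).sort_values(
        ["fly_id", "day", "onset_zt_s"], ignore_index=True
    )
    return plates, GroundTruth(frame=pooled)


def render_frames(
    trace: PositionTrace,
    config: SimulationConfig,
    *,
    height: int = 9,
    sigma_px: float = 1.2,
    amplitude: float = 120.0,
    background: float = 200.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a trace as a grayscale frame stack (dark Gaussian fly blob).

    One frame per sample; missing samples render as blank background frames.
    Deterministic given ``seed`` (used only for the optional pixel noise).
    """
    width = int(np.ceil(config.tube_length_px)) + 1
    rng = np.random.default_rng(seed)
    yy = np.arange(height)[:, None]
    xx = np.arange(width)[None, :]
    yc = (height - 1) / 2.0
    stack = np.empty((len(trace.positions), height, width), dtype=np.uint8)
    for i, (pos, miss) in enumerate(zip(trace.positions, trace.missing_mask)):
        frame = np.full((height, width), background)
        if not miss:
            blob = amplitude * np.exp(
                -(((xx - pos) ** 2) + ((yy - yc) ** 2)) / (2.0 * sigma_px ** 2)
            )
            frame = frame - blob
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, frame.shape)
        stack[i] = np.clip(frame, 0, 255).astype(np.uint8)
    return stack
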