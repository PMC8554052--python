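"""Independent brute-force reference implementations used by the tests.

Everything here walks data structures sample-by-sample / event-by-event in
plain Python, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

DAY_S = 86_400


def scan_events(positions, missing, body_length_px):
    """Per-sample scan for in-zone runs; returns (day, onset_zt_s, duration).

    The zone boundary per day is (max non-missing position of that day) minus
    the body length, recomputed here from first principles.  Runs break at
    missing samples and at day boundaries.
    """
    n = len(positions)
    n_days = math.ceil(n / DAY_S)
    boundary = {}
    for day in range(n_days):
        best = None
        for i in range(day * DAY_S, min((day + 1) * DAY_S, n)):
            if not missing[i]:
                v = positions[i]
                if best is None or v > best:
                    best = v
        if best is not None:
            boundary[day] = best - body_length_px

    events = []
    run_start = None
    for i in range(n + 1):
        day = i // DAY_S
        in_zone = (
            i < n
            and day in boundary
            and not missing[i]
            and positions[i] >= boundary[day]
        )
        boundary_break = i % DAY_S == 0  # runs never span the day boundary
        if run_start is not None and (not in_zone or boundary_break):
            d0 = run_start // DAY_S
            events.append((d0, run_start - d0 * DAY_S, i - run_start))
            run_start = None
        if in_zone and run_start is None:
            run_start = i
    return events


def tally_hourly(event_rows):
    """Hour -> (faen, faert) from (onset_zt_s, duration_s) rows."""
    faen = [0] * 24
    faert = [0] * 24
    for onset, dur in event_rows:
        h = onset // 3600
        faen[h] += 1
        faert[h] += dur
    return faen, faert


def tally_proportions(labeled_rows, bins):
    """(bin, label) -> (count, rt, faen_share, faert_share) by exhaustive iteration.

    ``labeled_rows`` are (label, duration) pairs; ``bins`` inclusive (lo, hi).
    """
    total_n = len(labeled_rows)
    total_rt = sum(d for _, d in labeled_rows)
    out = {}
    for lo, hi in bins:
        for label in ("feeding", "no_feeding"):
            cnt, rt = 0, 0
            for lab, d in labeled_rows:
                if lab == label and lo <= d <= hi:
                    cnt += 1
                    rt += d
            out[(lo, hi, label)] = (cnt, rt, cnt / total_n, rt / total_rt)
    return out


def tally_retention(labeled_rows, thresholds, high):
    """threshold -> per-label (event retention, rt retention) by brute filter."""
    out = {}
    for t in thresholds:
        row = {}
        for label in ("feeding", "no_feeding"):
            durs = [d for lab, d in labeled_rows if lab == label]
            kept = [d for d in durs if t <= d <= high]
            row[label] = (len(kept) / len(durs), sum(kept) / sum(durs))
        out[t] = row
    return out
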