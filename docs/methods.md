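# Methods

## The behavioural model

A fly housed alone in a narrow glass tube with food at one end does not sit
on the food; it approaches, stays for seconds to minutes, and leaves. Each
such visit is a *food-approaching event* (FAE). Given a per-second 1-D
coordinate trace (0 px at the cotton end, increasing toward the food), an FAE
is a maximal run of consecutive samples inside the *feeding zone*: the region
within one body length of the food surface. Three indices summarise feeding
behaviour over any zeitgeber-time (ZT) interval:

- **FAEn** — the number of events with onset in the interval;
- **FAErt** — their summed residence time in seconds;
- **FAErt/n** — residence time per visit, FAErt / FAEn.

Short visits are dominated by exploration without feeding and very long
stays at the food end (>= 5 min of quiescence) are sleep, so a duration band
filter **[7 s, 300 s]** (both edges inclusive) isolates feeding-related
events. The low edge is calibrated from manually annotated
high-magnification video (feeding = two or more proboscis extensions during
a visit); the calibration machinery — annotation merge, duration-bin
proportion tables, and a low-cut-off sweep over 2–9 s reporting per-label
retention of event counts and residence time — is part of the package, so
the band can be re-derived for other optics or species.

## Geometry and detection choices

- **Food surface.** Detected per fly-day as the farthest coordinate the fly
  reaches that day (`method="max"`, the definitional choice). A
  histogram-based variant (`method="peak_mode"`) takes the
  highest-coordinate local maximum of the 1-px position histogram, requiring
  at least 2 samples in the peak bin: a fly must dwell to mark the surface,
  so single-sample tracking glitches cannot inflate the geometry. Both are
  exposed; `max` is the default.
- **Zone membership** is `position >= surface − body_length`, inclusive, so
  a fly exactly at the boundary is inside. Body length defaults to 11 px
  (males) and 12 px (females) at the standard optics (~2 px/mm).
- **Binning by onset.** Events are assigned to hours, windows, and days by
  onset time, keeping FAEn additive over any partition of the day. Runs
  never span the ZT-0 day boundary, because the surface is per-day; a
  crossing run is split and each part assigned to its day.
- **Missing samples** (tracking dropouts, unparseable cells) are kept as a
  mask, never interpolated. By default a missing sample ends a run
  (presence in the zone is never invented); `bridge_k` optionally tolerates
  gaps of <= k missing samples flanked by in-zone samples.
- **Stuck-fly sanitation.** A fly-day whose first ZT-0 sample reads exactly
  0 was parked at the cotton plug by the tracker and is excluded; exclusion
  is per fly-day, not per fly.
- **FAErt/n with FAEn = 0** is reported as 0 with an `undefined` flag and
  excluded from group means of the ratio.
- **Multi-day recordings** are averaged within fly before any group
  statistic, so n counts flies, and SEM is across flies (sample SD / sqrt n;
  undefined for n = 1).

## The synthetic cohort generator

The generator produces the study conditions used throughout the tests: 1-fps
traces in a 130-px tube (food surface at 120 px) in which visits are drawn
from an inhomogeneous Poisson process with a per-hour rate profile and
overlaid on a bounded Gaussian random walk (step SD 2 px) kept strictly
below the feeding zone.

- **Rate profile** — bimodal by default: 2 visits/h baseline with 8 visits/h
  at ZT 0–1 and ZT 12–13, the few-fold morning/evening elevation of
  entrained wild-type flies. `mutant_flat` mode (the arrhythmic clock-mutant
  control) replaces the profile with its daily mean (3 visits/h).
- **Visit labels** — feeding with probability 0.36, the observed share of
  visits that involve feeding in the annotated calibration data.
- **Durations** — feeding: log-normal, median 15 s, sigma 0.8, capped at
  250 s (the longest annotated feeding visit); non-feeding: geometric with
  p = 1/3 (median 2 s), same cap. These reproduce the calibration regime —
  about 91% of non-feeding visits are shorter than 7 s and about 85% of
  feeding visits last 7 s or longer — while the exact distribution families
  are a modelling choice (only histogram summaries of the real data exist)
  and are fully configurable.
- **Placement** — visit counts per hour are Poisson; onsets are uniform in
  the hour with rejection on overlap, keeping a 2-s guard gap so adjacent
  programmed visits can never merge into one detected run. Persistent
  placement failure (rates too high to fit) is a hard error.
- Everything is deterministic given the seed (per-fly child streams), and
  the programmed visits are returned as ground truth in the annotation-table
  schema, so the calibration sweep consumes simulator output directly.

What the generator does **not** model: autocorrelated locomotor bouts,
sleep, egg-laying, tracking noise, or drift in the food surface. Passing the
end-to-end tests therefore demonstrates that the detection, filtering and
summarisation chain is correct and lossless under the programmed visit
structure — not that the band filter's specific 7-s edge is optimal for any
particular real recording, which is what the calibration sweep on annotated
data is for.

## Validation design and problem sizes

- **Oracle equivalence.** Segmentation, proportion tables, threshold sweeps
  and hourly tallies are each checked against independent brute-force
  Python implementations that walk the data sample-by-sample, on 100 seeded
  random traces (2,000–10,000 samples, plus day-boundary-crossing traces of
  90,000) and 100 random labeled event sets.
- **End-to-end recovery** uses a 20-fly x 2-day cohort (two plates; a plate
  holds at most 18 tubes): detector recall of programmed visits and their
  durations is exact by construction of the generator (asserted at >= 99%
  and <= 1 s), and band-filtered FAErt tracks ground-truth feeding time to
  within 15% in the mean over fly-days. Single fly-days are Poisson-limited:
  with ~26 feeding visits/day the residual (retained long non-feeding visits
  minus rejected short feeding visits) has a per-day spread of a few
  percent, so occasional individual fly-days exceed 15% even under perfect
  detection; the mean is the meaningful recovery statistic.
- **Rhythm recovery.** The group FAErt curve's morning and evening argmax
  hours fall in the programmed peak set {0, 1, 12, 13}. For the flat
  (mutant) profile, each hour's group mean exceeds the daily mean by more
  than 2 SEM in at most 5% of 100 replicates — the per-hour calibration
  statement of the 2-SEM rule. (A family-wise form — *no* hour exceeding in
  a replicate — is not attainable by any i.i.d. generator: 24 one-sided
  ~2% comparisons per replicate imply a ~20–40% family-wise exceedance
  rate, which is why the check is per hour.)
- **Statistical sanity.** One-way ANOVA on three equal-mean simulated
  groups (n = 10 each, 1,000 replicates) rejects at the nominal 5% rate
  (+/- 2 points); a t-test of identical samples returns t = 0, p = 1.
- **Numerical conventions.** Durations are integer seconds (1-fps samples);
  hour/window binning is half-open in ZT seconds; retention fractions and
  proportion shares are exact rational tallies (share conservation asserted
  to 1e-9); band-filter edges are inclusive at 7 and 300 s so results are
  bit-reproducible.

## Known limitations

- Single-food-end straight tubes only; multi-end chambers would need a
  second zone definition.
- The minimal centroid tracker (median-background subtraction with a global
  floor, intensity-weighted centroid) is a convenience for frame stacks with
  one dark fly per ROI; it is not a general tracker and does not handle
  occlusion, multiple animals, or illumination drift.
- No periodogram/cosinor rhythm-strength statistics and no sleep
  architecture analysis; the 300-s high cut-off is the only contact with
  sleep.
- Sub-second timing is out of scope; annotation matching tolerates +/- 1 s
  of onset disagreement between the 1-fps recording and higher-rate
  annotation video.
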