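# flyfae

Circadian feeding-rhythm analysis for *Drosophila* tube recordings, built on
**food-approaching events (FAE)**: discrete visits a tube-housed fly makes to
the food end, extracted from per-second 1-D position traces.

Standard video-recording rigs (the same setups used for sleep and locomotor
analysis) image 18 flies in individual glass tubes at 1 frame/s and export
each fly's barycentre coordinate per second. `flyfae` turns those traces into
feeding-rhythm measurements for chronobiologists and behavioural
neuroscientists screening genotypes, diets, and light regimes.

## Method

For each fly-day the food-surface coordinate is detected as the farthest
position the fly reaches; the *feeding zone* is everything within one body
length ℓ of it (ℓ = 11 px males, 12 px females at ~2 px/mm). With x(t) the
position trace and b = surface − ℓ the zone boundary, each maximal run
{t : x(t) ≥ b} is one event, and over any ZT interval

- **FAEn** = number of events (by onset),
- **FAErt** = Σ event durations (s),
- **FAErt/n** = FAErt / FAEn (s per visit).

Because short visits are mostly exploration without feeding and ≥ 5 min of
quiescence at the food is sleep, events are passed through a **7–300 s band
filter** (inclusive) before rhythm analysis. The low edge is calibrated from
manually annotated high-magnification video via the included threshold sweep
(retention of labeled feeding / no-feeding events and residence time over
cut-offs 2–9 s). Filtered events feed hourly FAEn/FAErt/FAErt-per-event
curves, canonical window totals (morning peak ZT 0–2, day ZT 3–11, evening
peak ZT 12–14, night ZT 15–23), day/night LD-vs-DD totals, group mean ± SEM
curves, and t-test / one- and two-way ANOVA (+ Tukey HSD) comparisons.

A seeded simulator generates cohorts with programmable circadian visit rates
and distinct feeding / non-feeding duration distributions, returning ground
truth in the annotation schema — the package's own end-to-end test bed.

## Worked example

```python
import numpy as np
import flyfae as F

cfg = F.SimulationConfig(seed=1, n_flies=18, n_days=2)   # bimodal LD cohort
plate, truth = F.simulate_cohort(cfg)

events = F.segment_plate(plate, body_length_px=11)
filtered = F.apply_band_filter(events, F.EventFilter(7, 300))
print(f"detected {len(events)} events; retained {sum(e.retained for e in filtered)}")

curve = F.group_aggregate(F.hourly_summaries(filtered))["all"]
h = int(np.argmax(curve.faert_mean))
print(f"peak hour ZT{h}: FAErt {curve.faert_mean[h]:.1f} +/- {curve.faert_sem[h]:.1f} s/h (n={curve.n_flies})")

labeled, _ = F.merge_annotations(events, truth.to_annotations())
sweep = F.sweep_thresholds(labeled)
i7 = sweep.thresholds.index(7.0)
print(f"7-s cut-off eliminates {100*(1-sweep.no_feeding_event_retention[i7]):.0f}% of "
      f"no-feeding events, keeps {100*sweep.feeding_rt_retention[i7]:.0f}% of feeding time")
```

prints

```
detected 2643 events; retained 907
peak hour ZT13: FAErt 68.5 +/- 9.1 s/h (n=18)
7-s cut-off eliminates 92% of no-feeding events, keeps 96% of feeding time
```

i.e. the simulated cohort's evening feeding peak lands at ZT 13 (one of the
programmed peak hours), and the calibrated low cut-off removes nearly all
exploratory visits while preserving almost all feeding residence time.

## Command line

The same pipeline is exposed as composable subcommands
(`flyfae simulate | detect | filter | rhythm | sweep`):

```sh
flyfae simulate --seed 1 --n-flies 18 --n-days 2 --out-dir sim/
flyfae detect  sim/positions.csv --sex male --out-dir det/
flyfae filter  det/FeedingPDF.csv --low 7 --high 300 --out-dir fil/
flyfae rhythm  fil/FeedingPDF.csv --out-dir rhy/
flyfae sweep   det/FeedingPDF.csv sim/ground_truth.csv --out-dir swp/
```

Outputs are plain CSV: `FeedingPDF.csv` (one row per event, retained flag),
`Activity.csv` (FAEn per fly-day per hour, columns ZT00–ZT23), `Feeding.csv`
(FAErt, same shape), group curves, window summaries, and a sweep report; each
output directory gets a `manifest.json` with inputs, config hash, seed, and
per-stage counts. Position tables default to headerless CSV, one fly per
column, one row per second, first row at ZT 0 (`TableDialect` makes other
layouts explicit). Annotation tables are CSV with
`fly_id, day, onset_zt_s, label` where label ∈ {feeding, no_feeding}.

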