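# cagetrack

Individual locomotor activity of **group-housed mice** from RFID
baseplate reads — plus a synthetic cage simulator that emulates the
acquisition physics so every analysis stage can be validated against
known ground truth.

Modern home-cage monitoring places a 3 × 6 grid of RFID antennas (50 mm
pitch) beneath an unmodified, rack-mounted home cage of three tagged
mice. Each read reports which animal is above which antenna, so the
system tracks *individuals inside an established social group* around
the clock, with no handling and no social isolation. The price is
coarse data: positions are quantized to antenna-tile centers, the plate
scans at only a few hertz, and each antenna reports at most one tag per
cycle. `cagetrack` is the analysis side of such a system, written for
behavioural phenotypers and chronobiologists: it turns raw read streams
into per-animal distance, actograms, circadian onset/offset and
anticipation statistics, and social-proximity measures — and it ships a
simulator that generates realistic read streams from known trajectories
so the whole chain is testable end to end.

## What it computes

- **Localization & quantization error** — snap-to-center (Voronoi)
  assignment on the antenna grid; for a tag uniform over one tile of
  side *a*, the expected snap error is `(a/6)(√2 + ln(1+√2))` ≈ 19 mm
  at *a* = 50 mm (max `a√2/2` ≈ 35 mm).
- **Tracking** — per-tag assembly of antenna-center sequences, linear
  interpolation onto a 1 s grid, distance estimation, and validation
  against ground truth (Spearman ρ, regression slope). Estimates
  systematically under-report true path length; a 1.4× linear
  correction is available on explicit request only.
- **Activity** — 6-min binned distance series; double-plotted
  actograms; light/dark phase totals with standard acclimation
  exclusions; settling-bout duration after cage transfer; the
  anticipatory-activity index (18:00–19:00 pre-dark activity with the
  daytime total as ANCOVA covariate); one-way ANOVA / ANCOVA with
  Tukey's post-hoc test, implemented from first principles.
- **Circadian** — single-component cosinor with known period,
  `x(t) = M + A·cos(2πt/τ + φ) + e(t)`, fitted by least squares (M =
  MESOR, A = amplitude, φ = acrophase/CoG); per-cycle activity onset
  and offset as threshold crossings of the smoothed series in
  CoG-centered windows, yielding anticipation of lights-off/lights-on
  in minutes.
- **Social** — pairwise inter-animal distances with a huddle
  indicator, and per-animal occupancy heatmaps in 6-min bins centered
  on the detected onset.
- **Simulator** — activity-propensity profiles λ(t) (nocturnal base
  levels, anticipatory ramps, settling bout; three strain-like
  presets), a two-state rest/active correlated random walk with
  huddling at a shared nest, and a sequential-polling acquisition model
  (3 Hz default, read probability 0.9, nearest-tag-per-tile rule).

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from cagetrack import (LightSchedule, make_profile, simulate_activity_series,
                       mean_localization_error, max_localization_error,
                       run_distance_validation)
from cagetrack.circadian import cosinor_fit, detect_onset_offset
from cagetrack.simulate import programmed_onset_anticipation_min

print(f"mean quantization error: {mean_localization_error(50):.2f} mm "
      f"(max {max_localization_error(50):.2f} mm)")

rep = run_distance_validation(seed=1)   # 13 cages x 3 animals, 6 min each
print(rep.summary())

schedule = LightSchedule()              # lights 07:00-19:00, start at noon
profile = make_profile(schedule, strain="intermediate", settle_duration_min=0.0)
series = simulate_activity_series(profile, n_days=7, seed=4)
fit = cosinor_fit(series)
print(f"cosinor: M = {fit.mesor:.0f} mm/bin, A = {fit.amplitude:.0f} mm/bin, "
      f"acrophase at {fit.acrophase_clock_h(schedule):.1f} h clock time")
cycles = [r for r in detect_onset_offset(series, schedule) if r.detected]
ant = [r.anticipation_onset_min for r in cycles]
print(f"programmed anticipation: {programmed_onset_anticipation_min(profile):.0f} min")
print(f"detected onset anticipation over {len(ant)} cycles: "
      f"mean {np.mean(ant):.0f} min (sd {np.std(ant, ddof=1):.0f})")
```

prints

```
mean quantization error: 19.13 mm (max 35.36 mm)
distance validation over 39 segments: Spearman rho = 0.968 (p = 1.02e-23), regression est = 0.547 * true + 359.6 mm, mean est/true = 0.644
cosinor: M = 768 mm/bin, A = 630 mm/bin, acrophase at 23.7 h clock time
programmed anticipation: 75 min
detected onset anticipation over 6 cycles: mean 78 min (sd 4)
```

Reading this: snapping a uniformly placed tag to its tile center costs
19 mm on average. Across 39 simulated six-minute segments spanning
~1–20 m of true travel, the baseplate estimate preserves rank order
almost perfectly (ρ = 0.97) while under-reporting magnitude (slope
0.55 < 1) — exactly why relative comparisons need no correction but
absolute distances do. The fitted rhythm of the intermediate-activity
strain peaks near midnight, and the onset detector recovers the 75 min
of anticipation programmed into the profile to within a few minutes.

## Command line

The same pipeline runs from a shell, one YAML config driving every
stage (`cagetrack init-config cfg.yaml` writes a commented default):

```bash
cagetrack simulate  -c cfg.yaml -o run/   # reads.csv + truth.csv
cagetrack track     -c cfg.yaml -o run/
cagetrack activity  -c cfg.yaml -o run/
cagetrack circadian -c cfg.yaml -o run/
cagetrack social    -c cfg.yaml -o run/
cagetrack validate  -c cfg.yaml -o run/
cagetrack report    -c cfg.yaml -o run/ --plots
```

All outputs are CSV with a `#` header block carrying geometry, light
schedule and the clock anchor; a fixed `simulation.seed` makes the
whole run bit-reproducible.

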