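# Methods

This note documents the models and procedures behind `wormarena`, the
defaults that matter, what the synthetic data generator emulates, numerical
choices, and known limitations.

## The scoring model

A worm confined to a microfluidic arena is observed once per hour (one
grayscale scan of the 50-arena array). The pipeline's core assumption is
behavioral: a living worm visibly relocates between hourly scans, a dead one
does not. Death is therefore inferred from the centroid displacement of
detected worm-like objects between adjacent frames:

- An object *moves* across a frame pair when its matched centroid
  displacement strictly exceeds `move_threshold` = 7 px (~55 µm at the
  nominal 3200 dpi ≈ 7.9 µm/px). Displacement of exactly 7 px is
  non-moving — the boundary is strict.
- Any appearance or disappearance of an object also counts as one moving
  worm (a worm crossing pillar shadows can fragment or merge; treating
  topology change as motion is the conservative choice, avoiding premature
  death calls), capped at the larger object count of the pair.
- The per-arena, per-frame moving counts form the movement matrix written
  as `moving_counts.tsv`.

**Death rule.** The death time is the last timepoint with observed movement
before the first quiescent run spanning at least `quiescent_h` = 4 h.
Movement reappearing *after* such a run resets the scan only when confirmed
over at least `confirm_m` = 2 consecutive frames; an isolated positive frame
is treated as spurious (detector noise, drifting debris). Animals with no
qualifying quiescent run surviving to the end of the recording are censored
at the final timepoint. `quiescent_h` is converted to a frame count using
the series' actual median sampling interval (ceiling), so sub-hourly series
work unchanged. Setting `confirm_m = 1` recovers always-reset semantics for
users who prefer that reading of the guard.

The production implementation is a single backward pass from the final
frame (when a run ends, every resident animal should already be still): it
locates the last confirmed movement run, then the first qualifying quiet
run after it; the death anchor is the last movement before that quiet run.
The test suite proves this equivalent to the forward scan-and-reset
definition on 1000+ randomized moving-count series against an independently
coded forward state machine.

**Consequence of the rule.** A death occurring within the final
`quiescent_h` hours of a recording cannot be called (the quiet run cannot
complete), so such animals are censored — the recovery oracle in the tests
encodes exactly this.

## Detection

Arena crops are binarized per arena per frame. Otsu thresholding is local
because flatbed scanners leave a residual exposure gradient across the bed;
a single global threshold would bias detection by arena position. Two
guards make Otsu safe on degenerate input:

- a constant crop yields an empty mask (no contrast, no evidence of an
  object);
- the two Otsu classes must differ by at least `min_contrast` = 20 gray
  levels in mean. Otsu always finds *some* threshold, and on an empty arena
  containing only scanner noise the thresholded foreground percolates into
  one large spurious component. Worms absorb transillumination and sit
  ≥ 100 gray levels below background, so the floor costs nothing on real
  objects while making empty arenas read as empty.

Connected components use 8-connectivity (thin diagonal worm segments must
not fragment) and the size filter keeps area ≥ `min_area` = 300 px
("too small to be a worm" is strictly smaller). Polarity defaults to dark
objects and is configurable.

## Global frameshift compensation

A physical disturbance of the chip or scanner translates every arena at
once between two scans, which mimics movement everywhere and would reset
death calls across the array. For each frame pair, all matched displacement
vectors are pooled across arenas; the componentwise median estimates the
candidate shift. Genuinely still objects (dead animals, debris) sit exactly
on that vector, while live movement is isotropic and medians out. The pair
is flagged and the median subtracted from every displacement when (a) the
median magnitude is at least `min_shift` = 3 px and (b) more than
`agree_frac` = 50% of populated arenas contain at least one matched vector
within `min_shift` of the median. The "any object agrees" form matters: in
a mixed arena one live worm corrupts the arena's mean vector, but its dead
neighbor still evidences the shift directly. Fewer than three populated
arenas gives no quorum and no compensation.

## Occupancy

Loading is imperfect: arenas can hold 0–4+ objects. The occupancy class is
the modal detected-object count over the first `occupancy_window_h` = 10 h,
ties broken toward the larger count (a transiently merged pair should not
demote a double). Arenas classed 4+ are excluded as bubbles/debris. Arenas
with 2–3 residents receive a death call from the arena's moving-count
series — the time the last resident stops — and are flagged
`multi_occupancy` so users can exclude them downstream. Yield is the
fraction of arena capacity producing a usable endpoint (a death or a
censored-alive call).

## Survival statistics

Kaplan-Meier estimation and the two-group log-rank test are delegated to
`lifelines`; the tests cross-check them against hand-computed product-limit
and O/E/V tables. Conventions:

- Median and quartiles are the smallest event time with S(t) ≤ q, with no
  interpolation — hourly sampling makes interpolated quantiles false
  precision. A curve that never reaches the quantile reports it as not
  reached (NaN).
- Mean and SEM are computed over observed death times only; the censored
  count is reported alongside and the summary is flagged whenever censoring
  is present. Without imputation this is the only self-consistent choice.
- Lethality at time t = deaths with time ≤ t over subjects still under
  observation at t or with an earlier event; equal to 1 − S(t) when no
  censoring precedes t.

The dose-response model is `median = a · dose^b`, fitted by least squares
on (ln dose, ln median) — the convention behind spreadsheet "power fit"
trendlines, so printed (a, b, R²) triples are directly comparable. R² is
that of the log-log regression; numerically perfect fits (including a flat
response, where b = 0) report R² = 1. Inverting the model gives the
equivalent dose x = (median/a)^(1/b), and relative sensitivity is
100·(x/actual − 1) percent.

## Synthetic data generator

The generator emulates the *observables* the pipeline consumes, not the
optics: hourly frames of a two-column arena array, each arena holding 0–4
dark elongated objects on a brighter background.

- **Worm shape**: a thickened unit-step random-walk polyline (disks of
  fixed radius stamped along the walk until the painted area reaches
  `worm_area_px`, default 1000 px ≈ a 1 mm adult at 3200 dpi). Postures
  re-randomize every live frame, so bounding-box dimensions vary while area
  stays within a few percent of target.
- **Movement**: each live worm's centroid steps |N(12, 2)| px per frame in
  a uniformly random direction, re-drawn until the step stays inside an
  interior margin (so the commanded magnitude is always realized and blobs
  rarely clip the arena wall). The 12 px mean is well above the 7 px
  movement threshold, and the 2 px spread keeps sub-threshold live steps
  rare (~1%) — the scoring rule is intentionally sensitive to missed
  terminal movements, and a vigorous swimmer is the regime the arenas are
  designed to elicit. The blob is stamped so its *pixel* centroid lands on
  the commanded centroid (±0.5 px rounding), making rendered displacement
  faithful to the commanded step.
- **Death**: times are drawn from a configurable distribution (exponential
  with 40 h mean by default, matching the scale of chronic-stress runs;
  Weibull and fixed lists are available). From the first frame at or past
  the death time, position and posture freeze, so displacement is zero for
  every frame pair whose earlier frame is at or past the death time —
  ground truth is unambiguous against the death rule. Optional
  `fade_after_death` decays the corpse's contrast exponentially
  (the "bagging" phenotype); 0 keeps a permanent rod-like corpse.
- **Artifacts**: static sub-threshold debris (40–200 px) and
  supra-threshold bubbles (400–1200 px), additive Gaussian noise
  (`noise_sd` = 4 gray levels; the true noise statistics of the scanner are
  uncharacterized, so Gaussian is assumed), and global frameshift events —
  whole-frame integer translations that persist cumulatively from their
  frame onward, recorded per frame in the ground truth.
- **Occupancy** defaults to the loading statistics observed on real chips
  (~38.8% empty, 50.5% single, 9.2% double, 1.2% triple, 0.3% with 4+
  objects).

Everything derives from a single seed through spawned substreams; identical
configs give bit-identical stacks and ground truth.

**What it does not emulate** — and hence what passing tests do not show
about real data: pillar arrays and other arena structure, the scanner's
exposure gradient and optical blur, worm self-occlusion and body-shape
dynamics (coiling, thrashing frequency), progeny, and gradual debris
accumulation. Tests on synthetic stacks validate the measurement chain
(segmentation → detection → matching → counting → death call → survival
statistics), not the biology of movement cessation.

## Problem sizes used by the test and acceptance suites

The end-to-end recovery property runs a 50-arena, 72-frame stack (one worm
per arena, exponential 40 h deaths, movement mean 12 px, seed fixed, no
artifacts), once clean, once with two consecutive frameshift events at
hours 60/61 with compensation on, and once with compensation off. One worm
per arena makes every arena yield a death call, so the ±1 h recovery
fraction scores the full chain with maximal resolution. Two consecutive
shift events are used because a single event produces a one-frame movement
blip that the `confirm_m` = 2 guard already discards — only a sustained
disturbance distinguishes compensation from the confirmation guard.
Smaller fixtures (6-arena arrays, ~20 frames) cover alignment invariance,
exclusions, QC, CLI chaining and determinism.

## Numerical and I/O choices

- Coordinates are 0-based (row, col), origin top-left, everywhere.
- Rectangles are half-open pixel intervals; grids tile exactly, remainder
  pixels going to the last cells deterministically.
- Alignment estimates a rigid (optionally similarity) transform by 2-D
  orthogonal Procrustes; full affine is rejected to avoid shear artifacts
  in thin filter channels. Warping is bilinear with the median border
  intensity as fill, so frame edges do not spawn spurious dark objects.
- Timestamp precedence when loading: sidecar CSV > filename pattern
  (`t<hours>h` or ISO-8601) > TIFF `DateTime` tag.
- Automatic QC flags an arena-frame whose mean intensity deviates from the
  arena's series median by more than `auto_qc_sd` = 5 robust standard
  deviations (1.4826 × MAD, so the fault cannot inflate its own scale
  estimate) *and* by more than 5% of the median intensity — acquisition
  faults change brightness grossly, whereas a worm shifting posture
  perturbs the arena mean by well under a percent and must not trip QC.
  Flagged frames (and user-specified time windows) are spliced out of the
  arena's series before death calling.
- Output formatting is fixed (hours to 1 decimal, fractions to 3 decimals)
  so identical runs produce byte-identical files; the run manifest records
  config, input checksums, stage counts and output checksums.

## Known limitations

- **Hourly quantization**: death calls land on the first scan after the
  true death; resolution is one frame interval.
- **Terminal-window censoring**: deaths in the last `quiescent_h` hours of
  a recording are reported as censored, by construction of the rule.
- **Multi-occupancy arenas**: when a live worm overlaps a dead one, the
  merged object's centroid moves roughly half the live displacement and
  can fall under the 7 px threshold, producing a premature arena-level
  death call. This is intrinsic to arena-level scoring of unmatched
  individuals; such calls are flagged `multi_occupancy` for optional
  exclusion.
- **Never-moving objects**: an arena whose only resident object never
  moves (e.g. a lone bubble misread as occupancy 1) scores "dead" at the
  first timepoint, as the rule implies; occupancy-window QC and the 4+
  exclusion catch most, not all, such cases.
- **Individual identity** is not tracked within multi-worm arenas, and no
  pose or behavior classification is attempted.
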