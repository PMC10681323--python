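# Methods

## Data model and pre-processing

The atomic record is a detection: one timestamped reception of a tag's
coded transmission by a receiver. Raw exports carry UTC timestamps and
receiver/transmitter codes (`VR2W-123456`, `A69-1602-28955`); the
token after the final hyphen is the serial / tag id, and the column
layout is configurable (`DetectionDialect`) for other download
dialects.

Pre-processing runs in a fixed order:

1. **De-duplication.** Identical rows (same tag, serial, timestamp)
   are dropped with a logged count — receiver downloads can overlap.
2. **Station resolution.** Receivers move between stations; each
   serial is resolved against a deployment calendar of date intervals
   (inclusive at both ends, non-overlap enforced per serial and per
   station). Detections with no covering interval are dropped and
   counted, never silently kept.
3. **Local time.** Timestamps are shifted by a fixed UTC offset
   (default −5 h; the Cayman Islands observe no daylight saving). A
   fixed shift preserves per-tag detection order.
4. **Station exclusion.** Stations whose receivers accumulated fewer
   than `min_station_months × 30` working days (default six months)
   are excluded, and their detections dropped.
5. **Single-detection filter.** A tag heard exactly once array-wide on
   a local calendar day is removed as a likely false detection. The
   rule is per tag per day, array-wide — the minimal reading that
   removes exactly those detections which can never contribute to a
   detection day (which requires two or more detections). The filter
   is idempotent.

## Residency

`RI = detection days / monitoring period`. The monitoring period is
the tag's expected battery life, truncated at the study end when the
battery outlives the study — a deliberately conservative denominator: a
shark that died or left early looks less resident than under a
last-detection denominator.

The classifier orders its rules as: ≥ 3 detection months → Resident
when presence (detection days / detection period × 100) is ≥ the 30%
threshold, else Pseudo-resident; otherwise any detection after the
first 30-day block → Transient; otherwise Passer-by. Two edge policies
are choices of this package: presence exactly at the threshold counts
as Resident (the published criteria print "< 30%" and "> 30%",
leaving equality unassigned), and a shark detected beyond the first
block but without a > 30-day silent gap and with < 3 months is
Transient (the published criteria do not cover it, and Transient is
the only category consistent with "detected beyond the first Month,
fewer than three Months"). Sharks with zero detection days are
unclassifiable and reported as absent from the residency analysis;
their RI is likewise absent rather than zero, matching the convention
of computing RI over detected sharks only. "Detection month" is a
calendar month (year + month) holding ≥ 1 detection day; the
classifier's "Month" is a 30-day block from tagging. Both are
implemented and named distinctly.

Cohort summaries impute zeros for never-detected sharks in the
detection-count, detection-day and detection-period means (the tagged
cohort is the denominator), but not for RI.

Summary tables from other studies can be inconsistent (e.g. more
detection months than detection days); `DetectionMetrics.inconsistencies()`
flags such rows instead of reproducing or repairing them.

## Space use

Distances use the haversine formula on a 6371.0 km sphere (the
convention of the calculator the field commonly cites; the radius is
an argument). Against an independent geodesic reference the
three-island centroid distances agree to < 0.01% (sphere) and < 0.2%
(WGS84 ellipsoid).

Station-level detection days require ≥ 2 detections *at that station*
by that shark on the day — the array-wide rule applied at station
grain; the threshold is configurable (`station_day_min_detections`)
because the source formulation does not restate it at station level.
SFI ties are broken by station id for reproducibility. The MLD
endpoint search is exhaustive over station pairs (arrays are tens of
stations; no heuristic needed) and uses post-filter detections.

UI and AI are implemented exactly as printed. Both mix a proportion
with a normalised count, so their absolute magnitudes are not
comparable across studies; only within-study rankings are meaningful,
and the package documents them as ranking indices. The AI's
shark-proportion denominator is read as the total number of detected
sharks over the whole study (so the proportion is ≤ 1 in every month).

## Movement networks

Transitions are successive detections of one shark at two distinct
stations; same-station runs collapse (no self-loops) and no maximum
time gap is imposed by default (a configurable `max_gap` exists,
default off). Subset networks filter detections first and pair within
the subset, so a movement belongs to the subset of its arrival
detection; the alternative (pair first, keep movements whose arrival
is in the subset) is available behind a flag. Season follows the
calendar month (summer April–September); the diel day window
06:30–18:29 is inclusive at minute resolution, so 06:30:00 is day and
18:30:00 is night.

The Mantel statistic is the Pearson correlation of the off-diagonal
entries of the two weighted, directed adjacency matrices — the
matrices are not symmetric distance matrices, which is why the test is
implemented here rather than delegated to a distance-matrix Mantel.
The null permutes rows and columns of one matrix simultaneously;
p = (1 + hits) / (1 + permutations), upper tail by default, 9,999
permutations, seeded. Mobility comparisons run Mann-Whitney on
node-degree vectors restricted to stations with positive degree in at
least one group (shared structural zeros otherwise dominate the
ranks); including all stations is switchable.

## Statistics

Standard tests delegate to scipy behind a uniform `TestResult`
surface: chi-squared goodness of fit, tie-corrected Spearman (both rho
and the mid-rank `S = Σd²` are reported), Mann-Whitney (exact null for
small tie-free samples, tie-corrected normal approximation otherwise;
statistic in the rank-sum `W` convention, with the classical U of the
second sample in `extras`), Kruskal-Wallis (df = k − 1; an all-tied
input returns statistic 0 rather than an error). Dunn's post-hoc Z
comparisons (pooled mid-ranks, tie-corrected, optional Bonferroni;
default unadjusted) and the 2×3 Fisher exact test (Freeman-Halton, by
full enumeration of tables with fixed margins) are implemented
directly, as no installed library provides them. Distributional
pre-screens (normality, homogeneity) are out of scope: the pipeline
always runs the nonparametric branch.

Degenerate inputs are contracts, not surprises: constant vectors are
errors for Spearman, equal-on-all-values samples compare equal (p = 1)
for Mann-Whitney and Kruskal-Wallis, zero-variance matrices are errors
for Mantel, and a zero margin makes Fisher's test degenerate (p = 1).

## Synthetic telemetry

The generator emulates the study conditions rather than idealised
data: stations on island-perimeter circles (three-island preset: 23 +
28 + 8 = 57 stations at the real centroids; minimal preset: one island,
8 stations), 0.3 km detection radius, ~90 s mean transmission
interval (exponential spacing), V9/V16 tag lives assigned by body
length, total lengths uniform on 76–196 cm, receiver outage windows
carving the deployment calendar, and the four behavioural archetypes
in the proportions observed among detected sharks (59% passer-by, 8%
transient, 15% pseudo-resident, 18% resident).

Movement is a daily-resolution station Markov choice: on a present day
the shark is at its home station with probability 0.75, else at a
random same-island station, and remains there for a residence window
(default 1 h) placed wholly inside one local day; transmissions within
the window are detected with probability `detection_prob_in_range`
(default 0.5, a free parameter — the study's true per-transmission
detectability is unknown, so validation uses recovery and relative
properties, never absolute detection counts). A present day therefore
yields a detection-day with probability `1 − e^(−μ)(1 + μ)`,
μ = window/delay × p, giving the closed-form RI used as a recovery
oracle. Daily resolution suffices because every downstream metric is
computed at day grain; continuous within-day positions exist only as
the residence window.

Archetype construction: residents and pseudo-residents draw a daily
presence probability (defaults U(0.4, 0.7) and U(0.06, 0.15));
passers-by are present only before a departure day ≤ 30; transients
are present in two short bursts confined to two calendar months
separated by > 30 silent days, so their detection-month count stays
below three by construction. Inter-island excursions are single-day
relocations with separate summer and winter daily rates (defaults 0.01
and 0 — the study system's inter-island movements were summer-only,
which no finite multiplier over a common base rate can express). An
optional summer presence multiplier forces seasonal activity for
testing the Activity Index.

What the generator does *not* emulate — continuous trajectories,
depth, sound-propagation variability, tag loss and mortality,
collisions between tag transmissions — bounds what passing tests show:
they validate the metric arithmetic, the classifier logic and the
pipeline plumbing under the stated behavioural model, not the field
detectability of real arrays.

## Problem sizes and determinism

Every stochastic procedure takes an explicit seed (numpy Generator);
simulation outputs and pipeline runs are reproducible to the byte.
The test suite validates against: the published 39-shark summary table
(exact arithmetic), exhaustive enumeration oracles (Mantel at n = 3,
Mann-Whitney at n = 2 + 2, Kruskal-Wallis at 3 × 2, Fisher 2×3),
frozen external references (R geosphere distances, R fisher.test
p-values), null calibrations at 200–400 replicates, and archetype
recovery over 200 simulated sharks on an 8-station, 400-day scenario
(~260k detections, a few seconds). These sizes keep the full suite
under a minute of simulation time while leaving recovery rates at
100% against the ≥ 75% acceptance bar.

## Known limitations

- The single-detection filter cannot distinguish a genuine brief pass
  from a false detection; the study's own convention is adopted.
- UI/AI magnitudes are not cross-study comparable (dimensionally mixed
  as printed); only rankings are reported.
- The classifier inherits the summary-table granularity when driven
  from published tables: transient vs passer-by needs day-level data.
- MLD is a lower bound on range (straight-line between stations and
  detection-radius padding only).
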