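# Methods

## Model and assumptions

`vespalocate` localizes the nest of a central-place forager from repeated
provisioning trips observed at fixed bait stations. Two measurements per
trip carry all the information used: the compass bearing along which the
departing hornet vanishes, and the elapsed bait–nest–bait time. The model
assumes

* straight, symmetric flight legs — outbound and return cover the same
  distance, so the flight portion of the round trip divides by two;
* a fixed nest-handling time `t_n` per visit (default 45 s), independent of
  distance;
* a true flight speed bracketed by `s_min = 1.8 m/s` (field-measured loaded
  flight, mean of a 30-flight sample with SD 0.32) and `s_max = 5.4 m/s`
  (the literature maximum for homing hornets). The wide bracket is the
  model's only uncertainty mechanism for distance: no variance for `t_n`
  is propagated, and the deliberately high `s_max` errs toward enlarging
  the search area rather than missing the nest;
* the vanishing bearing as an unbiased but noisy proxy for the true nest
  bearing, with deviation growing with distance — hence the two-regime
  sector half-angle (±10° under 10 min round-trip, ±15° over).

Estimation is strictly per individual. In high-density areas a single bait
feeds workers from several nests; pooling times or bearings across
individuals would average over different nests and is never done. An
individual enters the analysis only with `min_trips >= 3` round trips, and
the *shortest* trip is used: longer trips contain detours or queueing, so
the minimum best approximates the direct route the speed bracket assumes.

## Tunable parameters

| parameter | unit | default | role |
|---|---|---|---|
| `t_nest_s` | s | 45 | handling time subtracted from the round trip |
| `s_min` / `s_max` | m/s | 1.8 / 5.4 | distance-band bracket (ratio fixes `D_max/D_min = 3`) |
| `angle_short_deg` / `angle_long_deg` | deg | 10 / 15 | sector half-angles |
| `trip_time_threshold_s` | s | 600 | short/long regime boundary |
| `min_trips` | — | 3 | usability screen |
| `arc_step` | deg/vertex | 1 | polygon arc discretisation |
| `margin` | m | 50 | second-station placement distance |

All are exposed via CLI flags and the config file; the defaults are the
field-protocol values and should only change with new field calibration.

## Numerical choices

* **Local frame.** Geographic inputs are projected onto a local tangent
  plane centred on the bait-station centroid, scaled with the WGS84
  meridian and prime-vertical radii of curvature at the origin. At the
  method's sub-3-km scale this agrees with true WGS84 geodesics to well
  under 0.1% (verified against `geosphere::distGeo` reference values in the
  tests), is exactly invertible, and is numerically indistinguishable from
  an azimuthal equidistant projection while staying linear. Points more
  than 50 km from the origin are rejected as probable coordinate mix-ups.
* **Bearings** are compass bearings, degrees clockwise from true north,
  normalised to [0, 360). Whether field compasses read magnetic or true
  north is an input-data property; no declination correction is applied,
  and users of magnetic readings must correct upstream. Mean vanishing
  directions are circular (unit-vector) means — arithmetic means of degree
  values fail across the 0/360 wrap. A resultant vector shorter than 1e-9
  (antipodal bearings) raises a degenerate-direction error instead of
  returning an arbitrary angle.
* **Sector-annulus polygons** are built with one vertex per `arc_step`
  degrees of arc (default 1°), counter-clockwise, giving an area within
  ~0.005% of the closed form `(2α/360)·π·(D_max² − D_min²)` — negligible
  against the 3× speed bracket. Containment tests use a boundary tolerance
  of 1.05× the chord sagitta so points on the true (un-discretised) arcs
  count as inside.
* **Tie-breaks.** A round trip of exactly 10 min takes the wide 15°
  half-angle: the regime rule only specifies strictly-shorter and
  strictly-longer, and widening is the conservative direction (a larger
  search area can cost time but cannot lose the nest). A trip no longer
  than `t_n` raises an infeasible-trip error rather than producing a
  zero-radius band: it indicates a mistimed observation or confused
  identity, not a nest at the bait.
* **Convergence.** Fully formed sector-annuli are intersected (the
  operation is associative, so clipping order is immaterial). The tool
  reports every pairwise cross-station intersection and, with more than two
  regions, the full intersection as well, because individuals at one bait
  may come from different nests — blanket intersection alone could be
  empty while a pairwise one is the real nest area. An empty intersection
  is a reported outcome with a remedy (re-run with the wide half-angle),
  never a crash.
* **Second-station placement** goes just outside the likely area (hornets
  avoid protein baits near their nest): on the mean-bearing axis beyond
  the region's farthest vertex, at 1.5× the margin from the boundary,
  deterministically.

## Synthetic data

The simulator emulates the structure of field campaigns: repeated round
trips per marked individual with bearing scatter and trip-time variation.
Per trip it draws outbound and return speeds independently (load differs
between legs) from a truncated normal on `[s_min, s_max]` — default mean
2.7 m/s, the field-estimated maximum flight speed, taken as a central
loaded-flight speed between the bracketing constants; sd 0.5 m/s — a
handling time from a truncated normal (45 s mean, 10 s sd, 5 s floor,
the sd being a package choice since only the 45 s mean was measured), and
a bearing error `N(0, 3°)`, so the 10° half-angle covers roughly 3σ of
short-trip scatter. Rows are shuffled deterministically by the seed to
emulate interleaved observation; replicate *r* of an experiment reruns the
scenario with `seed + r`.

What it does **not** emulate: flight-path tortuosity (simulated times are
straight-line optimistic), wind and rain (the field protocol avoids them),
bait avoidance in the nest's immediate vicinity, vertical structure (the
geometry is strictly 2-D; real nests sit tens of metres up a tree), and
multi-nest interference beyond per-individual identity. Passing recovery
tests therefore demonstrate the estimator's internal consistency and the
correctness of the geometry — not field-accuracy guarantees.

The reference validation scenario places the nest 400 m north of station
BS1 with a second station at (300, 150) m, one marked individual per
station and four trips each; the recovery experiment runs 200 replicates
(a few seconds of CPU). In the noise-free limit — speeds strictly inside
`(s_min, s_max)`, handling fixed at `t_n`, zero bearing scatter —
containment of the true nest is mathematically guaranteed and the tests
require exactly 1.0.

## Known limitations

* Strictly 2-D; no terrain, visibility or canopy-height modelling.
* `t_n` and the speed bracket are constants, not estimated from the data.
* No posterior density over nest location — the output is a hard polygon,
  matching how the field protocol draws lines on a map.
* The reader expects the documented CSV schema; externally deposited
  datasets with other layouts must be mapped to it by the user
  (`station_id, hornet_id, bearing_deg, round_trip_s` or timestamp pair).
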