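# Methods

## The tracking procedure

`firetrack` treats a fire event as an *object* accumulating detections
over time, rather than as a set of independent pixel flags. The state of
a region at a half-daily step is an `AllFires` collection of `FireObject`
records; each step applies, in order: projection of the new detections to
an equal-area plane, single-linkage clustering, cluster-to-fire
assignment, perimeter/fireline recomputation for changed fires,
transitive merging, static-source screening, the activity countdown, and
attribute refresh. Every rule is deterministic; two runs on identical
inputs produce byte-identical outputs, and the per-step JSON state file
restores the exact state, so a season can be checkpointed and resumed
anywhere with identical downstream products.

Key assumptions inherited from the observation process:

- **Half-daily clock.** The sensor passes ~1:30 am/pm local time, so the
  system's native time unit is the half-day. Days are split into AM
  [00:00, 12:00) and PM [12:00, 24:00) windows in *local solar time*,
  computed from UTC with a fixed configured offset (no daylight saving) —
  a symmetric split around the overpasses that keeps partitioning
  deterministic. Window boundaries are closed on the left.
- **Type-dependent reach.** New clusters attach to an active fire when
  their shortest pixel-to-perimeter distance is within the fire's
  extended-area buffer — 5 km for forest fires, 1 km for all other types
  — reflecting faster spread in forest fuels. The distance is measured
  from the cluster's pixel points to the fire's perimeter polygon (the
  cluster side has no perimeter of its own yet); ties between equidistant
  fires go to the lower id, mirroring the merge convention.
- **Five-day memory.** A fire with no new pixels for more than 5 days
  (strictly more than 10 half-daily steps) becomes inactive and is never
  reactivated; later detections nearby found new objects.

## Geometry

All metre thresholds and km² areas are evaluated in a single equal-area
plane: an Albers equal-area conic on the authalic sphere (radius
6 371 007.181 m), standard parallels 34°/40.5° and central meridian
−120° by default (configurable per region). The spherical form is exactly
area-preserving, has a closed-form inverse (round-trip < 1e-9°), and at
the sub-100 km scales of individual fires distorts distances by well
under 1 %. Geometries are written to disk in WGS84 longitude/latitude;
the metre plane is internal.

The perimeter of a fire with ≥ 4 pixels is the **alpha shape** of its
pixel locations: the union of Delaunay triangles whose circumradius is at
most α (the radius of the carving disks), α = 1 km by default — large
enough to keep one event in one polygon across 375 m pixel spacing and
half-day gaps, small enough to trace concave boundaries. The hull is
buffered outward by 187.5 m (half the nadir pixel width, round joins) to
account for the detection footprint. Degenerate counts fall back:
3 pixels → buffered convex hull; 1–2 pixels → 187.5 m discs. Collinear
≥ 4-point sets, and point sets where no triangle survives the
circumradius cut, use the convex-hull and per-pixel-disc fallbacks
respectively; any isolated pixel left outside the buffered shape is
covered by adding its disc, so the perimeter always contains every
detection. Discs use 256 segments per quarter circle (area accurate to
~6e-6 relative); buffered hulls use 32.

The **active fireline** is the intersection of the hull boundary with the
500 m-radius neighbourhood of the step's new pixels — a linestring,
multi-linestring, or the full boundary ring when new detections surround
the perimeter. It is a per-step quantity: on a step with no new pixels
the fireline is empty.

## Attributes

The dominant land cover (`LCTmax`) is the modal 7-class value
(water/urban/barren/forest/shrub/grassland/agriculture) over cells whose
centres fall inside the perimeter, recomputed each step as the fire
grows; hulls too small to capture a centre use the class at the hull
centroid. The 1000-hr dead fuel moisture (`stFM1000`, percent) is sampled
once, at the ignition-pixel centroid at the ignition step, and kept. Fire
type combines the two: forest with FM-1000 ≥ 12 % is *forest wildfire*,
below 12 % *forest management fire*; shrub/grassland split the same way;
agriculture, urban, and water/barren map unconditionally. The 12 %
boundary is closed on the wildfire side. Note an internal tension in the
source material for this rule: the descriptive claim is that prescribed
burns happen under *higher* coarse-fuel moisture, while the operational
table assigns the moist side to wildfire. The classification table is
implemented as printed; both the threshold value and its direction are
exposed in `TrackerConfig` for users who want the opposite convention.

Rasters are single-band regular grids georeferenced in the projected
metre plane and stored as Esri ASCII grids (plain text). Merging a
30 m national land-cover product into the 7-class legend is data
preparation outside the package's scope; the tracker consumes the merged
grid.

## Validation metrics

Burned/unburned agreement inside a region is summarised by a confusion
matrix of areas: TP = pred ∩ ref, FP = pred \ ref, FN = ref \ pred,
TN = region − (TP+FP+FN); the four cells sum to the region area to
clipping tolerance. Derived scores: ratio = (FP+TP)/(FN+TP), accuracy =
(TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN), IoU =
TP/(TP+FP+FN), F1 = harmonic mean of precision and recall; zero
denominators yield "missing", not an exception. Per-fire scoring matches
each reference fire to every tracked fire it spatially overlaps and
scores the *union* of the matched tracked fires against it (one reference
fire frequently corresponds to several tracked objects); means are
reported with the population (divide-by-*n*) standard deviation.
Per-fire accuracy is not reported: without a per-fire background region
TN is undefined.

## The synthetic-data generator

The simulator emulates the *observation process*, not fire physics. A
fire's true footprint grows as an ellipse centred on the ignition point
with semi-axes k·rate_along × k·rate_cross at step k, oriented by a wind
direction — closed-form areas make downstream checks exact. Detections
are sampled by laying a 375 m grid (the nadir detection spacing) over the
newly burned ring of each step, keeping each node with the detection
probability, adding Gaussian positional jitter, lognormal FRP, and the
step's overpass timestamp. Static industrial sources emit 1–3 detections
per step at a fixed point with ~50 m jitter. All randomness flows from a
single seeded generator per scenario.

Canonical scenarios (used by the test suite and the acceptance script)
fix the study conditions: 12 half-daily steps (6 days), spread rates
500 × 250 m per half-day, detection probability 0.95, jitter σ = 40 m,
uniform forest land cover with mean FM-1000 of 15 % — a moist-season
forest wildfire of ~57 km², comfortably above the 4 km² large-fire
threshold. The **merge scenario** places two such fires 12 km apart on a
shared axis: beyond the 5 km forest buffer at ignition, so each forms its
own object, and closing below it mid-run, so the later fire is absorbed
with a heritage record. Two simultaneous ignitions only 1 km apart are
instead aggregated at the clustering stage (linkage 1 km) into a single
object from the first step — one valid fire, but no heritage record; both
behaviours are asserted. In the **static scenario**, because invalid
fires no longer attract pixels, a flagged hotspot re-forms as a fresh
object at the next overpass and each incarnation is flagged once dense
enough; at season end a remnant younger than a day may still be valid.
Tests therefore assert the source was flagged and the spreading fire
untouched, not a fixed object count.

What the simulator does *not* emulate — and hence what passing tests do
not establish about real data: cloud/smoke obscuration gaps longer than
one overpass, scan-angle-dependent pixel growth (up to ~470 m mean across
the swath; the hull buffer is fixed at the nadir half-width), false
alarms away from fires, irregular (non-elliptical) spread, and
re-ignition within an old scar.

## Numerical and design choices

- Alpha-shape convention: α is the disk radius; triangles are kept when
  circumradius ≤ α (the standard alpha-complex criterion matching the
  disk picture).
- Cluster linkage default 1 km: equal to the smallest extended-area
  buffer; over-splitting within a step is self-healing because the split
  parts merge immediately.
- Merge scan: pairs of active fires in ascending id order, restarting
  after every merge until a fixpoint, so chains (9→5, 5→2) resolve within
  one step and all pixels end in the lowest id; a pair merges when either
  perimeter reaches the other's extended area (the larger of the two
  buffers).
- New fire ids are issued sequentially in cluster order, clusters ordered
  by the record order of their first pixel — reproducibility over
  aesthetics.
- Pixel conservation is an invariant: merging *moves* pixel objects,
  never copies or drops them, so the multiset union over all fires
  (valid and invalid) equals the ingested stream.
- Serialization is a versioned JSON document (geometry as WKT) rather
  than a language-native pickle: the contract is lossless, portable state
  round-trip.
- Snapshot/large-fire layers are GeoJSON FeatureCollections (one file per
  layer, named by the `YYYYMMDDAP` step pattern) sharing the `fid` key;
  the summary series is NetCDF3 (scipy backend) plus CSVs.
- Problem sizes in the default test run and acceptance script: scenarios
  of ~390–750 detections over 12 steps, geometry oracles on 200 random
  ≤ 25-point sets — each configuration completes in seconds while
  exercising every rule of the system.

## Known limitations

- The tracker is single-region, in-memory; a continental run would need
  spatial tiling and out-of-core state.
- Fires are never re-split: a spurious merge (e.g. two fires bridged by a
  bad detection) is permanent, as is pixel assignment.
- The fixed 187.5 m buffer under-represents off-nadir pixel footprints.
- Per-fire validation uses union-of-matched-objects; alternatives (score
  each object separately) would give different per-fire spreads.
- The static-fire rule is density-based and can momentarily spare a
  freshly re-formed hotspot (see above); a location blacklist would catch
  these at the cost of a second pass.
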