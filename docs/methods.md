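# Methods

`skatemark` re-implements, as a tested pipeline, a community-science analysis
of flapper skate (*Dipturus intermedius*) capture records around an island
coastline: curation of angler-submitted capture/recapture records from two
programmes, detection of capture hotspots on an equal-area hexagonal grid,
and per-individual dispersal distances that respect the coastline.  The real
Irish datasets are available only on request, so the package ships a
synthetic-data generator with known ground truth; every stage is exercised
and validated on generated data.

## Record model and curation rules

Records arrive in two CSV dialects mirroring the two programmes' forms: a
tagging-logbook dialect (up to three tag ids per animal, a length unit flag
because some anglers reported inches, converted at exactly 2.54 cm/inch) and
a specimen-claim dialect (no tags, lengths in cm).  Missing values are blank
cells on disk and `None` in memory; no sentinel numbers.  Dates in the source
dialects are day-first; the canonical output dialect is ISO-8601.  Rows are
never silently dropped: unparseable dates/lengths leave the field absent with
a warning attached to the record, and a row with neither coordinates nor a
resolvable port is emitted flagged unresolvable.

Location provenance is explicit: `exact` (angler gave a position),
`port_proxy` (angler chose to name a port), `standard_list` (digitisation
assigned a position from the programme's coordinate list).  Resolution is
idempotent and never overwrites exact coordinates.  Each programme has its
own port table; the two tables were built independently in reality and need
not agree, which the generator reproduces by jittering half the claim-scheme
entries.

Curation applies, in order:

- **Cross-programme deduplication.**  A specimen claim matching a tagging
  record on exact date, total length within 0.5 cm and position within 1 km
  is removed; the tagging copy is retained.  The originating programmes
  resolved such pairs by manual review; the pipeline replaces that with the
  explicit tolerances above and an ambiguity flag (one claim matching several
  records, or several claims matching one record) for follow-up.
- **Species length filter.**  Within the common skate complex, total length
  >= 160 cm identifies flapper skate.  A *history* is retained iff any of its
  events reaches 160 cm — so an individual measured at 147 cm and recaptured
  above the threshold stays, with both events.  Absent lengths never satisfy
  the criterion.
- **Sex reconciliation.**  Sex reported on some events and missing on others
  is trusted; any male/female conflict within a history makes the individual
  unknown and excludes it from sex-specific analyses.  The result is
  invariant to event order.
- **Maturity.**  Length-based: males mature at >= 165 cm, females at
  >= 203 cm; unknown sex or absent length is unclassified.  Maturity is
  classified per event (an individual can be immature at capture and mature
  at recapture); per-individual maturity, where needed, uses the largest
  recorded length.
- **Coast sectors and territorial seas.**  The coastline is partitioned into
  named arcs between ordered landmark points; a record belongs to the sector
  whose arc is nearest, with exact ties going to the earlier-declared sector.
  "Within territorial seas" means at most 12 NM (22.224 km) from the nearest
  coastline point — a descriptive rule, not legal baselines.

## Histories and time at liberty

Records sharing any tag id are linked into one history by transitive closure
(animals carry one to three tags, and a record listing tags {A, B} bridges
records listing only {A} or only {B}).  Claims without tags are singleton
histories.  Linkage is independent of input order.  Days at liberty are
whole-day differences between successive dated events; a same-day recapture
is a valid 0-day interval; undated events are kept for spatial counts but
excluded from intervals.  Years are days / 365.25 rounded half-up to one
decimal.  Tag shedding makes linkage undercount recaptures; the pipeline
does not attempt re-identification, but the generator can simulate shedding
so the direction and size of the bias can be measured (see below).

## Hexagonal hotspot grid

Capture positions are port-accurate at best, so occurrence is aggregated to
50 km^2 flat-topped regular hexagons (circumradius
R = sqrt(2A / (3 sqrt 3)) ≈ 4.387 km for A = 50 km^2).  All planar work uses
one Lambert azimuthal equal-area projection on a sphere of radius
6371.0088 km, centred on the study extent: equal-area is what makes
"50 km^2 cells" meaningful, and the azimuthal form keeps local distance
distortion negligible at study-area scales.  The grid is anchored at the
lower-left corner of the projected extent, so cell ids and vertices are
reproducible across runs.

Because regular hexagons are the Voronoi cells of their centres, a point is
binned to its nearest centre; near-ties (points on shared edges) go to the
smallest cell id, giving each hexagon a deterministic half-open boundary and
exact count conservation.  Cells holding more than 10% of a stratum's events
are hotspots; 5%-10% inclusive is an "area of interest" (exactly 10% is AOI,
not hotspot; exactly 5% is AOI).  Strata are the three timeframes (all
records; year <= 2006 "older"; year >= 2007 "recent", with undated records
only in "all") crossed with event subsets (all, mature, mature by sex).

The absolute per-cell counts of the original analysis depend on a grid
origin and orientation that are not recoverable, so per-cell counts are not
comparable across implementations even on identical data; classifications
and fractions are.

## Dispersal distances

For each successive pair of dated, located events of one individual the
displacement is:

- the great-circle (haversine, R = 6371.0088 km) distance when the straight
  projected track does not enter land — endpoints touching the coastline do
  not count as crossing;
- otherwise the shortest path through a water-only network: a regular
  triangular lattice (default triangle area 0.3 km^2, edge
  s = sqrt(4T / sqrt 3) ≈ 0.832 km) laid over the projected extent, with
  every edge overlapping the land interior erased and isolated nodes
  dropped.  Endpoints snap to the nearest surviving node; the two snap
  offsets are added to the path length, and an endpoint farther than two
  edge lengths from any node is an error rather than a silent bridge over
  land.  Paths use uniform-cost search with lexicographic node-id
  tie-breaking, so distances *and* node paths are reproducible; the suite
  checks distances against an independent exhaustive-relaxation oracle.

On an open-water lattice the worst-case detour of a lattice path over the
straight line is 2/sqrt(3) ≈ 1.155, which bounds the discretisation error;
halving the triangle area can only shorten marine distances up to snap
slack.  Marine distance is never below the great-circle distance.

## Synthetic data generator

The generator emulates the statistical structure of the two record sources
so recovery can be tested against known truth.  Defaults (chosen once, as
the study conditions):

- ~1000 individuals over 1972-2021; 60% female; truncated-normal total
  lengths (males 182 ± 12 cm on [150, 215], females 205 ± 25 cm on
  [150, 260]) so most males classify mature and roughly half the females do;
  growth at 2 cm/year between captures (which produces occasional
  below-threshold first captures later legitimised by the species filter's
  growth exception).
- Capture locations from a mixture of three coastal hotspots (weights 0.36,
  0.19, 0.14 — mirroring the observed hotspot shares — Gaussian spread
  2.5 km, centres a few km offshore) plus a diffuse uniform-in-water
  remainder; rejection-sampled so every true position is wet and in extent.
- Month weights put 80% of captures in June-October with a 20% July peak.
- A 10% recapture process (geometric continuation), displacement from an
  exponential kernel (mean 10 km) with a 2% uniform long-range tail to
  180 km — mimicking the observed "93% under 50 km, maximum 171 km"
  pattern — and lognormal days at liberty (mu 5.88, sigma 0.89: mean
  ≈ 530 d).  Displacement bearings are resampled until the endpoint is in
  water, preserving the planted distance.
- Corruptions, each applied after truth is recorded: coordinates snapped to
  the nearest port with probability 0.5; sex blanked (0.30) or flipped on a
  recapture (0.02); tags shed on recapture (0 by default, configurable); 5%
  of tagging events duplicated into the claim dialect (exercising
  deduplication) plus standalone claims at 25% of the individual count; 5%
  of logbook lengths written in inches with the unit flag.

Coastlines are a circle island, a Fourier-perturbed island, or two disjoint
islands; ports sit on the coastline; 4-6 sector landmarks are evenly spaced
coastline points.  Everything is driven by one seeded `numpy` generator, so
a seed fixes the dataset bit-for-bit.

What the generator does *not* emulate: real coastline geometry, depth or
habitat preference, temporally varying effort (taggers are drawn uniformly,
so effort concentration in real data is stronger than generated), weight
fields, and inter-annual trends.  Passing recovery tests therefore shows the
pipeline recovers planted structure under the stated noise model, not that
the original data would yield the same maps.

## Recovery experiments and problem sizes

Three experiments quantify end-to-end behaviour (run both in the test suite
and by `scripts/acceptance.py`):

- **Planted hotspots.**  Three spots of weight 0.30 each, spread 1 km,
  planted exactly at water cell centres >= 30 km apart, 1000 records, no
  snapping: classification recovers exactly those cells (precision = recall
  = 1) over 20 seeds.  With port snapping on, detected hotspots move into
  port cells — a faithful reproduction of what port aggregation does to real
  data.
- **Kernel mean.**  ~2000 intervals at kernel mean 10 km, tail and snapping
  off: the measured mean dispersal distance falls within 3 standard errors
  of 10 km.
- **Shedding bias.**  Tag shedding at 0.5 strictly lowers the estimated
  recapture rate below the true rate in 20 of 20 seeds, the direction
  expected when shed tags masquerade recaptured animals as new individuals.

Sizes used throughout (1000-2000 individuals, 20 seeds, 0.3-2 km^2
triangles for the networks involved) were chosen so each suite completes in
seconds while keeping Monte-Carlo standard errors well inside the asserted
bounds.

## Numerical choices and degenerate inputs

- One rounding rule for every reported share: half-up at the printed
  precision (integer percentages; one decimal for year/km means), via
  `decimal.Decimal`.
- "Same port" for the dispersal summary means identical resolved
  coordinates (distance exactly 0), consistent with port-proxy aggregation.
- The share of individuals dispersing under 50 km uses each individual's
  maximum interval distance, not the mean.
- The recapture-rate denominator is the number of unique individuals in the
  tagging-programme subset, reported alongside the rate.
- Zero-denominator percentages raise; a zero-event stratum classifies all
  cells background with a warning; an empty water region, an empty sector
  list and a degenerate extent raise immediately.
- Geometry tolerances: 1e-9 km slack on nearest-centre ties and edge-erasure
  overlap; floating-point round-trips through the projection are exact to
  well below these scales.

## Known limitations

- Marine distances inherit lattice discretisation (bounded by the 1.155
  detour factor plus snap slack); the default 0.3 km^2 triangles make this
  error small relative to port-level position accuracy, which dominates.
- Histories cannot see through shed tags (quantified, not corrected).
- The 12 NM rule uses nearest-coastline distance, not legal baselines.
- Sector assignment presumes landmarks lie on (or near) one coastline ring;
  multi-island coastlines take sectors from the ring nearest the landmarks.
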