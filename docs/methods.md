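# Methods

## Model overview and assumptions

The simulator treats each migrating *Spodoptera frugiperda* adult as a
Lagrangian particle in hourly gridded meteorology. Horizontal motion is pure
advection plus a fixed self-propulsion airspeed aligned with the local wind
("leeward" flight); vertical motion combines resolved vertical velocity,
turbulent diffusion as a random walk, a drift term proportional to the
vertical gradient of the diffusivity, and a fixed climb during the
post-take-off ascent phase. The moth makes no navigational decisions: no
crosswind orientation (crab angle), no selection of fast wind levels, no
landing. These are deliberate first-approximation choices; orientation and
height selection are documented extension points, not features.

The vertical coordinate is terrain-following,
z\* = (z − z_g)·z_t/(z_t − z_g), which lets one set of levels span the whole
domain. All vertical physics (diffusion, ascent, ceiling) operates in z\*;
geometric height is only needed for reporting.

## Flight parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `flight_speed` | 3.0 | m/s | self-propulsion along the local wind; zero in calm air (heading undefined) |
| `ascent_speed` (w_c\*) | 0.75 | m/s | dusk climb rate, anchored by radar observations of moths reaching ~1350 m about 1800 s after take-off |
| `ascent_end_s` | 3600 | s | ascent window measured from the *release start*, not per moth: a release at 10:00 UTC means all climbing stops at 11:00 UTC, so late take-offs ascend for less time |
| `temp_min_c` | 13.0 | degC | wing-beat (flight ceiling) temperature |
| `dt_s` | 120 | s | integration step; must divide one hour |
| `horizon_h` | 48 | h | forecast horizon (long crossings to northern Japan need ~48 h) |
| release | 500 moths/source over 3600 s | | constant temporal rate, even spacing; positions uniform over the source polygon; take-off from the ground (z\* = 0) |
| detection radius | 18 | km | trap arrival rule, checked at every step |

The random-walk term is written sqrt(24·Kz\*·dt)·R with R uniform on
[−0.5, 0.5]. Var(R) = 1/12, so the step variance is exactly 2·Kz\*·dt, the
standard Lagrangian diffusion rate; together with the dKz\*/dz\* drift this
passes the well-mixed test (below).

## Boundary rules

* **Temperature ceiling** — the vertical component of a step whose candidate
  end point sits in air at T ≤ 13.0 degC is cancelled; the horizontal
  component is kept. Moths are barred from *entering* cold air but keep
  flying below it; they are neither deactivated nor pinned to the isotherm.
* **Ground** — reflective (z\* < 0 becomes −z\*). No landing process is
  modelled; moths fly for the whole horizon.
* **Top** — reflective about the highest met level. Reflection (rather than
  clamping) is required for the diffusion scheme to preserve a well-mixed
  vertical distribution; in realistic scenarios the temperature ceiling
  keeps moths kilometres below the model top, so the choice only matters in
  verification runs that fill the whole column.
* **Horizontal domain exit** — the moth is deactivated at its last valid
  position and never moves again.

Metre-to-degree conversion uses fixed constants (110,540 m per degree
latitude, 111,320·cos(lat) m per degree longitude). All distances that
matter for arrival use the haversine with Earth radius 6371 km, so the
tangent-plane approximation only affects individual 120 s steps (< 0.2 %).

## Evaluation protocol

Each trap-day is classified:

* **positive case** (prediction "yes" with flight time FT): the predicted
  arrival instant is the previous evening's 10:00 UTC take-off (19:00 JST)
  plus FT hours. The evaluation window of L ∈ {3, 5} consecutive days starts
  on the arrival's JST date when the arrival is before 12:00 JST, otherwise
  on the next date — a moth arriving in the afternoon cannot reach a lure
  before the following collection morning. Hit iff any day in the window has
  a recorded catch; windows truncated by the end of the data are evaluated
  on the available days; a window with no data at all is unevaluable.
* **negative case** (no prediction): hit iff the date has no recorded catch,
  judged on that single day. Days within [p, p + L − 1] of any positive
  prediction row p are excluded — immigrants from that predicted arrival
  could still be trapped, which would bias the negative score. Days not
  covered by any collection are likewise excluded.
* **hitting ratio** = hits / (hits + fails), rounded half-up to two
  decimals; yearly and overall summaries are plain means of the per-site
  rounded ratios (half-up rounding is what makes a mean of 0.765 report as
  0.77).

Collections are daily or at 2–5-day intervals. A catch is recorded *on its
collection date*; a zero count certifies every day of its interval as
catch-free; interval coverage of either sign marks days as "has data". This
date-of-collection attribution is the only variant we found consistent with
the packaged worked example at both sites: attributing an interval's
positive count to every covered day flips three published Isahaya marks.
The noon cutoff and the row-date-anchored exclusion spans are likewise the
simplest rules that reproduce every published Koshi mark; both are exposed
as parameters (`cutoff_hour`, `window_len`).

Known gap: the published Isahaya record marks 31 May 2021 as a negative-case
fail, but no collection covering that date appears in the published month
(it presumably ran into June). With the packaged records the classifier
reports that day as excluded (no data); all other Isahaya marks and the
whole Koshi month reproduce exactly.

## Synthetic weather

The generators emulate exactly the features the model is sensitive to:
uniform flow; a low-level jet with a Gaussian speed profile (default 15 m/s
peak at 1250 m, width 800 m) and linear direction turning with height
(Ekman-like, default 10 deg/km); linear temperature profiles, including ones
crossing 13 degC at a prescribed height; constant, linear or parabolic
diffusivity profiles. Scenarios are horizontally homogeneous and (by
default) time-constant so that every downstream expectation is closed-form,
and w\* = 0 with flat terrain. They deliberately do not contain fronts,
horizontal shear, realistic boundary-layer physics or terrain, so passing
tests demonstrate the correctness of the numerics and the decision rules —
not forecast skill against real weather, which depends entirely on the
quality of the driving meteorology.

## Verification suite: problem sizes and numerical choices

* well-mixed condition: K(z\*) = 2 + 0.009 z\* m²/s over a 0–2000 m column,
  10,000 particles initially uniform, 6 h at dt = 120 s; chi-square over 20
  bins must not reject uniformity at the 1 % level. This test fails if the
  gradient-drift term is dropped or miscoded.
* variance growth: K = 10 m²/s, 100,000 particles started mid-column, 1 h;
  var(z\*) must equal 2Kt within 5 %.
* analytic transport: uniform 10 m/s wind plus 3 m/s self-speed for 10 h
  must give 468 km ground distance within 0.5 % (the residual is the
  constant-per-degree conversion versus the haversine, ~0.12 %).
* ceiling: an inversion crossing 13 degC at 1500 m; after every step no
  active moth may occupy air at T ≤ 13 degC (asserted exactly, no
  tolerance).
* arrival detection is compared against a brute-force all-pairs oracle on
  small random-walk trajectory sets.
* jet crossing: 200 moths, 12 h horizon; first-arrival flight time within
  10 % of distance/(jet speed + 3 m/s).

These sizes run the whole suite in well under a minute on one CPU while
keeping Monte-Carlo standard errors several times smaller than the asserted
tolerances.

Interpolation is linear in time and trilinear in space
(`scipy.interpolate.RegularGridInterpolator`), exact at grid nodes and
bounded by the surrounding node values; out-of-domain queries return a
signal that deactivates the moth. dKz\*/dz\* uses centred differences at
interior levels and one-sided differences at the boundary levels — exact for
linear profiles. Heights below the lowest met level sample that level
(constant extrapolation over at most a few tens of metres). Hourly input
cadence is required, not resampled; non-hourly files are rejected.

## Open design choices made

* "500 moths … within each province" is read as 500 per source area (2500
  total for the five packaged sources).
* Take-off is unconditional and from z\* = 0; the release window uses even
  spacing rather than a Poisson process ("constant temporal rate", and
  deterministic per seed).
* The drawn map circles are 18 km in *diameter* while the arrival rule uses
  an 18 km *radius*; both follow the operational convention and the
  discrepancy is kept as-is.
* w\* is taken from the input file (synthetic scenarios set it to 0), not
  diagnosed.
* Cold air blocks only the vertical step; self-propulsion is not suppressed.
* The fixed 10:00 UTC dusk release is a configurable default, not a
  constant.

## Limitations

* No orientation/crab-angle compensation and no flight-height selection;
  both change arrival areas and times for real migrations.
* No landing, mortality or energetics: moths fly until the horizon or the
  domain edge.
* Packaged source polygons are coarse (~10 vertex) simplifications of the
  provinces; supply precise boundaries for operational use.
* Maps are plain plate-carrée axes without coastlines; the GeoJSON output
  carries the geographic content for GIS display.
* Forecast skill on real events requires real mesoscale forecast fields
  (wind, temperature, vertical diffusivity) in the documented NetCDF
  convention; producing those fields is outside this package's scope.
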