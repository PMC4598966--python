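# Methods

## Model and procedure

The toolkit estimates two geographic-access indices from the distribution
of user-to-nearest-provider distances.

1. **Nearest distances.**  Participants and providers are point sets in a
   declared frame: planar meters (Euclidean distance) or WGS84 degrees
   (haversine on a sphere of mean radius 6 371 008.8 m).  The metric is a
   straight-line stand-in for travel effort; road-network distance is out of
   scope, and the indices themselves are metric-agnostic.  Nearest-provider
   ties are broken by lexicographically smallest provider id for
   determinism.  For privacy, participant coordinates may first be snapped
   to administrative-zone centroids; snapping is an explicit optional step
   because the downstream indices can be computed either way.
2. **Binning.**  Distances are grouped into contiguous half-open bands
   [k·w, (k+1)·w) with w = 50 m by default.  Counts conserve the sample
   size; the band width trades resolution against per-bin noise.
3. **Trend curve.**  An ordinary-least-squares polynomial y = f(x) is
   fitted to (band midpoint, count) pairs.  The fit is performed on a
   domain rescaled to [−1, 1] for conditioning and converted back to
   power-basis coefficients in meters.  When the counts are exactly
   polynomial of degree ≤ d at the midpoints the fit interpolates them, so
   analytic fixtures recover their generating coefficients to rounding
   error.
4. **Index extraction.**  Derivative roots come from companion-matrix
   eigenvalues of f′ and f″.  A root is kept if its imaginary part is below
   10⁻⁸ × the domain span, it lies strictly inside the open fit domain with
   a margin δ = w/100 (boundary roots are fit artifacts), and the
   derivative changes sign across [root − δ, root + δ].  The PWD is the
   smallest f′ root changing + → −; the TLD is the smallest f″ root beyond
   the PWD changing − → + (from the origin when the PWD is undetected).
   Multiple qualifying roots always resolve to the one nearest the origin.
   Each index is reported with its containing band and the band's upper
   edge as the buffer radius (a root of 1612 m in 50-m bands gives band
   1600–1650 and radius 1650).

### The global-maximum requirement on the PWD

A raw "first + → − root of f′" is not robust: where the count curve is
monotone decreasing, the polynomial oscillates around zero in the sparse
tail and produces spurious interior maxima (in the rural preset, a
degree-4 fit yielded a false PWD in 100 of 100 seeds).  Because the PWD is
defined as the distance band holding the *maximum* number of participants,
the accepted root must also attain the global maximum of f on the closed
fit domain (evaluated exactly via the critical points).  This single
condition removes all spurious rural detections while leaving genuinely
peaked curves untouched.  It can be disabled with
`find_pwd(..., require_peak_maximum=False)`.

### The TLD sign convention

A curve that rises, peaks, declines and flattens is concave down around the
peak and concave up in the tail, so the post-peak curvature change is
− → +.  That is the default (`"down-up"`).  The opposite convention is kept
behind `find_tld(..., convention="up-down")` for users who want the
pre-peak reading; with a unimodal count curve it generally returns nothing
beyond the peak.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `bin_width` | 50 m | width of the distance bands (the index resolution) |
| `degree` | 4 | trend polynomial degree; 2–10 supported.  4 is the minimum able to express rise–peak–decline–flatten.  Resolving the curvature change of a long-tailed unimodal density needs more flexibility: the planted-gamma preset carries degree 6, chosen during method development because degree 4's f″ root is biased ≈180 m late on gamma-shaped counts while degrees ≥ 11 inflate root variance.  An AIC-based selector (`select_degree_aic`) ships as an exploratory option; on planted-gamma data it overfits (picks 7+) and degrades TLD recovery, so it is not a default. |
| `tail_quantile` | 0.99 | the fit domain ends at the band containing this quantile of the sample.  Ending at the last nonzero band (available via `tail_quantile=None`) makes the domain the sample maximum — an unstable endpoint whose sparse 0/1-count tail measurably inflates the variance of the curvature root.  The 99% rule keeps the domain a stable functional of the distribution. |
| `require_peak_maximum` | True | see above |
| `cap` | 7 | multiplicity table pooling: counts ≥ cap share one "≥cap" row |
| eligibility threshold | 39.93 | self-care domain score (0–100, higher = worse) at/above which a record enters the cohort; the motivating cohort used its population mean |

Percentages in choice tables are rounded half-away-from-zero to two
decimals, matching how such tables are conventionally printed; two-sample
t statistics default to the pooled-variance variant (Welch available), and
the report labels the variant used.  Chi-square tests are uncorrected
Pearson; Fisher's exact test replaces them automatically on 2×2 tables
with any expected cell below 5.

## Synthetic scenarios: what they emulate and what they do not

No real addresses ship with the package; three generator models stand in.

- `urban-default` (15 × 15 km, 1000 participants, 30 providers):
  participants scatter as Gaussian clusters (σ = 500 m) around a 10 × 10
  grid of zone centroids with a 20% uniform background; providers are
  uniform.  Nearest distances then rise to an interior peak — the regime
  with a detectable PWD.
- `rural-default` (20 × 20 km, 1000 participants, 5 providers):
  participants sit around the few providers with a two-scale exponential
  distance decay (65% at 500 m, 35% at 3000 m scale), emulating villages
  near providers plus a diffuse hinterland.  Binned counts decrease
  monotonically, so the PWD is undetected by construction.  A uniform
  background was tried instead of the long-scale component and rejected:
  its nearest-distance density rises roughly linearly and creates a genuine
  mid-range bump, i.e. a real interior peak, which contradicts the regime
  this preset exists to produce.
- `planted-gamma` (1 provider, 5000 participants): each participant is
  placed at a gamma(k = 4, θ = 150 m) distance from the provider at a
  uniform bearing, so the nearest distance follows the planted law exactly
  and the indices have closed-form targets — mode (k−1)θ = 450 m and
  − → + inflection θ(k−1+√(k−1)) ≈ 709.8 m.  A lognormal family is also
  available (mode analytic; inflection located by root-finding on the exact
  density derivatives).

Extents are order-of-magnitude stand-ins for a dense city (~270 km²
upscaled to a square) and a sparse county (~4600 km² downscaled), not
calibrated maps.  The generators do not emulate road networks, coastline or
terrain constraints, provider capacity limits, or address-geocoding error
beyond optional centroid snapping — so passing tests show the estimators
recover the *distance-distribution geometry* they target, not that any
particular real region has a specific PWD.  Each draw site uses a named
RNG substream derived from (seed, component name), so outputs are
bit-reproducible and adding a draw site never shifts existing ones.

A note on regime contrasts: because rural participants co-cluster with
their providers, the rural *median* nearest distance is small; the
disparity signature of the presets lives in the upper tail (99th
percentile) of nearest distances and in the PWD detection flag, and that is
what the tests assert.

## Numerical choices and degenerate inputs

- All-zero counts, underdetermined fits (bins ≤ degree), empty provider
  sets, mixed coordinate frames, negative distances and out-of-range scores
  raise explicit validation errors; an undetected index is a value
  (`None` / JSON `null`), never an error.
- Tiny scenarios (e.g. 10 participants) flow through the pipeline and
  yield undetected indices or an explicit underdetermined-fit error — no
  crashes.
- Monte Carlo evaluation sizes — 200 replicates at n = 5000 for planted
  recovery, 100 seeds per regime at n = 1000 for the detection contrast —
  were chosen to estimate the ≥ 90% rates with low binomial noise while
  keeping the whole acceptance run in seconds.
- Bin-containment checks against analytic truth treat the band as closed
  on both edges: the gamma mode 450 m falls exactly on a band boundary, and
  an estimator landing in either adjacent band has localised the truth to
  band resolution.

## Known limitations

- Straight-line distance understates travel effort in fragmented terrain;
  the indices inherit whatever metric they are fed.
- A single global polynomial is a deliberately simple trend family; counts
  with several genuine peaks (multi-centre cities) violate its unimodal
  reading, and the global-maximum rule then reports only the dominant peak.
- The TLD of a monotone-decreasing curve (rural regime) is read from the
  fitted polynomial's tail curvature and is sensitive to the fit domain;
  interpret it as a smoothing-dependent summary, not a sharp threshold.
- Reported percentages follow printed-table rounding (half-away-from-zero,
  2 dp), so within-group shares can sum to 99.99 or 100.01.
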