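# Methods

## The classification model

A marine occurrence record carries an observation depth *d* (metres,
positive down) and coordinates; a bathymetry grid supplies the seabed depth
*z* at the record's cell. Benthic sampling concentrates within a narrow band
above the seafloor, while water-column sampling is strongly
surface-biased, so the joint distribution of (*z*, *d*) shows a dense
"benthic data cloud" hugging the *d = z* line. The package estimates the
cloud's shallow edge — the benthic minimum *t(z)* — and labels a record
benthic iff *d ≥ t(z)* (inclusive boundary). The threshold is clamped into
`[30 m, z]`: 30 m is the global shallow cut-off of the analysis (records
above recreational-diver depth are excluded at ingest), and a threshold can
never lie below the seafloor. Records *deeper* than the local seabed are
labelled benthic by this rule — they are usually bathymetry-resolution or
data-entry artefacts rather than water-column observations — and carry a
`qc_flag` when *d* exceeds 1.1 *z*.

## Stage by stage

**Ingest.** Occurrence tables are Darwin-Core CSV/TSV; rows failing
validation (coordinates out of range, missing or negative depth) are
counted per reason, never silently dropped, and input = survivors +
rejections is asserted at every stage. When a single `depth` is absent but
a min/max interval parses, the midpoint is used (the OBIS convention for
`depth`; configurable). Seabed depth is a nearest-cell lookup (the cell
containing the point, half-open `[lo, hi)` edges, longitude 180 wrapped to
−180) — no interpolation, for reproducibility and speed at database scale.
Cells with elevation ≥ 0 are land (elevation exactly 0 included): records
there are removed with reason "on land", the classic museum-coordinate
artefact.

**Horizons.** Training subsets are records whose seabed depth falls in a
narrow band around each horizon. Defaults: 14 targets
{100, 250, 500, 750, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000,
6000} m with ±1% bands — a config-driven choice spanning shelf to abyss;
any horizon set can be supplied. Each subset is trimmed at the q = 0.95
empirical quantile (type-7/linear interpolation, pinned for bit
reproducibility) of record depth: depths strictly above the cut are
removed. This targets grossly erroneous entries; at q = 0.95 no more than
`ceil(0.05 n) + 1` records can be removed. Subsets below 20 records are
skipped with a warning (clustering 2–10 groups needs enough points).

**Clustering.** Record depths are min-max normalised to [0, 1] (constant
input maps to zeros) and clustered with k-medoids under Euclidean (=
absolute) distance. For 1-D data the optimum partition is contiguous in
sorted order and each segment is best served by its median, so the solver
is a segment dynamic program returning the *global* optimum for every
k = 1..10 in one O(k n²) pass; the classic BUILD + SWAP search (with
exhaustive enumeration on small instances) backs the optional multivariate
mode, and the CLARA best-of-subsamples strategy (5 subsamples of
`min(n, 40 + 2k)` by default) handles subsets above the exact-PAM threshold
(2000 points). k is selected by maximum average silhouette width — mean of
`s = (b − a)/max(a, b)` with the singleton convention `s = 0` — computed on
the full subset, or on a seeded 2000-point subsample above the threshold;
ties break toward smaller k. ASW selection is an automated stand-in for
expert review of cluster plots; a per-horizon `k_override` in the config
reproduces expert-chosen solutions when desired. The benthic cloud is the
cluster whose closed depth range contains the horizon's seabed depth; when
trimming has removed the deepest records the target may exceed every
cluster's range, in which case the cluster with the nearest medoid is used
and a fallback flag recorded. The envelope is the min/max record depth of
that cluster's members.

**Threshold smooth.** The (seabed depth → benthic minimum) pairs (≥ 6
required, duplicates rejected) are fitted with a penalized regression
spline: cubic B-splines on uniform *unclamped* knots (basis dimension 10,
capped at n − 1) with a second-order difference penalty and Gaussian
errors/identity link. Uniform unclamped knots make the penalty's null
space exactly the straight lines, so linear training data are reproduced
to machine precision at any smoothing level. The smoothing parameter
minimises GCV, `n·RSS / (n − γ·edf)²`, over a 49-point log grid
10⁻⁶..10⁶ (ties toward the smoother fit; the grid is capped to keep the
penalized normal equations well conditioned). The inflation γ = 1.4 is the
standard counter to GCV's tendency to undersmooth at small n — with 14
points and a 10-dimensional basis, plain GCV can select near-interpolating
fits that oscillate wildly between horizons. Reported diagnostics: edf
(trace of the smoother matrix), deviance explained (1 − RSS/TSS), residual
scale, and pointwise 95% confidence intervals at the training horizons from
the Bayesian posterior covariance `scale · (BᵀB + αP)⁻¹`. Predictions use
constant extension beyond the training range (flagged `extrapolated`).
Models serialise to JSON (knots, coefficients, training pairs);
classification from a stored model never refits.

**Summaries.** All summaries are pure functions: 1°×1° half-open grid
cells anchored at (−180, −90); hemisphere fraction counts latitude > 0 as
northern (exactly 0 counts southern, fixed for determinism); medians are
linear-interpolated; kernel densities are Gaussian with Silverman's
bandwidth on a 512-point grid padded by three bandwidths, reported both raw
(integrates to 1) and ×1000 for readability; phylum tallies rank
descending with alphabetical tie-break, missing phyla counted separately as
unassigned; the seafloor-coverage fraction weights ocean cells by
cos(latitude) by default (cell counting available for comparison, since the
area convention of such statements is rarely stated).

## The synthetic-data generator

`make_bathymetry` builds a deterministic shelf–slope–abyss ramp (land
margin on the west, ~40 m shelf to 6500 m) with seeded 2% multiplicative
noise; the two ramp columns nearest each default horizon are stamped with
exactly that depth, so every horizon band is guaranteed non-empty.

`simulate_records` draws, with exact class counts (`round(n·fraction)`):

- **benthic** (fraction 0.66): depth = seabed − |N(0, σ)| with σ = 25 m and
  the offset truncated at 4σ (redraw), floored at 30 m — a cloud hugging
  the seafloor, emulating grabs/cores/ROV and demersal-trawl sampling;
- **pelagic**: depth = 30 + Exp(150 m) sampled by inverse CDF conditional
  on depth < seabed − 4σ, so every truth label is unambiguous; draws at
  cells too shallow for that ceiling are re-homed to a random eligible
  deeper cell and counted. The 150 m scale gives the strong surface bias
  (median ≈ 130 m) characteristic of water-column records;
- **erroneous** (fraction 0.01): depth = seabed × U(1.1, 3), the
  deeper-than-the-seabed entry error the per-horizon trim exists to remove;
- optional **trawl lines** (default off): meridional tracks of truly
  pelagic records whose depth field carries the seabed depth — the
  mis-entry mode that produces linear artefacts in mapped data; they
  exercise the QC flag, not the classifier.

Latitudes follow an exact hemisphere split (northern fraction 0.79,
matching the hemispheric bias typical of these databases); phyla are drawn
from a vertebrate-dominated weight table (Chordata 0.45, Arthropoda 0.25,
…). Everything flows from one seed (per-stage child seeds are derived by
hashing), so identical configs give bitwise-identical datasets and
byte-identical pipeline outputs.

What the generator does **not** emulate: spatially autocorrelated sampling
effort, coastline geometry, species-level composition, depth-varying noise
in the bathymetry–record relationship, and — importantly — pelagic records
*near* the benthic cloud (they are held 4σ clear so truth is well defined).
Passing recovery tests therefore demonstrate correctness of the machinery
under the stated sampling model, not field accuracy on any real database.

## Known limitations

- Where a horizon's seabed is too shallow to admit unambiguous pelagic
  records (≤ 130 m under the defaults), its subset is pure benthic; forcing
  k ≥ 2 then necessarily splits the cloud and the identified cluster
  under-captures. Real shallow-water data contain pelagic records above the
  cloud, so this is a property of the generator's truth-separation rule,
  not of field behaviour.
- The truncated-exponential pelagic column has non-zero density up to its
  ceiling, so isolated deep-pelagic points between the pelagic bulk and the
  benthic cloud can attach to the benthic cluster at the ASW-optimal k,
  pulling a horizon's benthic minimum below the cloud. The per-horizon
  `k_override` is the supported remedy, mirroring expert selection of
  cluster solutions; end-to-end label accuracy is barely affected because
  the threshold smooth regularises across horizons.
- GeoTIFF bathymetry is not read directly; convert to NetCDF.
- Taxonomic name resolution and CRS reprojection are out of scope; inputs
  are assumed WGS84 lon/lat.

## Problem sizes

Default study sizes were chosen so a full run is interactive: 50,000
records over a 240×120-cell grid give horizon subsets of ~500–1700 records,
exact clustering throughout, and an end-to-end run (simulation included) in
a few seconds on one CPU; the test suite completes in about a minute.
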