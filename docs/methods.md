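# Methods

This note records the models, conventions and design choices behind
`netnight`, in the spirit of a statistical package's methods
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time conventions and schedules

All capture times are minutes since a nominal 18:00 sunset; the night is
the half-open interval [0, 720). Clock times are mapped onto this axis
(18:30 → 30, 05:30 → 690) and snapped *down* to the start of their
net-check interval (default 30 min), reflecting that a capture is
observed at a check, not at the true flight time. Real sunset drift is
ignored: activity is pooled by clock hour, which is how repeated-night
capture data are recorded in practice. All window membership is
half-open, so a record at exactly minute 360 (midnight) belongs to the
second half-night; this makes the `6h`/second-half partition exact and
the `6h` + [360,720) matrices sum cellwise to the `12h` matrix.

Schedule restriction never drops night replicates: a night with zero
captures under a schedule survives as an all-zero matrix row, because
the *failure mode* of a schedule — too many empty nights to ordinate —
is a result, not a nuisance. Each downstream stage decides explicitly
how to treat zero rows (see congruence below).

## Synthetic data generator

The generator emulates the structure the analyses assume, not any
specific fauna:

* **Abundance.** Per-species expected captures per occupied site-night
  are lognormal (default σ = 1), realising the right-skewed
  species-abundance distributions of real assemblages. By default the
  rates are placed at evenly spaced quantiles of the lognormal rather
  than drawn, so the expected total is stable across seeds while the
  realised counts stay Poisson (a negative-binomial overdispersion
  switch exists for robustness checks). Presets rescale rates so the
  analytic expected grand total matches a target (e.g. ~1,742 captures
  over 66 nights for the species-rich preset).
* **Activity.** Each species gets one of four densities on [0, 720):
  uniform; early peak (normal bump centred 120 min, sd 90); late peak
  (centred 670, sd 40); or bimodal (both bumps, 70/30, the classic
  "first four hours plus last hour" shape). Non-uniform shapes keep a
  15% uniform floor — no bat is strictly confined to its peak. Capture
  times are drawn per 30-min bin from the integrated density.
* **Rarity structure.** Site occupancy is Bernoulli per species × site
  (default p = 0.6); site coordinates are uniform in a bounding box, so
  occupied-site hulls vary realistically in extent.

The amazonia-like preset (10 sites, 66 nights, 40 species, 25% of
species late-peaking) is the package's standing test bed for the
schedule comparison; atlantic-like and cerrado-like presets scale the
sites/nights/species down to the sparser survey regimes where degenerate
sub-matrices become likely. What the generator does **not** model: net
shyness and trap avoidance, within-night weather, detectability
differences among species, lunar phobia, or seasonal turnover. Passing
tests therefore demonstrate that the *analysis machinery* recovers
planted structure under idealised sampling — not that any specific field
system behaves this way.

## Rarity index

LA uses the per-site reading of "relative abundance": mean captures per
night of the species divided by the site's total captures (all species,
all nights), medianed over occupied sites. The log transform is
log(x+1) so that GR = 0 (single-site species) stays finite; min–max
standardisation then maps each metric to [0, 1] across species, which
also makes RI invariant to any common affine rescaling on the log scale.
The independence weights use ω = 1/2 + (1−|r₁|)/2 + (1−|r₂|)/2 on the
standardised metrics (so the weights describe the quantities actually
averaged); a squared-correlation variant ω = [(1−r₁²)+(1−r₂²)]/2 is
available behind `variant="half_sum_sq"` since published renderings of
this weighting differ. Quartile class boundaries are inclusive
(R: RI ≤ Q1, C: RI ≥ Q3) so distinct RI values always produce non-empty
Rare and Common classes; an all-equal RI vector collapses to all-Common
with a warning, and fewer than four species cannot support quartiles
(all Uncommon, warned).

Geographic range is the convex-hull area of occupied-site coordinates
under a spherical Lambert azimuthal equal-area projection centred on the
occupied sites' mean coordinate (R = 6371.0088 km). LAEA is exactly
equal-area on the sphere, so hull areas are correct at regional extents
without an external projection library; fewer than three non-collinear
sites give 0 km². Coordinates may optionally be pooled across datasets
(multi-region surveys) via `extra_site_coords`; the default is
within-dataset.

## Activity change points (TITAN)

Sample units are (site, night, 30-min interval) cells — the finest unit
the check protocol defines, giving enough observations along the
gradient for midpoint candidates and minimum split sizes. Candidates
are midpoints between consecutive *distinct* capture times of the taxon;
any split leaving fewer than `min_split` = 4 units on a side is
discarded. IndVal is the Dufrêne–Legendre product 100·A·B.

Candidate selection maximises the **permutation z-score** of IndVal
(each candidate/side standardised by its own permutation mean and sd),
not raw IndVal: raw IndVal is systematically inflated for very small
splits (a four-unit early window with perfect occupancy can outscore
the true change point), and standardisation removes that bias. This is
the reference behaviour of the method's canonical implementation; raw
maximisation remains available as `selection="indval"`. The permutation
p-value uses the null distribution of the selection statistic maximised
over candidates and both sides, so the candidate search is accounted
for.

Bootstrap diagnostics rerun the entire selection (candidates included)
on each resample of units: purity = fraction of resamples agreeing in
direction; reliability = fraction with permutation p ≤ 0.05;
significance requires both ≥ 0.95; the 90% change-point CI is the
5th–95th percentile of bootstrap change points. Defaults n_perm = 250,
n_boot = 500 are the method's customary sizes, configurable throughout.
Community thresholds are cumulative step-function sums of responder
z-scores in change-point order (restricted to pure-and-reliable taxa by
default; configurable), peaking at the community-level z− and z+
thresholds; a direction with no responders is flagged, not invented.
Species under 9 records are pooled once into (guild, rarity-class)
composite taxa and never re-pooled.

## Rarefaction and extrapolation

Rarefaction is the exact hypergeometric expectation, computed with
log-gamma arithmetic (exact to enumeration within 1e-12 at small n, no
overflow at large n). Extrapolation uses the Bernoulli-product-model
closed form with Chao-type f0 (bias-corrected f1(f1−1)/2 when f2 = 0);
it is continuous at the reference point, monotone, and asymptotes at
S_obs + f0. Sample-based curves mirror this with incidence counts
(Q1, Q2, Chao2). Confidence intervals are percentile bootstrap over
night replicates (default 200 resamples) rather than the analytic
unconditional variance: the bootstrap is assumption-light, respects the
night-replicate sampling structure, and is directly testable; the
analytic variance remains a possible extension. Curves for different
schedules share the full-night target effort so endpoints are
comparable; "significantly different" is operationalised as
non-overlapping 95% CIs at the common effort.

## Congruence and the null model

Ordination rows are night replicates, not sites: schedule matrices
describe the same sampling events, and five PCoA axes are impossible
with a handful of sites, whereas tens of nights make them well defined.
All-zero rows are removed per matrix before ordination; configurations
are then restricted to the shared rows before Procrustes. A matrix is
*degenerate* — reported, never silently fixed — when fewer than three
usable rows or fewer than two positive axes remain; this is exactly how
a sparse split-schedule sub-matrix with "too many zeros" fails.

PCoA drops negative eigenvalues without Cailliez/Lingoes correction
(the common default; proportions explained are relative to the positive
part). Procrustes uses symmetric scaling — both configurations centred
and scaled to unit sum of squares — so m² ∈ [0, 1] and r = √(1−m²);
with that normalisation m² = 1 − (Σσ)², σ the singular values of XᵀY,
which is also how the permutation test is evaluated cheaply. When the
two ordinations retain different axis counts, the narrower is padded
with zero columns. PROTEST permutes target rows with the +1-corrected
p = (1+#{r_perm ≥ r_obs})/(n_perm+1), default n_perm = 999.

The null model draws k species uniformly without replacement from the
full-night matrix and scores the column subset exactly as a schedule
would be — full-night counts, so the null carries the sample-area
effect (fewer species) but no time-of-night bias. Curve mode sweeps a
k grid; matched-k mode fixes k at a schedule's species count and
returns the schedule's mid-rank percentile in the null r distribution.
Whether a published analysis draws its ~1,000 subsamples in total or
per k is ambiguous in this literature; both modes are provided. Failed
draws (degenerate subset ordinations) are recorded as failed, never
dropped.

## Determinism and problem sizes

Every stochastic component takes a seed or `numpy` Generator;
`run_pipeline` derives all stage randomness from one config seed and
reruns are byte-identical. The test suite and the acceptance script run
the resampling machinery at moderated sizes (e.g. 100–200 permutations
and bootstraps, 20–800 null draws, the 66-night preset) — sizes chosen
so the full verification cycle completes in minutes on a single core
while keeping Monte-Carlo error far below the tested margins; all sizes
are parameters, and field analyses can raise them freely.

## Known limitations

* Effort is assumed standardised across nights (equal net-metre-hours);
  there is no per-net model or effort offset.
* The rarity index is dataset-relative by construction; RI values are
  not comparable across datasets, only classes within one.
* Change-point inference assumes independence of (site, night,
  interval) units; within-night autocorrelation of activity is not
  modelled and will make purity/reliability mildly optimistic.
* MCP geographic range uses raw convex hulls — no land clipping or
  alpha shapes — and a spherical Earth.
* Richness comparison offers no coverage-based standardisation or Hill
  numbers; extrapolation inherits the usual caution against going far
  beyond ~2× the observed effort.
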