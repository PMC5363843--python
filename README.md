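# netnight

Do partial-night mist-net schedules representatively sample a bat
assemblage?

Neotropical bat surveys overwhelmingly rely on understory mist-nets
checked every 30 minutes through the night, and — because even nocturnal
fieldworkers must sleep — most studies net only the first six hours
after sunset, on the assumption that this window holds the activity peak
of every species. `netnight` implements the complete analysis needed to
test that assumption on capture data: it restricts full-night (12-h)
capture matrices to alternative schedules, quantifies species rarity and
nocturnal activity thresholds, and asks whether a schedule's sample is
merely *smaller* (a sample-area effect: fewer individuals, hence fewer
species) or *biased* (a differential species-activity effect: the wrong
species), by comparing each schedule against full-night sampling in
richness and in composition.

The package is aimed at community ecologists designing or re-analysing
capture surveys (bats, birds, any repeated-session netting protocol).

## What it computes

Time is minutes since nominal sunset at 18:00, the night the half-open
window [0, 720). Three canonical schedules: `12h` = [0, 720); `6h` =
[0, 360); `6hB` = [0, 180) ∪ [540, 720) (first three plus last three
hours).

* **Rarity** — per species *i*: local abundance LA_i (median over
  occupied sites of mean nightly captures / total site captures),
  regional abundance RA_i (dataset records / occupied sites), geographic
  range GR_i (minimum-convex-polygon area, km²). After log(x+1) and
  min–max standardisation, the rarity index is the weighted mean
  RI_i = (LA_i ω_LA + RA_i ω_RA + GR_i ω_GR)/(ω_LA + ω_RA + ω_GR), each
  ω rewarding a metric for independence from the other two (via Pearson
  correlations). Quartiles of RI give Rare / Uncommon / Common classes.
* **Activity thresholds (TITAN)** — per taxon, candidate change points
  are midpoints between observed capture times; each split is scored
  with Dufrêne–Legendre indicator values IndVal = 100·A·B
  (abundance concentration × occurrence fidelity), standardised against
  a permutation null; bootstrap purity/reliability ≥ 0.95 flags
  significant negative (early-night) or positive (late-night)
  responders; cumulative z-score sums give community-level thresholds.
  Species with < 9 records are pooled by (guild, rarity class).
* **Richness** — individual- and sample-based rarefaction
  E[S(m)] = S_obs − Σ_i C(n−n_i, m)/C(n, m), extrapolated beyond the
  observed effort with the Chao-type estimate f0 = f1²/(2 f2) under the
  Bernoulli product model, bootstrap 95% CIs over night replicates.
* **Compositional congruence** — Jaccard / Bray–Curtis dissimilarities
  among night replicates, PCoA (first five axes), Procrustes
  superimposition of the schedule's configuration on the full-night one:
  m² = residual sum of squares, r = √(1 − m²), significance by PROTEST
  permutation. A random-species-subset null model (k species drawn from
  the full-night matrix) isolates the pure sample-area effect: a
  schedule whose r falls below the matched-k null distorts *which*
  species are sampled, not just how many.

A synthetic-data generator (`netnight.simulate`) produces multi-site,
multi-night capture datasets with known ground truth — skewed lognormal
abundances, uniform/early/late/bimodal nocturnal activity densities,
occupancy-driven rarity structure — so every stage is testable without
field data.

## Worked example

```
netnight simulate --preset cerrado --seed 7 --out demo/   # or use your own CSVs
netnight run --config cfg.yaml --out demo-out/
```

with `cfg.yaml`:

```yaml
preset: cerrado
seed: 7
titan:      {n_perm: 100, n_boot: 200}
richness:   {n_boot: 100}
congruence: {n_perm: 199}
null_model: {n_draws: 100}
```

prints (`demo-out/summary.txt`):

```
nights: 24  species: 18
captures per schedule: 12h=490, 6h=359, 6hB=322
full night caught 36% more individuals than the best six-hour schedule (6h)
the split schedule (6hB) caught 10% fewer individuals than the first-six-hours schedule
taxa with significant activity thresholds: 5
congruence 6h/jaccard: r=0.886 (m2=0.215, p=0.0050, k=17)
congruence 6hB/jaccard: r=0.934 (m2=0.128, p=0.0050, k=16)
congruence 6h/braycurtis: r=0.961 (m2=0.076, p=0.0050, k=17)
congruence 6hB/braycurtis: r=0.926 (m2=0.142, p=0.0050, k=16)
```

Reading: the full night caught 36% more individuals than the best
six-hour schedule (the sample-area effect), five taxa show significant
activity thresholds, and each six-hour schedule reproduces the
full-night compositional structure with r ≈ 0.89–0.96 (all PROTEST
p < 0.01) — high, but (see `null_curve.csv`) below what a random subset
of the same number of species achieves, i.e. sub-sampling the night
biases species identity. Stage tables (`rarity.csv`, `titan_taxa.csv`,
`rarefaction.csv`, `congruence.csv`, `null_curve.csv`,
`cumulative_yield.csv`) hold the full results; `manifest.json` pins
parameters and seeds, and a rerun with the same config is
byte-identical.

The same analyses are available as a library:

```python
from netnight import build_matrix, restrict_to_schedule, FIRST_SIX_HOURS
from netnight.congruence import strategy_congruence
res = strategy_congruence(full, six_hour, metric="braycurtis")
print(res.r, res.p)
```

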