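# Methods

## Dissimilarity family and its partition

All dissimilarities are Jaccard-family indices computed from a triple of
shared and unique mass.  For presence/absence data the triple is the
classical (a, b, c): items common to both assemblages, exclusive to the
first, exclusive to the second.  For abundance data the Ruzicka
(quantitative Jaccard) triple is A = Σ min(x_i, y_i), B = Σ x_i − A,
C = Σ y_i − A.  The total dissimilarity (b+c)/(a+b+c) is partitioned
additively into replacement (turnover) 2·min(b,c)/(a+b+c) and
richness-difference |b−c|/(a+b+c).  The additivity identity holds
algebraically; tests assert it to 1e-12 in double precision rather than
bit-exactly.  When both assemblages are empty (a = b = c = 0) all three
components are defined as 0 — two empty communities are identical, and
any other convention would break the identity property and punch holes in
pairwise matrices.

The same machinery is applied to four views of a pair of site networks:

* **L** — plant composition.  The plant vector is the site's full floral
  abundance vector: plants recorded in the floral plots even if never
  visited, plus visited plants missing from the plots, which are assumed
  rare and assigned abundance 1 (`complete_plant_abundances`).
* **U** — pollinator composition, quantified by per-species total visit
  counts (the only abundance currency the webs record for pollinators).
* **WN** — the two whole link-weight maps, keyed by (plant, pollinator).
* **OS** — the link maps restricted to plants *and* pollinators present
  in both networks.  OS turnover is the signature of true rewiring; OS
  richness reflects diet-breadth (link-count) differences among
  co-occurring species.  When a pair shares no plant or no pollinator,
  OS is reported missing, not coerced to 1: an absent comparison is not
  evidence of maximal rewiring.  Raw visit counts are used in the shared
  subwebs without renormalization.

Partition proportions ("turnover explains X% of beta") are ratios of
sums over defined pairs, not means of per-pair ratios, so pairs with
zero total contribute zeros rather than undefined terms.  The rewiring
fraction is the product mean(OS total) × turnover share of OS.

## Metaweb realization (OS′)

The metaweb aggregates link weights across all sites.  Each local web is
compared, as the first assemblage, to the metaweb restricted to the local
species sets.  Because the default metaweb includes the focal site, no
local link can be absent from it, so binary b = 0 and binary OS′ turnover
is structurally zero; quantitatively local weights cannot exceed metaweb
sums, so B = 0 there too.  A leave-one-out toggle excludes the focal
site's links from the aggregation (links unique to the focal site then
count as genuine turnover mass); it defaults off, matching the
aggregate-over-all-sites definition.  A local link missing from a
strictly built metaweb raises a consistency error — it signals the
metaweb was not built from a study containing that site.

## Connectivity

CI_i = Σ_j exp(−α·d_ij)·A_j^b over neighbouring grassland patches with
0 < d_ij ≤ radius.  Defaults: α = 1 /km (an average dispersal distance of
1 km), b = 0.5 (a typical insect emigration–area scaling), radius 5 km.
Distances are Euclidean on the planar km grid; at the spatial extent of a
regional pasture study, map-projection curvature is negligible.  Without
an external patch table, `study_connectivity` uses the study's own sites
as the neighbourhood; this yields much smaller CI values than a survey of
all grasslands in the landscape would, because focal sites are sparse.

## PERMANOVA

One-way, adonis-style, computed directly on squared distances:
SS_total = Σ_{i<j} d²_ij / n, SS_within analogous per group,
pseudo-F = (SS_among/(g−1))/(SS_within/(n−g)), with an unrestricted
random-relabelling null and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm).
Perfect separation (SS_within = 0) yields F = ∞, which orders correctly
under the ≥ comparison.  Matrices with undefined entries (possible for
OS) are reduced by listwise site deletion — sites are dropped greedily by
missing-entry count until the matrix is complete — and dropped sites are
logged; pairwise-complete subsetting would break the exchangeability the
permutation null assumes.  Tests cross-check pseudo-F against scikit-bio
and against exhaustive enumeration of label arrangements at small n, and
verify type-I error calibration on null synthetic studies.

Bounded responses headed for beta regression pass through
`epsilon_adjust`, which maps exact 0 to 1e-7 and exact 1 to 1−1e-7; the
shift is orders of magnitude below the data resolution, so between-site
ordering is untouched.

## Synthetic study generator

The generator emulates a space-for-time pasture survey: by default 10
abandoned, 18 restored and 10 continuously grazed sites on a 100-km
square extent, with log-normal pasture areas around category means of
2.6, 3.8 and 2.8 ha.

* **Regional pool and metaweb.**  80 plants × 90 pollinators; each pair
  is linked with probability 1 − (1 − connectance)^g_j, where g_j is a
  mean-one log-normal per-pollinator generality weight (σ =
  `generality_sigma`, default 0.75), giving degree heterogeneity while
  keeping connectance 1 a complete web.  Webs are resampled (bounded)
  until every species has a link.
* **Site assembly.**  The regional pool is split into a core shared by
  all categories (`core_fraction`, default 0.35) and three
  category-specific pools; each site draws `category_turnover` (default
  0.4) of its species from its category pool and the rest from the core.
  Site richness targets default to (22, 16), (26, 32), (26, 20)
  (plants, pollinators) for abandoned/restored/continuous, mirroring
  similar plant richness but elevated pollinator richness in restored
  pastures.
* **Floral survey.**  Log-normal flowering-unit totals (σ =
  `abundance_dispersion`); each visited plant is deleted from the survey
  with probability 0.1 and re-completed at abundance 1, exercising the
  rare-plant rule.
* **Visitation.**  Events are sampled one at a time: a pollinator
  proportional to its local abundance (optionally scaled by local partner
  count to the power `degree_abundance_coupling` — generalists tend to be
  more abundant; default 0, uncoupled), then a plant proportional to
  floral abundance among the pollinator's metaweb partners present — but
  with probability `rewiring_prob` (default 0.15) the plant is drawn
  uniformly among all plants present, a genuinely rewired link.  Uniform
  rewiring is the least-assumption null: the analysis must detect
  rewiring whatever its mechanism.  Pollinators with no metaweb partner
  at the site are not sampled (they could not forage there).
* **Sampling effort.**  The per-site event count is
  `visits_per_site` (default 85) × a category effort multiplier
  (defaults 0.45/1.55/0.55, echoing mean pollinator counts of roughly
  37/133/47 per category) × mean-one log-normal noise
  (`visits_dispersion`, default 0.5).  Varying effort is essential:
  with identical totals at every site the quantitative U and WN
  richness components are identically zero, which no field study shows.
  Setting the dispersion to 0 and multipliers to 1 recovers fixed-count
  sampling.
* **Managed taxon.**  Optionally a fixed pollinator id receives an extra
  ~4% of visits spread over the flora, to exercise the managed-bee
  exclusion filter.

Randomness is a hierarchical stream from one seed (pool, species-pool
partition, then each site), so adding sites leaves earlier sites'
draws unchanged.

What the generator does *not* emulate: phenology within the season,
spatial autocorrelation between neighbouring sites, trait-matching
constraints on rewired links, and observer biases other than effort.
Passing tests therefore demonstrate that the statistics recover known
structure under these idealized conditions, not that field estimates are
unbiased.

## Test design notes

* The rewiring-recovery test runs the generator in a
  sampling-saturated regime: low metaweb connectance (0.06), near-flat
  abundances, degree–abundance coupling 1 and 1200 visits/site, so
  every metaweb-constrained link among co-occurring species is realized
  at every site (~9 events per faithful link) while the uniformly
  rewired pair space (~2250 pairs) stays far from saturation.  In that
  regime the binary OS turnover share is zero without rewiring and
  rises monotonically with the rewiring probability.  Outside it the
  share is confounded: undersampling fakes turnover, and oversampling
  of rewired links makes shared subwebs converge.  A study with no OS
  dissimilarity at all has turnover share 0 by convention (no signal).
* PERMANOVA calibration uses studies with `category_turnover` 0 and equal
  per-category settings, making category labels exchangeable by
  construction.
* Problem sizes throughout the suite (6–12 sites, pools of tens of
  species, hundreds to ~2000 visits) are chosen as the smallest designs
  in which each property is expressed cleanly.

## Known limitations

* The pollinator abundance currency for U is visit totals; flying-but-
  not-visiting individuals are invisible to the networks and excluded.
* OS missingness is handled by listwise deletion in PERMANOVA; with many
  disjoint pairs this can discard a large share of sites.
* The quantitative OS′ of a site against a metaweb that includes it is
  bounded away from 0 whenever other sites contribute weight to the same
  links; interpret it relative to other sites, not as an absolute.
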