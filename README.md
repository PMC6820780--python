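# netbeta

Partitioned beta diversity of plant–pollinator interaction networks.

Restoration ecologists comparing flower-visitation webs across sites (for
example abandoned, restored and continuously grazed semi-natural pastures)
need to know *why* two networks differ: because different species occur
there, because species carry different numbers of links, or because
co-occurring species genuinely switched partners ("rewiring").  `netbeta`
implements the dissimilarity decomposition that separates these causes, the
regional-metaweb comparison, a landscape connectivity index, a PERMANOVA
for category effects, and a seeded generator of synthetic multi-site
studies with tunable rewiring so the whole pipeline is testable end to end.

## The statistics

Every dissimilarity is Jaccard-family, built from shared/unique mass
(binary: counts *a, b, c*; quantitative Ruzicka: sums of abundance minima
*A, B, C*):

    beta_total = (b + c) / (a + b + c)

split additively into a true-replacement (turnover) part and a
richness-difference part:

    beta_turnover = 2 * min(b, c) / (a + b + c)
    beta_richness = |b - c| / (a + b + c)

Applied to four views of a site pair: plant composition (**L**),
pollinator composition (**U**), whole link sets (**WN**), and link sets
restricted to species present in both networks (**OS**).  The OS turnover
component is the signature of true rewiring; its richness component
reflects differences in the number of links among co-occurring species.
The product `mean(OS) * turnover_share(OS)` estimates the fraction of
interactions genuinely rewired between networks.

Each local web is also scored against the **metaweb** (all interactions
aggregated across sites, restricted to the local species): OS' near 0
means the site realizes most regionally known links of its species.
Site connectivity uses the incidence-function index
`CI_i = sum_j exp(-alpha * d_ij) * A_j^b` (alpha = 1 /km, b = 0.5, 5 km
search radius by default).

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_pairwise_beta.py
python analysis/03_metaweb_realization.py
python analysis/04_landscape_inference.py
```

The first script writes a synthetic 38-pasture study (10 abandoned / 18
restored / 10 continuously grazed).  The second prints, for this seed:

```
[quantitative] mean L=0.89 U=0.94 WN=0.98 OS=0.79
[quantitative] OS turnover share 0.38 -> ~30% of interactions truly rewired
[binary] mean L=0.73 U=0.85 WN=0.98 OS=0.70
```

Read: almost every site pair has a near-maximal whole-network link
dissimilarity (WN 0.98), driven by strong species turnover (L, U).  Among
co-occurring species the dissimilarity is lower (OS) and is mostly a
matter of link-number differences; only the turnover share of OS — here
38%, reflecting the generator's 15% rewiring probability plus sampling
effects — counts as true rewiring.  The fourth script adds connectivity
and PERMANOVA, e.g.

```
[quantitative] PERMANOVA L: F=3.20 R2=0.155 p=0.001 (n=38)
```

meaning plant composition differs among pasture categories (15.5% of
distance-matrix variance).  The same analyses run on user data via the CLI:

```bash
netbeta simulate --outdir study/          # or bring your own three CSVs
netbeta analyze --config config.yaml --outdir results/
netbeta report --outdir results/
```

Input format: `interactions.csv` (site_id, plant, pollinator, visits),
`floral.csv` (site_id, plant, flowering_units), `sites.csv` (site_id,
category, x_km, y_km, area_ha, years_since_restoration).

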