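# fluvidiv

Diversity analytics for river bacterioplankton continua: dendritic
river-network residence-time proxies, OTU-table processing, alpha/beta
diversity with permutation inference, core-community and habitat-term
continuum statistics, and a synthetic dendritic meta-community generator.

## The scientific problem

Along a large river, bacterioplankton communities change gradually from the
headwaters to the mouth.  Two meta-community processes compete to shape this
continuum:

* **mass effects** — headwater streams have a large streambed/riparian
  contact zone per unit water volume, so soil and groundwater bacteria are
  continuously advected into the channel faster than they are lost;
* **species sorting** — once in-stream residence time exceeds bacterial
  generation times, environmental filtering lets a small set of competitive,
  typical-freshwater taxa (acI tribes, LD12, *Polynucleobacter*, ...) take
  over.

The observable signatures are declines in richness (Chao1) and evenness
(Pielou's J) downriver, a rising read share of an occupancy-defined core
community, and decreasing soil/groundwater-affiliated reads — all regressed
against **mean dendritic stream length**, the average of the flow-path
lengths from every upstream spring to a site (shared reaches counted per
path), which at constant velocity is proportional to mean water residence
time.

`fluvidiv` implements this analysis chain end to end and, because deep
river-network surveys are rare, ships a generative model of the whole
process so each statistical claim can be tested against known ground truth.

## Core quantities

For a site *s* with upstream springs *k = 1..K* and flow paths of length
*L_k*:

* mean dendritic stream length `MDSL(s) = (1/K) Σ_k L_k`;
* cumulative dendritic distance = total upstream channel length, each reach
  once (a drainage-density measure);
* contact-zone ratio = wetted perimeter / cross-sectional area (m⁻¹).

For a rarefied count vector with singleton/doubleton counts F₁/F₂:
`Chao1 = S_obs + F₁(F₁−1) / (2(F₂+1))`, `J = H′ / ln S` (natural-log
Shannon).  Beta diversity uses Bray–Curtis dissimilarity
`d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)`, non-metric MDS minimising Kruskal
stress-1, and permutation inference (one-way PERMANOVA, PROTEST,
beta-dispersion homogeneity, envfit vector fitting) with
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`.

## Worked example

```sh
python examples/network_metrics.py
```

```
springs upstream of X: ['A', 'B']
mean dendritic stream length (km): 9.0
median dendritic length (km):      9.0
cumulative dendritic distance (km): 12.0
catchment area (km^2):             60.0
contact-zone ratio upstream 0.830 1/m, downstream 0.056 1/m, fold decrease 14.8x
```

Two springs feed site X via paths of 8 km (A→J→X) and 10 km (B→J→X), so the
residence-time proxy is their mean (9 km), while the drainage network itself
holds only 12 km of channel.  The contact-zone comparison shows riparian
influence per unit water volume dropping ~15-fold from a headwater channel
to a large lower course — the physical basis for sorting overtaking mass
effects downriver.

```sh
python examples/core_community_continuum.py
```

```
core community (FL, q=0.90): 464 OTUs over 13 mainstem samples
...
chao1 ~ mean dendritic stream length: slope=-0.816/km, R2=0.70, p=0.00037
core_share ~ mean dendritic stream length: slope=+0.0007194/km, R2=0.93, p=8.6e-08
soil_term ~ mean dendritic stream length: slope=-0.002287/km, R2=0.93, p=9.5e-08
first occurrences per site (source -> mouth): [1094, 249, 42, 29, 23, 5, 2, 0, 6, 3, 3, 2, 0] | total distinct OTUs: 1458
```

On a simulated 64-spring continuum the free-living fraction loses richness
downriver (negative Chao1 slope), the core community's read share rises, the
soil habitat-term share falls, and nearly all OTUs are already present in
the uppermost reaches — the expected continuum signatures.

Other examples: `otu_processing.py` (filters and rarefaction),
`alpha_beta_diversity.py` (NMDS, PERMANOVA, beta dispersion),
`simulate_and_run.py` (full pipeline round trip).

## Command line

```sh
fluvidiv simulate --preset paper-like --seed 42 --out data/
fluvidiv network-metrics --network data/network.tsv --sites data/sites.tsv --out metrics.tsv
fluvidiv run --table data/otu_table.tsv --meta data/metadata.tsv \
    --network data/network.tsv --sites data/sites.tsv \
    --taxonomy data/taxonomy.tsv --terms data/terms.tsv \
    --alpha-depth 7000 --beta-depth min --perm 999 --seed 42 --out results/
fluvidiv report --out results/
```

Identical configuration + seed gives byte-identical outputs; the run
manifest (`manifest.json`) records seeds, depths and dropped samples.

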