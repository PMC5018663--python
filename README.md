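# inventario

Inventory completeness and sampling-hotspot analysis for species occurrence
records.

Biodiversity data portals serve millions of occurrence records, but only a
handful of places were ever sampled thoroughly enough that their species
list can be called *complete*. Finding those places matters: a demonstrably
complete historical inventory is a baseline against which faunal change can
be measured by resurveying the same site decades later. `inventario`
implements the full analysis for Darwin-Core-style occurrence tables, built
around the Mexican pre-1980 avifauna use case but configurable for any
region, taxon and cutoff:

1. **Clean and reduce** — normalize taxonomy against a synonym table, drop
   records that cannot be dated or post-date the cutoff year, and collapse
   multi-portal duplicates into unique *events* (species × date × place).
2. **Grid and score** — assign georeferenced events to 0.05° grid cells
   clipped to a boundary polygon, then score every cell with the
   small-sample-adjusted Chao2 estimator of expected species richness,

   ```
   S_exp = S_obs + ((N − 1) / N) · a(a − 1) / (2(b + 1))
   ```

   where `N` is the number of events, `S_obs` the species observed, and
   `a`, `b` the species recorded exactly once and exactly twice. Inventory
   completeness is `C = S_obs / S_exp`; cells with `N ≥ 200` and `C ≥ 0.8`
   are well-inventoried (`C ≥ 0.9`: excellent).
3. **Detect hotspots** — the Getis-Ord Gi\* local statistic flags cells
   whose neighborhood concentrates sampling effort (99% confidence,
   BH-FDR-controlled); contiguous significant cells merge into named
   hotspots, re-scored with the same completeness index.
4. **Rescue** — non-georeferenced records are matched into hotspots by a
   locality-name synonymy derived from the georeferenced data (rejecting
   descriptors offset by more than 5 km), and the remaining unmatched
   localities with `N ≥ 200` are scored standalone.

A synthetic-data module generates occurrence dumps with known ground truth
(per-species daily detection probabilities, planted effort clusters,
cross-portal duplication, georeferencing loss), so the whole pipeline is
testable offline.

## Worked example

Scoring three classic survey sites from the reference catalog shipped with
the package (`python examples/01_completeness_from_counts.py`):

```
Isla Cedros   N= 213  S_obs= 45  a=12  b=10  ->  S_exp=  51.0  C=0.88
Totontepec    N= 533  S_obs=107  a=15  b=30  ->  S_exp= 110.4  C=0.97
Misantla      N= 307  S_obs=108  a= 3  b=62  ->  S_exp= 108.0  C=1.00
```

Misantla's three singletons against 62 doubletons mean almost nothing
remains undetected (`C = 1.00`); Isla Cedros is about 88% inventoried.
`examples/02_pipeline_on_synthetic_data.py` runs the end-to-end pipeline on
a generated dump and rediscovers the planted cluster as its single hotspot
row; `03` and `04` demonstrate Gi\* detection and locality rescue in
isolation. A thin CLI wraps the same calls:

```sh
inventario simulate --seed 1 --out scratch/demo
inventario run scratch/demo/occurrences.csv boundary.geojson --out scratch/results
```

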