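# Methods

## The sampling model

The unit of sampling effort is one day at one place. Every occurrence
record reduces to an *event*: a unique combination of canonical species
name, date key and place key. Dates may be partial — `1964_7_16`,
`1964_7_NA` and `1964_NA_NA` are three distinct time events — because
coarse labels on historical specimens still carry information; records with
no date element at all, or with a year that cannot be checked against the
cutoff, are dropped. The cutoff year itself (default 1980) is inclusive:
"after the cutoff" is removed, the cutoff year is kept.

Place is resolved along two paths. Georeferenced records land in half-open
0.05° grid squares `[edge, edge + 0.05)`; the half-open convention makes
cell assignment a partition, so no event can be counted twice. The grid
origin is configurable because published cell centers need not align with
multiples of the resolution and the registration of any particular external
grid is generally unknown. Non-georeferenced records keep their normalized
locality string (trimmed, whitespace-collapsed, case-folded, diacritics
stripped) and enter the analysis through rescue or as standalone
localities.

## Chao2 completeness

Within a unit (cell, hotspot or locality), incidence frequencies are: `N`
events, `S_obs` species, `a` species with exactly one event, `b` with
exactly two. Expected richness uses the small-sample-adjusted Chao2
estimator

    S_exp = S_obs + ((N − 1)/N) · a(a − 1) / (2(b + 1)),

a lower-bound-type estimator: many singletons relative to doubletons signal
many species still undetected. Completeness is `C = S_obs / S_exp`, in
(0, 1]; with no singletons `C = 1` exactly.

Selection of well-inventoried units applies `N ≥ 200` first (smaller
samples yield artificially complete inventories), then tiers on `C`
**rounded to two decimals** — the reporting precision. Rounded-C tiering is
a deliberate choice: raw-C thresholding would misclassify units whose raw
completeness sits just under a tier boundary but rounds onto it (e.g. raw
0.8969 reported as 0.90), and it is the rule that reproduces the reference
catalog's published 24/71 excellent/good split. `S_exp` is reported to one
decimal and `C` to two; raw values are kept internally.

The package ships the published reference catalog (95 grid cells, 5 rescued
localities, 20 hotspots) as data. Recomputing every row from its printed
(N, S_obs, a, b) reproduces the printed `S_exp` within ±0.05 and `C` within
±0.005 — the printing precisions — for 116 of 120 rows. Four hotspot-table
entries are internally inconsistent as printed: the printed C of El
Triunfo (0.95), Comitán (0.89) and Los Tuxtlas (0.87) disagrees with the
ratio of their own printed S_obs and S_exp (0.944, 0.896, 0.865), and the
Miahuatlán/Mixtepec S_exp (245.9) is 0.053 from the recomputed 245.847.
The corresponding cross-check tests are left failing on exactly those rows
rather than widening the tolerance; the estimator is the same one that
reproduces the other 116.

## Hotspot detection

Per-cell event counts — over *all* retained cells, zeros included — feed
the Getis-Ord Gi\* statistic with binary weights: a fixed distance band of
1.5 grid steps between cell centers, self included, which captures exactly
the queen (8-neighbor) neighborhood. The standard score is

    z_i = (Σ_j w_ij x_j − x̄ W_i) / (S √((n W_i − W_i²)/(n − 1))),

with global mean x̄ and population standard deviation S. Constant fields
define `z = 0` everywhere and nothing is significant. Significance takes
`z > 0` only (sampling *concentrations*; gaps are not of interest) with
two-sided normal p below α = 1 − confidence (default 0.99), after
Benjamini-Hochberg FDR control across cells. The band, self-inclusion, α
and FDR switch are all configurable; the defaults are a declared,
reproducible stand-in for the undocumented band-selection heuristics of
GUI hot-spot tools, which cannot be matched bit-for-bit.

Significant cells merge into hotspots as connected components under queen
contiguity — the inclusive reading of "contiguous". Hotspots are named
deterministically after the cell center of their southwestern-most member
and their areas are spherical-Earth sums (authalic radius 6371.0072 km)
over member cells (~29 km² per cell at latitude 20°). Hotspot completeness
pools all events in member cells plus rescued events keyed by the hotspot
name, collapsed to unique species × date combinations, so the same species
on the same day in two member cells counts once.

## Rescue

Locality strings attached to georeferenced events inside a hotspot form
that hotspot's synonymy; a string seen inside two or more hotspots is
ambiguous and excluded (a false assignment would corrupt completeness more
than an omission). Non-georeferenced records whose descriptor matches —
either in full or after stripping an offset prefix of the form
`<number> <km|mi> <direction> [of|by road] <name>` (1 mi = 1.609 km) — are
pulled into the hotspot unless the offset exceeds 5 km. A distance-like
prefix that cannot be parsed is treated as offset 0 but flagged and
counted, since a human reviewer resolved such cases in the original
workflow. Rescue only adds events keyed by hotspot name; every quantity
computed from georeferenced cells alone is invariant under it.

Remaining unmatched non-georeferenced records are grouped by normalized
locality string and scored standalone under the same `N ≥ 200` / `C ≥ 0.8`
rules.

## Synthetic data

The generator emulates what the analysis assumes about real portal dumps:
sites with a known species pool (default 150 species per site from a pool
of 400), per-species daily detection probabilities `p_i = expit(Normal(μ,
σ))` with defaults μ = −2.0, σ = 1.5 — median daily detectability ≈ 0.12
with a heavy tail of hard-to-detect species, which produces the realistic
singleton/doubleton regimes the estimator must handle, including a ≫ b and
a = 0 — and independent detection across survey days (default 60 per
site). Planted clusters multiply a site's survey days; a configurable
fraction of records is re-emitted under a second portal tag (default
0.12), has its coordinates blanked (default 0.30), carries a distance
offset prefix of 1–12 km (default 0.10 of blanked records, so some must be
rejected by the 5 km rule), or loses date elements (default 0.05). All
ground truth — true event set, duplicate counts, site-to-cluster map — is
exported for tests.

Under these conditions the estimator recovers true richness well: over 200
replicates at 150 species × 60 days, mean S_exp ≈ 145 (3% low, as expected
of a lower bound) with mean C ≈ 0.95, and C rises monotonically with
effort. What the generator does *not* emulate: real taxonomic name chaos
beyond a supplied synonym table, spatially extended sites spanning several
cells, non-independent detections (flocking, weather), or real coastline
geometry. Passing tests therefore demonstrate correctness of the
computation under the stated sampling model, not robustness to every
pathology of real portal data.

## Numerical and design notes

- Coordinate parsing normalizes Unicode minus/dash variants and comma
  decimal separators; unparseable values become missing, never dropped
  rows, and a coordinate missing one member of the lat/lon pair loses
  both.
- Duplicate groups keep the lexicographically first record by (source,
  original row order) as representative, making deduplication
  deterministic and idempotent.
- Boundary buffering is planar in degrees (default 0.05°, i.e. "within one
  cell of the boundary"); cell retention uses the exact polygon distance
  with a 1e−9 tie tolerance so cells exactly at the buffer distance do not
  flip on float rounding of grid-aligned coordinates.
- Gi\* denominators of zero (constant field, or a neighborhood covering
  every cell) define `z = 0`.
- Empty units emit no summary rather than a degenerate one; Chao2 on
  `N = 0` or inconsistent frequencies (`a + b > S_obs`, `S_obs > N`)
  raises.
- Test problem sizes (synthetic dumps of ~10³–10⁴ records, 20 × 20 Gi\*
  fields, 100–200 Monte-Carlo replicates) were chosen as the smallest
  scales at which the statistical claims are stable; the full suite runs
  in a few seconds.

## Limitations

The countrywide tallies of the original national analysis (half a million
events, 54k rescued records, the specific 100 cells / 20 hotspots) require
the original multi-portal dumps and cannot be regenerated from printed
material; the package validates against the printed per-site catalog and
against synthetic ground truth instead. Grid registration of the original
analysis is unpublished, so recomputed cell memberships need not match it;
all catalog-level checks therefore work from printed incidence summaries
rather than re-gridded coordinates. Gi\* significance relies on the normal
approximation, which is rough for very small study areas.
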