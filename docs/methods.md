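# Methods

This note documents the models, conventions and defaults behind
`cwr-phylospace`, and what the synthetic data do and do not establish
about behaviour on real occurrence data.

## Gridding and cleaning

Coordinates are geographic degrees throughout; no projection is applied.
The analysis grid is a rectangle of square cells (default 0.1°, roughly
10 km at the equator), indexed row-major from the lower-left origin.
Cells are half-open `[edge, edge + size)` in both axes so a point on an
interior shared edge belongs to the higher-index cell; the outermost
upper edge is closed so the grid's exact corner is kept. Because the
edge test divides floats, positions are snapped to a boundary when they
fall within 1e-9 cell-units of it — a tolerance of ~1e-10 degrees that
is far below any realistic coordinate precision.

Cleaning drops, in order: blank species names, non-finite coordinates,
exclusion-listed species, points off the grid, points in masked cells.
Rules are counted separately so injected-defect audits can reconcile the
report exactly. Cleaning is idempotent. Duplicate records (same species
and coordinates) count toward per-cell sampling effort `N` but collapse
to one incidence: redundancy is about samples versus species, incidence
about presence. Species names match tree tips exactly after trimming and
collapsing whitespace — no fuzzy matching, because silently "repairing"
names hides real curation errors. Unmatched occurrence species are
dropped with a warning; unmatched tips stay in the tree, where they
still shape the comparison-tree mean.

## Trees, PD and RPD

The root is treated as having no subtending edge; a root edge present in
an input file is discarded with a warning. This makes PD of the full
taxon set equal the total tree length, the standard Faith convention.
Zero-length branches are legal (they add nothing to PD) but are excluded
from the comparison tree's mean, which is the mean of the strictly
positive branch lengths applied to every branch, zero-length ones
included. Polytomies pass through unresolved — PD is well defined on
multifurcations.

Per-cell PD is computed vectorized: a boolean tips × branches path
matrix (tip-to-root paths) turns the cells × species incidence into a
cells × branches "spanned" indicator by one matrix product, and PD is
its product with the branch-length vector. The comparison-tree PD needs
no second tree traversal: it is the spanned-branch count times the mean
non-zero length. Exhaustive subset enumeration on small trees (≤ 8 tips,
all 2^n subsets) is kept in the test suite as the independent oracle.

## Randomization null

The null hypothesis fixes each cell's richness (row sums) and each
taxon's range size (column sums) and randomizes everything else. The
sampler is the curveball trial-swap: two random cells exchange a random
subset of the species they do not share, which preserves both marginals
exactly at every step. Defaults: 5 × (number of presences) trades
between consecutive realizations, realizations chained (each continues
from the previous state) with the rep's RNG seeded at `seed + rep`, so
any rep is reproducible in isolation. 999 realizations is the library
default, the conventional choice for rank tests at α = 0.05; the
pipeline's standard desk-scale scenario uses 199, which still resolves
p = 0.005.

Significance is rank-based with ties counted on both tails and the +1
correction: `p_high = (#{null ≥ obs} + 1)/(n_reps + 1)`, so p is never 0
and `p_high + p_low ≥ 1 + 1/(n_reps+1)`. PD is reported for both tails
at α each (maps conventionally show both significantly high and
significantly low PD); RPD is two-tailed at α/2 per tail. Within one
landscape the cells share realizations, so per-cell p-values are
correlated across space — fine for mapping, but not a basis for
landscape-wide multiple-testing arithmetic.

## Conservation gap scores

Eight per-species scores, all 0–100, three per system plus their mean:

| score | ex-situ | in-situ |
|---|---|---|
| SRS (sampling) | 100·G/(G+H), germplasm vs reference records | % of records inside buffered protected areas |
| GRS (geographic) | % of suitable cells within 50 km of a germplasm point | % of suitable cells inside buffered protected areas |
| ERS (ecological) | % of suitable-area ecoregions reached by the germplasm buffers | % reached by protected areas |
| FCS | mean of the three | mean of the three |

FCSc-mean = (FCSex + FCSin)/2. Buffers use great-circle distance to cell
centres (degree grids distort; kilometres are what collection radii
mean); the protected-area buffer default is 5 km, the germplasm buffer
50 km, both configurable. Area ratios are fine-grid cell counts, treating
cells as equal-area — acceptable at the ~tens-of-km scale of these
buffers and grids, and it avoids projection machinery. A species with no
suitable cells gets GRS = ERS = 0 and a flag rather than NaN, keeping it
in the priority ranking. Species without a distribution model are not
scored: they are assigned high priority by rule, with NaN scores so
cohort means never average fabricated zeros.

Categories are left-closed bins of FCS: HP < 25 ≤ MP < 50 ≤ LP < 75 ≤ SC.
Reported percentage shares are truncated (floored) to one decimal, not
rounded — the convention under which published cohort tallies of this
kind reproduce exactly — with a 1e-9 epsilon so exactly-representable
tenths are not pushed down by float noise. The protected-area assessment
table applies the same truncation to its percentages, row averages,
column totals (means over departments with data; empty departments are
no-data, not zero) and grand average (mean of the column totals).

## Hot spots

Hot spots of SR and PD are occupied cells at or above the q-th
percentile (default 95) of occupied-cell values, computed with the
linear-interpolation percentile and an inclusive ≥ threshold; for
significance metrics the "hot spots" are simply the classed cells. A
cell counts as protected by the centre-in rule: its centre lies in a
protected cell of the analysis grid. With all values equal, every cell
is a hot spot — degenerate but well defined.

## Indicators

The coarse PD surface is resampled to the fine (distribution-model) grid
by bilinear interpolation between cell centres, clamping beyond the
outermost centres and propagating no-data; the refinement factor
defaults to 2 (the 10 km → 5 km relation between occurrence and model
grids). Gap richness sums, over species, the suitable cells *not* within
the germplasm buffer — the spatial complement of GRSex, and by
construction never exceeding predicted richness. Composites divide each
input by its own maximum over valid cells and average, so the result
lies in [0, 1], is invariant to rescaling either input, and reaches 1
only where both inputs peak together. All-zero inputs cannot be
standardized and raise an error rather than emitting NaN maps.

## Synthetic data

The generator supplies every input with the structure the analysis
assumes: a Yule (pure-birth, rate 1) tree grown by exponential waiting
times so all branch lengths are strictly positive and the root has no
edge; Gaussian species ranges (kernel sd 0.3°) around uniform random
centres; a lognormal (σ = 1) abundance profile with every species
guaranteed one record; sampling effort thinned by a low-frequency
Gaussian random field (`exp(bias · smoothed noise)`), giving the uneven
redundancy surface real surveys show; a Bernoulli germplasm flag
(default 0.2 — germplasm accessions are a minority of occurrence records
in aggregated databases); blocky protected areas hitting the target
coverage to within one cell (default 15%, a typical national terrestrial
figure); departments as a contiguous round-robin-grown partition;
ecoregions as a Voronoi partition; and suitability as a Gaussian bump at
twice the range-kernel sd, binarized at 0.5, for a random 55% of species
(the observed fraction of CWR cohorts that clear distribution-model data
requirements), leaving the rest to exercise the high-priority-by-rule
path. Each generator call draws from its own stream at `seed + fixed
offset`, so outputs are bit-reproducible and mutually independent.

The standard scenario is a 30 × 30 grid, 60 species, 3000 records and
199 realizations — sized so a complete run takes seconds while every
code path (empty cells, unmodelled species, no-data departments) is
exercised. What the synthetic data do *not* emulate: real geography and
climate, spatial autocorrelation of suitability beyond a single bump per
species, taxonomic name noise, or database-specific duplication
patterns. Passing tests therefore demonstrate the correctness of the
computations and conventions, not the ecological realism of any
particular map.

## Numerical notes

- Incidence matrices are dense uint8; at the package's intended scale
  (10³–10⁴ cells, a few hundred species) this beats sparse formats.
- Curveball uses Python's `random.Random` (cheap single draws and
  shuffles of small lists); everything array-shaped uses
  `numpy.random.Generator`.
- Score algebra (FCS = mean of components) holds to 1e-9 and is asserted
  in tests; scores are clamped to [0, 100] as a cheap guard.
- RPD is guarded against a zero comparison-tree PD, which the
  comparison-tree construction already makes impossible for non-empty
  assemblages on a tree with any positive branch.

## Known limitations

- Cell-count area ratios ignore the cos(latitude) shrink of degree
  cells; over a country-scale latitude span the bias is a few percent.
- The curveball chain's mixing is not formally tested per dataset; the
  5 × presences default is generous for the matrix sizes here, and the
  planted-signal and type-I calibration tests bound its practical
  behaviour.
- The protected-area "centre-in" rule differs from polygon-overlay
  intersection when protection is fragmented below cell scale.
- Ecoregion representativeness treats ecoregions as present/absent per
  cell, without areal weighting inside a cell.
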