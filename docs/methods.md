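# Methods

## Model and scope

The package operates on three objects: a rooted, time-calibrated phylogeny
(branch lengths in MY), a sparse binary species × grid-cell occupancy
table, and a per-cell Human Footprint (HF) surface on the same grid. All
spatial metrics are computed on the species present in *both* the tree and
the occupancy table; names on only one side are logged and dropped, and a
branch with no mapped descendant contributes nothing. Terminal branch
lengths (TBLs), by contrast, are read off the full input tree before any
intersection, so a species' unique contribution reflects the complete
phylogeny.

Grid cells are opaque keys: projection handling, polygon rasterisation and
area weighting happen upstream. For paraphyletic assemblages the package
takes a forest of independent trees and sums their per-cell metrics; no
connecting branches are invented, so such totals are conservative.

## Branch accounting conventions

* An explicit root edge in the Newick input is recorded but excluded from
  total PD and every metric; accounting is on the ingroup tree.
* Zero-length edges and polytomies pass through unchanged.
* Subtree PD of ≥ 2 species is the edge-length sum over the union of
  root-to-tip paths (root path included). A single-occupant cell scores
  the occupant's TBL only. These two rules are deliberately discontinuous
  — the single-species rule is the field's convention for cell-level PD —
  and both are implemented verbatim rather than smoothed.
* Pruning keeps the original root (even unifurcating) and merges emptied
  internal edges additively, so PD loss = ΔPD holds exactly, and pruning
  to one survivor leaves its full root-to-tip path as its pendant edge.

## Human-pressure weighting

HF values are binned into five categories with linear weights: none
(HF = 0) → 1.0, low → 0.8, moderate → 0.6, high → 0.4, very high → 0.2.
Because block-mean upscaling produces fractional HF, the integer anchor
ranges (0; 1–2; 3–5; 6–11; 12–50) are extended to half-open intervals:
none iff HF = 0 exactly; low on (0, 3); moderate on [3, 6); high on
[6, 12); very high on [12, 50]. The three published cutoffs (HF < 3,
HF ≥ 6, HF ≥ 12) fall on boundaries of this convention. Upscaling takes
the mean of non-missing fine cells per block (missing ≠ zero: zero-filling
coastal blocks would fabricate "no pressure"); wholly missing blocks are
absent. Occupied cells missing from the HF surface get weight 1.0 with a
logged warning — the neutral fallback, which degrades HIPE toward PE
rather than inventing threat. Raster input is accepted as a 2-D array
with NaN missing values (plus per-cell CSV); GeoTIFF georeferencing is
out of scope.

## Numerical and procedural choices

* **Conservation.** PE, HIPE and EDR partition the mapped PD; sums agree
  with the mapped total to 1e-9 relative tolerance (plain float
  accumulation suffices at desk scale). EDR computes fair-proportion ED on
  the tree pruned to mapped species so the partition is exact.
* **Tie-breaking.** All rankings (top-fraction cells, cumulative-capture
  bands, HITE ranks) order by descending value then ascending key, so runs
  are reproducible.
* **Cumulative capture.** A cell joins band *f* (smallest requested
  fraction) if the running share of the total, before the cell is added,
  has not yet reached *f*; cells reached after the last requested fraction
  are NaN. A 1e-12 tolerance absorbs float boundary noise.
* **Residual PD** regresses PD on richness (OLS, statsmodels) — the
  direction that makes a positive residual mean "more PD than expected for
  the observed richness". Constant richness is rejected as singular.
* **Medians over tree distributions** use the midpoint convention for even
  counts; a key must appear in ≥ 50% of trees to be reported, otherwise it
  is dropped with a warning.
* **Pressure null.** Observed HF values are permuted (sampled without
  replacement) over the occupied-cell universe, preserving the empirical
  HF distribution; categories are re-derived from the permuted values,
  which is equivalent to permuting category labels under the fixed
  interval map. The statistic is the HF ≥ 6 share of the fixed top-fraction
  cells.
* **Extinction null.** Stratified: each replicate drops, per stratum, a
  uniform random set matching the observed count. The data-deficiency
  scenario's `random_subset` mode draws the subset size uniformly on
  {1..n} (the size law is unspecified in the source problem; it is
  overridable by calling `pd_loss` directly on chosen sets).
* **Units.** Scores are reported in MY per (weighted) cell; the CLI's
  `--cell-area-km2` writes an additional per-km² column for a given cell
  area (e.g. 96.5² km² ≈ 9312.25).
* All randomness flows through explicit integer seeds (numpy PCG64, or
  `random.Random` for tree simulation); rerunning any generator or null
  with the same seed byte-matches its output.

## Synthetic data: what it does and does not emulate

The generator reproduces the structural features the metrics are sensitive
to: ultrametric pure-birth trees (default 50 species at 0.02
speciations/MY, giving crown ages of a couple hundred MY and a heavy-tailed
TBL distribution, with pendant edges extended by the exponential waiting
time to the next uncommitted speciation so TBLs are strictly positive);
contiguous ranges grown by random frontier accretion with log-normal sizes
(median 4 cells, log-sd 1.2 on a 20 × 20 grid — most ranges small, a few
large); phylogenetic signal in log range size (default 0.373, interpolating
an iid and a Brownian component with variance-preserving weights, matching
the moderate signal reported for squamate range sizes); and an HF surface
built from Gaussian noise smoothed over ~3 cells, affinely mapped and
clipped to [0, 50] so that all five pressure categories, including exact
zeros, occur. A threat simulator marks the top fraction of a
signal-blended trait as threatened, producing phylogenetically clumped
threat at signal 1.

Not emulated: real biogeography (climate, niches, coastlines), range-size
/ latitude structure, the eight HF component layers, and any correlation
between HF and occupancy (they are generated independently). Passing tests
therefore demonstrate the algebraic and statistical correctness of the
machinery under realistic structure, not empirical global patterns, which
require the underlying atlas and phylogeny data.

## Problem sizes used in the shipped checks

The conservation suite runs 100 seeded instances of 10–50 species on a
10 × 10 grid; oracle-equivalence checks 25 instances of 12 species on
7 × 7; the pressure null uses 1000 replicates on a 40-species, 15 × 15
instance; the clumped-extinction check uses 100-species trees, threat
prevalence 0.25 at full signal, two root-clade strata, and 50 null
replicates across 50 seeded runs. These sizes are the package's chosen
desk-scale study conditions.

## Known limitations

* On pure-birth trees a phylogenetically clumped species set is typically
  a *young* clade: its short terminal branches partly offset the internal
  branches it removes, so at small tree sizes (tens of species) clumped
  extinction can occasionally lose *less* PD than the stratified random
  null. The excess-loss direction becomes near-certain once the threatened
  fraction spans whole multi-species clades (of order 100 species at 25%
  prevalence). Real threat patterns concentrated in old, distinct lineages
  strengthen the effect beyond what the Yule model shows.
* HP weights are a coarse five-level proxy; any binning amplifies small
  HF differences at category boundaries (11 vs 12) and compresses large
  ones within a category (12 vs 50).
* The single-species-cell PD rule makes cell PD discontinuous as richness
  crosses 1; comparisons across cells of very different richness should
  use the partition metrics (PE/HIPE) instead.
* Forest totals omit the branches connecting the component trees and are
  therefore lower bounds.
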