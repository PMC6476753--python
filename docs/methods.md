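# Methods

This note records the models, conventions, numerical choices and
limitations behind `landres`, in the order data flows through the package.

## Analysis grid and transects

All spatial analysis happens on an abstract grid of 1-km cells addressed
`(row, col)`, row 0 at the top, cell centres at `(row + 0.5, col + 0.5)` km.
Distance conventions follow the analytical unit: individuals in the same
cell are 0 km apart, individuals in any of the 8 neighbouring cells are
1 km apart (rook and queen neighbours are deliberately not distinguished at
this resolution), and all other pairs use the centre-to-centre Euclidean
distance.

Every unordered pair of individuals is joined by the straight segment
between their cell centres.  The cells the transect "contains" are its
**supercover**: every cell whose closed square the segment touches.  The
supercover was chosen over Bresenham-style rasterization because the
land-use statistic counts cells *within* the network line — inclusiveness
matches that definition.  When the segment passes exactly through a cell
corner, both off-diagonal neighbours are included (a symmetric tie-break).
The implementation walks row strips with exact integer arithmetic
(coordinates doubled so cell centres are odd integers), so corner events
are decided exactly, and it is regression-tested against an independent
Liang–Barsky segment–square clipping oracle.

Per transect the package records four elevation parameters — mean,
max − min, sample standard deviation (denominator n − 1; a single-cell
transect has SD 0) and the coefficient of variation CV = SD/mean — plus the
cell count and presence of each of the seven land-use classes (forest,
grass field, farmland, urban, open water, special matrix, wetland; codes
1–7).  CV is undefined when the mean elevation is non-positive; such pairs
surface as errors when a CV matrix is requested, not silently.  A helper
(`resample --method mean`) block-averages a finer digital elevation model
onto the analysis grid.

## Genetic distance

Genotypes are unordered diploid calls at microsatellite loci (GENEPOP
2- and 3-digit dialects are read; 3-digit is written; `000` means missing).
The genetic distance is Bray–Curtis dissimilarity on allele-abundance
profiles: each (locus, allele) pair observed in the table is a slot, an
individual's abundance is its copy number (homozygote 2, heterozygote
1 + 1), and

    BC(i, j) = Σ |a_i − a_j| / Σ (a_i + a_j)

over slots of loci scored in both individuals (pairwise deletion of
missing data).  Per-pair totals then equal 4 x (shared loci), so BC lies in
[0, 1]; a pair with no shared scorable locus is an error naming the pair.
This "allele as species, copy number as abundance" encoding is the
conventional one in the ecology-distance packages this field uses.  Marker
summaries report allele counts, observed heterozygosity and unbiased
expected heterozygosity He = (2n/(2n−1))(1 − Σ p²); formal
Hardy–Weinberg/linkage testing is out of scope, and a configurable locus
exclusion list stands in for marker-quality decisions (e.g. null-allele
suspects).

## Mantel machinery

The Mantel statistic is the Pearson correlation of the vectorized strict
upper triangles.  The permutation null jointly permutes rows and columns of
one matrix — relabelling individuals — and

    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)

for the default one-tailed `greater` alternative; ties count as extreme
(conservative), and 999 permutations floor p at 0.001.  The default tail is
one-tailed because the screening question is whether cost models are
*positively* associated with genetic distance; the tail is recorded in
every result.  Joint permutation leaves the off-diagonal multiset intact,
so means and norms are precomputed and only dot products are recomputed per
permutation.

The partial statistic is the first-order partial correlation of the
triangle vectors.  The default permutation scheme permutes the first
(genetic) matrix raw and recomputes the partial statistic each time — the
scheme of the classic ecology packages; a residual-permutation variant is
available behind `method="residual"` but is not the default.  Collinear
conditioning (|r| = 1) is an error.  For n ≤ 8,
`exhaustive_mantel` enumerates all n! joint permutations (identity
included) and returns the exact p, serving as the engine's oracle; the
test suite checks Monte-Carlo agreement within binomial bounds and type-I
calibration at α = 0.05 on independent inputs.

## Model matrices and the decision rule

Resistance matrices are `weight x (cells of the class on the transect)`
with the weight grid (2, 5, 25, 50, 100) by default.  Because a single-class
product is a pure rescaling — and the Mantel correlation is scale-invariant
— the package exposes `resistance_base`:

* `none`: the bare product (weight choice cannot affect the simple r);
* `add_distance` (default): entry = Euclid km + weight x count, which makes
  the weight a real parameter trading off distance against land-use cost.

The mode is recorded in matrix metadata and the run manifest rather than
silently chosen.  Combined resistance sums member products; in
`add_distance` mode the distance base enters once, so a single-member
combination equals its own resistance matrix.  Barrier matrices are the
0/1 presence of a class on the transect.

The classification follows a causal-modelling triad: a class is
**resistance** (analogously **barrier**) when G × R|Dis is significant
(strictly p < α, α = 0.05 by default) and G × Dis|R is negative or not
significant (strictly p > α); p = α exactly counts as not significant.  A
class's headline row is its best weight (argmax simple Mantel r, ties to
the smallest weight), and the combined model is built from classes whose
best rows pass, each at its best weight.  No multiplicity correction is
applied across screen rows; α is configurable.  Rows whose model matrix is
degenerate (class absent from every transect, or exactly collinear with
distance) are marked untestable instead of raising.

Screens replicate over all pairs, male pairs and female pairs, each
stratum on an independently rebuilt genetic-distance matrix and network;
because transect profiles are pair-local, subsetting full-network matrices
is provably identical (asserted by test), and rebuilding is simply the
clearer contract.

## Synthetic landscapes

The generator is the package's stand-in for field data and defines the
study conditions under which the pipeline is validated.

*Elevation* is a base level (200 m) plus 6 randomly placed Gaussian hills
(amplitude up to 400 m, width 10 km) — a smooth positive surface.
*Land use* carves the seven classes out of one smoothed random field
(Gaussian kernel, 3 cells) by rank thresholding, so realized class shares
match the requested proportions to one cell of rounding while forming
spatially aggregated patches, as real landscape mosaics do.  Default
shares are strongly skewed and forest-dominated (forest 64.6 %, grass
20.3 %, farmland 12.9 %, urban 1.6 %, open water 0.5 %, special matrix
0.05 %, wetland 0.02 %).  *Individuals* (default 100 on a 60 × 60 km grid,
male fraction 0.7) are placed uniformly over forest cells, one per cell.

*Genotypes* implement a planted-signal model: the true pairwise cost is

    D_eff(i, j) = Euclid_km(i, j) + beta x (farmland cells on the transect)

— exactly the statistic the downstream screen tests, so detection power is
measured against the signal that generated the data.  With `beta_female`
set, a pair's beta is the mean of its members' sex-specific values, which
reproduces the female-biased landscape sensitivity pattern as a recoverable
simulation property.

Latent values are multivariate normal per locus (two independent draws;
quantile-binned into 8 equiprobable alleles by default).  The correlation
matrix is *calibrated* rather than taken as a raw kernel of D_eff, for two
reasons discovered during design:

1. D_eff is not a metric embedding, so exp(−D_eff/λ) is generally not
   positive semi-definite, and every generic repair (eigenvalue clipping,
   nugget inflation) either distorts the planted signal toward distance or
   dilutes it;
2. any convex decay profile makes the expected Bray–Curtis *nonlinear* in
   cost, and with thousands of correlated pairs the partial Mantel test is
   powerful enough to flag that curvature as a spurious residual distance
   effect, corrupting the G × Dis|R arm of the decision rule.

The calibrated construction: (a) classically MDS-embed D_eff and keep the
embedding's non-Euclidean remainder orthogonalized against
{1, Dis, count} — "texture" that keeps the correlation matrix near the PSD
cone without correlating with either tested predictor; (b) form the planted
cost as scaled D_eff plus that texture; (c) pass it through the inverse of
the dissimilarity response φ (the Monte-Carlo-estimated expected per-locus
Bray–Curtis as a function of latent correlation, computed once per allele
count with a fixed internal seed), so that **expected genetic distance
rises linearly in the planted cost** from φ(1/(1 + noise_sd²)) for
coincident pairs to φ(0) at the largest cost.  `noise_sd` (default 0.6)
sets the correlation ceiling — non-spatial noise; `decay_lambda`, when
given, is the cost (km) at which correlation reaches zero and must cover
the landscape's cost range (default: automatic, the observed maximum).
Any residual negative eigenvalue is absorbed by a small diagonal nugget,
and the equiprobable bin edges use the exact marginal SD.  All stages are
deterministic given the config seed (independent named substreams per
stage).

Under these defaults the pipeline recovers a planted farmland cost of
beta = 2 as a "resistance" verdict in ≥ 80 % of replicate worlds
(18/20 over seeds 1–20 in the acceptance suite, 999 permutations), flags
farmland in 0/20 pure-IBD worlds, and detects IBD itself in 20/20 null
worlds.

What the generator does **not** emulate: coalescent or forward-in-time
genealogy, mutation models, linkage, Hardy–Weinberg departures, null
alleles or genotyping error, and any real geography.  Passing tests
therefore demonstrate that the statistical chain detects the cost structure
it assumes — not that microsatellite data from a real population satisfies
those assumptions.

## Numerical choices and problem sizes

* Permutations: 999 everywhere the screens run; 9,999 when checking the
  Monte-Carlo engine against exhaustive enumeration.
* Diagonals are stored as 0 and never enter any statistic.
* Covariance jitter 1e-8; nugget repair is refused beyond eigenvalue −1
  (a config far outside the calibrated regime).
* Test and acceptance problem sizes: 60 × 60 km grids with 100 individuals
  and 12 loci for signal-recovery runs (20 replicates per condition);
  30-individual worlds for structural and pipeline tests; n = 30 matrices
  with 500 replicates for type-I calibration; 1,000 random pairs on a
  50 × 50 grid for the supercover oracle.

## Known limitations

* Partial Mantel tests are known to show inflated type-I error when both
  matrices are strongly spatially autocorrelated; the calibration here is
  verified on independent inputs, matching the method's own assumptions.
* The straight-line transect is the study design, not a movement model;
  least-cost or circuit-theoretic distances are out of scope.
* The resistance weight grid is screened, not estimated; "best weight" is
  a model-selection convenience, not a calibrated cost estimate.
* Real-data mode (GENEPOP + locations CSV + two ESRI ASCII grids) is
  supported but exercised only synthetically in this repository.
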