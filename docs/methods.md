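# Methods

## Model

A species' thermal niche is summarised by four temperatures,
`SRZ_lower <= STZ_lower <= STZ_upper <= SRZ_upper`. The underlying
assumption is ecological: occupancy is densest at temperatures where
physiological costs are low, so the frequency curve of unique localities
against temperature rises steeply across the tolerance zone (STZ) and decays
through the resistance zone (SRZ). Each locality contributes two
temperatures taken from 12-month minimum and maximum temperature surfaces at
the containing raster cell: the coldest monthly minimum (`t_cold`) and the
minimum of the monthly maxima (`t_hot`). The latter deliberately understates
heat exposure; it is a proxy for night-time conditions, appropriate for
nocturnal taxa that shelter through the daily maximum. Cold- and hot-axis
samples are binned separately; `STZ_lower` is the inflection of the rising
flank of the cold histogram, `STZ_upper` the inflection of the falling flank
of the hot histogram, and the SRZ limits are the respective sample extremes.

This is an occupancy-based ("realised") niche: it conflates physiology with
range limits imposed by dispersal, biotic interactions and collection
effort, and inherits any spatial bias in the occurrence data.

## Record curation

Records are read from delimited text with a configurable column map; rows
with unparsable or out-of-range coordinates are skipped and counted rather
than fatal, because museum data are dirty. Exact-coordinate duplicates
(after rounding to 6 decimal places, which absorbs float noise from file
round-trips at ~0.1 m scale) collapse to one locality, keeping first-seen
order. Optional spatial thinning is a greedy pass in input order dropping
any locality within `min_km` (haversine, Earth radius 6371 km; default 1 km)
of one already retained: points at least 1 km apart always survive, and
whether sub-kilometre neighbours should be merged at all is left to the
caller (thinning is a separate, optional step from deduplication). Range
filtering keeps points inside or on the boundary of user-supplied polygons
(GeoJSON or shapely geometries, geographic WGS84).

## Rasters

Grids are ESRI ASCII format, 12 monthly minima plus 12 monthly maxima on a
shared geotransform. `scale` converts stored units to degC (0.1 for the
stored-tenths integer dialect, 1.0 for plain degC grids); quantising to
tenths bounds round-trip error by 0.05 degC. Point-to-cell mapping uses
half-open cell intervals with no interpolation — standard "extract value to
point" behaviour. A nodata cell in any band excludes the locality with a
report; silent nearest-neighbour filling would bias niche limits toward
whatever happens to border the gap.

## Inflection detection

The extremum distance estimator (EDE): on a sigmoid segment, with chord L
through the endpoints and deviations `d_i = y_i - L(x_i)`, the estimate is
`(x[argmax d] + x[argmin d]) / 2`, ties to the smallest index. It is exact
for symmetric sigmoids, equivariant under shifts of x, and invariant under
positive scaling of y. `ede_inflection` enforces the sigmoid contract
strictly: if the deviations never change sign the segment is entirely
convex or concave and a no-inflection error is raised.

Applying this to histogram flanks needs one adaptation. The flank chord
joins two points *on the curve itself* (the leftmost non-empty bin and the
mode bin), so the deviations vanish at both ends by construction, and the
deviation lobe adjacent to the mode is small — of the order of bin noise —
whenever the opposite tail is long. A strict sign-crossing test then fails
on a substantial fraction of perfectly well-behaved samples (for
Normal(10, 3) histograms at n = 5000 and 1 degC bins, roughly a third of
seeds). `estimate_niche` therefore takes the extremal deviations over the
flank *interior*: identical to strict EDE whenever a genuine crossing
exists, and degrading gracefully to the nearest-to-chord interior bin when
noise hides it. Measured over 200 seeded replicates of the scenario above
this gives bias ~0.7 degC (cold flank) and ~0.6 degC (hot flank) with zero
failures — within one bin width of the true density inflections mu ± sigma.

Flanks are split at the histogram mode (first-encountered if tied): the
flanks of a unimodal curve are the only sigmoid-shaped segments on which a
single inflection is defined. Flanks shorter than 4 bins refuse with an
error rather than guessing. Estimated STZ limits are clamped into the SRZ
interval (with a report) so the output always satisfies the niche ordering.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `bin_width` | 1 degC | histogram resolution; matches the granularity of monthly climate surfaces |
| `min_n` | 15 | minimum localities per axis before estimation is attempted |
| `smooth` / `smooth_window` | off / 3 | centred moving average applied to the histogram before inflection detection; reduces estimator variance roughly two-fold at the cost of smearing sharp flanks |
| `stz_lower_threshold` | 15 degC | summary-level flag for species whose tolerance zone reaches unusually cold temperatures |

## Variance diagnostics

For each subsample size m = 2..n, `variance_trajectory` records the mean
sample variance over `replicates` (default 100) random subsets, implemented
as running variances along random permutations (a permutation's length-m
prefix is a uniform random subset). Values are sorted before permuting so
the trajectory depends only on the multiset of values for a given seed.
`stabilization_check` replaces eyeballing the plot with a rule: stable at
the smallest m whose trailing `window` increments (default 10) have relative
range (max − min)/mean below `tol` (default 0.05). The rule is deliberately
config-exposed; it is not claimed to reproduce any particular published
stability labelling, for which no numeric rule exists.

## Comparative analyses

*Ancestral states.* Squared-change parsimony minimises
`sum over branches of (change)^2 / w` with `w` = branch length (weighted,
default when lengths exist) or 1 (unweighted). The optimum solves the graph
Laplacian linear system restricted to internal nodes — deterministic, and
every reconstructed value lies within the tip range. The weighted optimum at
the root equals the Brownian GLS phylogenetic mean computed from the tip
covariance matrix `C` (`C_ij` = shared root-to-MRCA path length), which the
test suite exploits as a closed-form oracle. Tips without trait values are
pruned with a warning; zero-length internal branches are collapsed to
polytomies before weighted reconstruction (configurable to a hard error).

*Phylogenetic signal.* Blomberg's
`K = (MSE0/MSE) / E[MSE0/MSE]`, with `MSE0` the mean squared tip deviation
from the GLS mean, `MSE` its `C^-1`-weighted counterpart, and
`E[MSE0/MSE] = (tr(C) - n/sum(C^-1)) / (n - 1)`. K is affinely invariant
and equals 1 exactly on equal-branch star trees. Significance uses the
variance of phylogenetically independent contrasts as the permutation
statistic: `p = (1 + #{permutations with contrast variance <= observed}) /
(n_perm + 1)` (default `n_perm` 999), so `p >= 1/(n_perm+1)` and identical
seeds give identical p. Polytomies are resolved arbitrarily with zero-length
internal edges before computing contrasts; this leaves `C` (hence K)
unchanged and keeps contrast denominators positive as long as terminal
branches are.

## Warming projection

Classification is on the hot axis (`t_hot` against `STZ_upper`/`SRZ_upper`),
since uniform warming moves localities across *upper* limits; limits are
inclusive on the tolerant side. Both reported percentages are integer-count
ratios over all localities: in-STZ before and in-SRZ after, and not-beyond
before but beyond `SRZ_upper` after. Both are monotone non-decreasing in the
warming increment, and invariant under duplicating the locality set. The
cross-species regression of impact on breadth is ordinary least squares with
the slope's two-sided p (equal to the regression F-test with one predictor).

## Synthetic data

The generators emulate the study conditions with known truth. Species
scenarios draw `t_cold ~ Normal(mu_cold, sigma_cold)` and `t_hot ~
Normal(mu_hot, sigma_hot)` and resample pairs violating `t_cold <= t_hot`
(scenarios whose hot mean sits more than 5 sigma below the cold mean are
rejected as infeasible); the true STZ limits are the analytic density
inflections `mu - sigma` / `mu + sigma`, making niche estimation a
parameter-recovery problem without circularity. The parameter-recovery suite
uses n = 5000 localities and 100 seeds — comparable to the best-sampled real
species — and the Brownian calibration suite 500 simulations on a fixed
16-tip tree, where the mean K over replicates falls in [0.85, 1.15].

What the generators do *not* emulate: spatial autocorrelation of real
climate surfaces, collection bias, coordinate error, and skewed or
multimodal temperature distributions. Passing recovery tests therefore shows
the estimator chain is correct under clean unimodal sampling, not that real
occurrence data meet those assumptions.

The packaged reference table ships the published niche limits for the 23
Glossophaginae species plus the mormoopid outgroup (*Pteronotus parnellii*),
with sample sizes, clade membership, and the variance-stabilisation flag.
The outgroup is excluded from 23-species summaries by default. Two genus
names printed inconsistently in the original are normalised to
*Choeroniscus*.

## Numerical choices and degenerate inputs

* Argmax/argmin ties everywhere resolve to the smallest index (determinism).
* Histograms are anchored at `floor(min/bin_width) * bin_width`; interior
  empty bins are retained; total count is conserved exactly.
* Fewer than 2 distinct values is a degenerate-distribution error; fewer
  than 4 flank bins an insufficient-resolution error; n < `min_n` an
  insufficient-data error.
* Sample-variance prefixes guard against catastrophic cancellation by
  clamping tiny negative sums of squares to zero.
* All stochastic routines take explicit integer seeds and are
  bit-reproducible given (parameters, seed).

## Known limitations

* STZ estimates carry a bias up to roughly one bin width toward the mode
  when one histogram tail is much longer than the flank's concave segment;
  smoothing reduces variance but not this bias.
* The EDE variant is the only inflection estimator implemented (no
  fitted-curve or ESE alternative).
* Squared-change parsimony and K assume the supplied branch lengths are
  meaningful; reconstructions on a tree with arbitrary lengths are only as
  good as those lengths.
* The warming projection applies a spatially uniform shift; it is a
  sensitivity analysis, not a downscaled climate scenario.
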