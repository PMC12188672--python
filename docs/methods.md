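# Methods

This note documents the model, the defaults and the numerical choices made
where the design was genuinely open, in enough detail to judge what the
package's results do and do not show.

## Signal preparation

Measured trajectories are short (typically ~10 timepoints over 24 h, mean
± sd over ~3 replicates). They are densified to 100 points with the cubic
spline of Forsythe, Malcolm and Moler: a C2-continuous interpolant whose
end conditions impose the third derivative of the exact cubic through the
four boundary knots, so the spline reproduces cubic polynomials exactly
and passes through every measurement. The implementation solves the
classical tridiagonal system for half second derivatives directly (no
installed Python spline offers these end conditions; the coefficients were
verified against R's `spline(method = "fmm")` to 5e-13 during
development). The dense grid is a uniform grid with the nearest uniform
point replaced by each knot, keeping the total at `n_out` (default 100)
while containing all knots exactly. Negative interpolated concentrations
are clipped to zero with a warning; error half-widths are interpolated
with the same spline and clipped at zero.

Uncertainty is propagated by curve resampling: 100 replicate curves drawn
uniformly and independently per grid point within ±(error half-width).
Pointwise (rather than whole-curve) sampling is the weakest assumption
consistent with "anywhere inside the band"; an optional `smooth=True` mode
draws offsets at the knots only and splines between them. Whole-curve
modes change Δ-magnitudes, not point estimates.

## Information flow

All information quantities are plug-in (maximum-likelihood) estimates in
bits over quantile-binned symbols, raw counts, `0·log 0 = 0`. Defaults:
**3 quantile bins, lag τ = 1 sample, Markov order 1** — chosen for the
very short series this package targets, where finer alphabets starve the
contingency tables; every setting is exposed in `ConeConfig` and the
pipeline configuration. Transfer entropy is clamped at zero when floating
error produces values above −1e−9.

Significance uses **circular-shift surrogates of the source** (100 by
default, significance level α = 0.10): rotation preserves the source's
autocorrelation and marginal while destroying cross-coupling, and the
p-value `(1 + #{TE_surr ≥ TE_obs}) / (1 + n_surr)` is exact under
exchangeability. On 200 independent AR(1) null pairs of length 200 the
test is calibrated (fraction with p ≤ 0.10 measured at 0.11 by the
acceptance suite). Rotation surrogates are deliberately conservative for
smooth, trend-dominated deterministic curves: two monotone trajectories
are never declared coupled, because a rotated monotone source predicts a
monotone target about as well as the original. Pairs whose target
trajectory has non-monotone structure (a concentration pulse) are the
detectable ones. This conservatism is a property of the null model, not a
bug; permissive shuffle-style nulls would declare almost any pair of
smooth curves significant.

Time-resolved TE splits the series into consecutive non-overlapping
chunks (default 10 × 10 points). Both series are discretized **once over
their full length**, and each chunk's TE is computed on the symbol
subarrays: a single alphabet makes chunk values comparable over time and
gives slowly varying species their characteristic flat (exactly zero)
profiles. Per-chunk re-binning would hand every chunk its own alphabet
and destroy both properties.

## Cone distances

The interaction volume `V` sums the TE of the significant directions
(p ≤ α); both directions null means no interaction and the pair enters
the distance matrix as 0 with a flag. Radii are the mean absolute first
difference of the chunk TE profile over chunk mid-times (central
differences optional). A **flat profile falls back per direction** to the
absolute least-squares slope of that node's own trajectory: a linear
course carries no resolvable information dynamics, so the propensity is
read from the concentration rate of change itself. The fallback is
per-direction because a radius of exactly zero would make the height
diverge whenever only one direction is flat — a common situation for
monotone trajectories. "Flat" means mean |difference| < 1e−12: exact
zeros arise structurally (constant symbols within every chunk), so no
looser tolerance is needed.

The height formula and its error propagation are evaluated exactly as
stated, including the dimensionally inhomogeneous `(ΔV)²` term of the
propagation formula; both reproduce the published per-pair values at
printed precision (40 of 41 interacting rows across the three
individuals; the remaining row, Individual 2 AS–ASoOH, is inconsistent
with its own cone parameters in the source tables and is flagged in the
packaged fixture). A dimensionally homogeneous variant
(`dh_variant="homogeneous"`, `(ΔV·q)²` under the root with `q` the base
polynomial) is available. ΔV and Δr are standard errors of the mean over
the 100 resampled curves; significance gating is decided once on the mean
curves and held fixed across replicates, so the spread measures estimator
variability rather than gate flipping.

## Embedding and geometry selection

The stress `(1/Ξ)·√Σ(h_ij − h*_ij)²` sums over **ordered** pairs (each
unordered pair twice) with Ξ = number of nodes. This convention reproduces
the published classical-MDS stresses of the case study to 6 significant
figures (0.8585136 vs 0.8585134, and 2.2776566 vs 2.277656); the
unordered variant (values 0.607/1.611) does not, and remains available as
a flag.

Euclidean embeddings: classical MDS (double centering, top-m non-negative
eigenpairs) and a graph-Laplacian spectral embedding with Gaussian
similarity weights `exp(−d²/2σ²)` on interacting pairs, σ = median
positive distance, coordinates from the m smallest non-trivial
eigenvectors, scaled by the single least-squares factor minimizing the
stress. The kernel construction disconnects pairs whose distance is many
multiples of σ (the weight underflows); the pipeline therefore exposes
`euclidean_method` and the synthetic end-to-end analysis uses classical
MDS, which has no such failure mode. For bare arrays a zero off-diagonal
distance means coincident nodes (full similarity); inside a pipeline
`DistanceMatrix` the no-interaction flags decide.

Curved embeddings diagonalize the curvature Gram matrix. Hyperbolic
(k < 0): the m most negative eigenpairs give space-like hyperboloid
coordinates `w_i`; because `diag(C) = 1`, the time coordinate is implied,
`x0_i = √(1+‖w_i‖²)`, and distances follow from the Minkowski product —
this reconstruction is **exact** whenever the input is exactly
hyperbolic, which the recovery tests exercise (stress < 1e−6 on sampled
hyperboloid point sets, 2-point distances to 1e−9). Normalizations that
divide `w` by `√(1−‖w‖²)` presuppose Klein-ball coordinates and break
exact recovery; they are not applied to the distance computation.
Poincaré-disk coordinates `u_i = w_i/(1+x0_i)` (always inside the unit
disk) are exported for plotting. Spherical (k > 0): the m+1 largest
positive eigenpairs, row-normalized to the unit sphere, distances
`arccos(⟨v_i,v_j⟩)/√k`; requires `√k·max(d) ≤ π`, otherwise the space is
skipped with a warning rather than aborting the run. Embeddability
verdicts follow the eigenvalue-sign conditions (hyperbolic: exactly one
positive and at most m negative; spherical: no negative and at most m+1
positive), with zero tolerance 1e−9·max|λ|; when the conditions fail the
dominant eigenpairs give the approximate embedding. Geometry selection is
argmin stress with ties preferring Euclidean, then hyperbolic, then
spherical (flat space is the weaker claim). Default curvatures ±1,
dimension m = 2.

## Bottleneck classification

The triangle threshold builds a histogram over [min, max] (256 bins by
default), draws the line from the top of the peak bin to the base of the
farthest non-empty bin, and returns the midpoint of the bin with the
maximal perpendicular distance to that line (ties to the lower bin); it
agrees exactly with an exhaustive per-bin search and with
scikit-image's implementation on shared inputs. The elbow characteristically
sits just beyond the dominant peak. 256 bins suit pools of a few dozen
values (the case-study tables); for a handful of values the histogram
degenerates into singletons and a Sturges-scale bin count (the synthetic
pipeline uses 16) keeps the threshold meaningful — the bin count is part
of the analysis configuration.

A pair is a bottleneck iff both radii fall below the (pooled, by default)
radius threshold and its embedded distance in the selected geometry is at
or above the distance threshold. The distance condition uses "large"
(prose sense): bottlenecks are far-apart low-propensity links; the
inverted "small" mode is available. Non-interacting pairs are excluded
throughout; classification runs over the pairs supplied (an interaction
graph when given, otherwise all pairs) — bottlenecks are properties of
*reactions*, so handing the method the known reaction edges is the
intended use.

## Synthetic data

`CascadeSpec`/`simulate_cascade` generate linear first-order mass-action
cascades `dC/dt = K·C` (conversion edges plus optional first-order
elimination — the standard open-compartment picture) solved exactly with
the matrix exponential. Replicate scatter is multiplicative log-normal
with unit mean (default level 0.1, emulating LC-MS-style relative error),
summarized as mean ± sd across 3 replicates on 10 timepoints over 24 h —
the shape of the study data. What the generator does **not** emulate:
intrinsic kinetic stochasticity, enzyme saturation, correlated
measurement error across species, missing values, and limit-of-detection
censoring. Passing tests therefore demonstrate the machinery on clean
first-order kinetics, not robustness to those real-data features.

`bottleneck_scenario` is the designed end-to-end experiment: a bolus
parent P converts fast (0.5/h) to a hub L whose concentration pulses; L
drains through a three-stage chain so the terminal product rises late, and
through one weak (0.02/h), slow conversion to N1, itself cleared at 0.3/h
so it traces a small delayed pulse. The analysis graph is the hub's three
couplings. The design exploits the estimator's structure deliberately:
pairs with a pulse target are rotation-significant with large margin
(exact rotation-null fractions ≤ 0.03, and 0.00 for the weak pair at the
chosen clearance rate), every strong pair has one flat TE profile that
falls back to a steep trajectory slope, and only the weak pair has two
time-varying profiles with tiny derivatives — hence the unique towering
cone height. Replicate noise default 0.05; the flags were verified stable
over 50 simulation seeds at noise 0.02 and 0.05 before freezing the
defaults. `generate_null_pair` provides independent AR(1) series
(coefficient 0.3, unit variance, mean offset 10 to stay positive) for
type-I calibration.

## Known limitations

- Plug-in TE on ≤100 points with 3 symbols has a positive small-sample
  bias of order 0.1 bits; absolute TE values are not comparable across
  estimator settings, and the published per-pair TE magnitudes of the
  case study are not reproducible without the original estimator
  configuration (which is why the packaged fixtures carry the printed
  values rather than re-estimates).
- Radii derived from chunked TE inherit chunk-level estimation noise;
  their meaningful signal is the flat-vs-varying distinction and order of
  magnitude, not the third decimal.
- The spectral Euclidean embedder's kernel bandwidth (median distance) is
  a heuristic; matrices whose distances span many orders of magnitude
  should use the classical-MDS route.
- Distances exceeding π/√k have no spherical embedding at curvature k;
  the pipeline records the skip rather than rescaling k, since curvature
  is part of the hypothesis being compared.
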