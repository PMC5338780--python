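# Methods

## Study design the package encodes

A central-place forager breeds at a fixed colony and makes repeated foraging
trips; individual specialisation means an individual's behaviour (where it
goes, how deep it dives, what it eats) is persistently narrower than the
population's repertoire, beyond what sex or morphology explain. The package
measures this at three timescales: consecutive trips within a breeding stage
(GPS/TDR metrics and their CVs), between stages of one season (blood
isotopes at incubation vs chick-rearing, stage co-clustering), and between
breeding and moult (feather vs blood isotopes).

## Track processing

Fixes are WGS84 lat/lon with strictly increasing timestamps. Distances are
haversine on a 6371-km sphere. The speed filter is a single forward pass:
each fix is tested against the last retained fix and dropped when the
implied speed exceeds 18 m s⁻¹ (the first fix is always kept). This is
idempotent and deterministic; a multi-pass root-mean-square variant was not
needed for the error model simulated here (isolated displaced fixes).

Trip segmentation replaces visual inspection with an explicit rule: maximal
runs of fixes farther than `colony_radius_km` (default 0.2 km) from the
colony, padded with the nearest bounding at-colony fix, discarding runs
shorter than 10 min or 5 fixes. All three thresholds are configurable; the
defaults are a deterministic surrogate for judgement-based segmentation, so
the absolute trip count on real data would depend on them.

Heading is the initial great-circle bearing from the colony to the fix at
maximum colony distance, in (−180°, 180°] (so a slightly-west-of-north
strategy reads as a small negative heading rather than ~359°). Interpolation
to 1 Hz is linear in raw lat/lon — at coastal foraging scales (≤ 30 km) the
curvature error is far below GPS noise; gaps longer than 30 min are flagged
but still interpolated.

Rasterization projects positions to east/north km offsets with a
colony-anchored equirectangular projection (x = Δlon·111.320·cos φ_colony,
y = Δlat·110.574) and floors them into `cell_km` squares with the colony at
a cell corner. The projection is deliberately simple: no external CRS
database, exactly invertible (the simulator uses the inverse), and its
distance distortion over these ranges (~0.1%) is irrelevant to cell
membership except exactly on cell boundaries.

## Dive processing

Zero-offset correction subtracts a centred rolling 5%-quantile baseline
(600-s window): surface drift is slow, so the lower quantile of a window
that contains surface time tracks the drifting zero. Records shorter than
the window are left uncorrected. Dives are maximal runs with corrected
depth > 1 m, extended to the bracketing 1-m crossings by linear
interpolation of time; sub-2-s spikes are discarded as sensor noise.
Vertical distance integrates |Δdepth| between the crossing points, so every
dive satisfies vertical ≥ 2·(max depth − threshold). Dives are
georeferenced at their start time (the surface position before descent;
the bird is nearly stationary underwater). Whether the 1-m rule should
apply to raw or corrected depth is ambiguous in the field; corrected depth
is used, which is the stricter and more physical choice.

## Consistency statistics

CVs use the n−1 sample SD over the mean and require ≥ 2 trips. Circular
mean/SD of headings use the resultant vector: mean = atan2(Σsin, Σcos),
SD = √(−2 ln R̄) in radians (+∞ for a perfectly balanced direction set).
Radians are the natural unit here; typical per-individual values are
0.1–0.8.

The space-use consistency index divides the mean pairwise shared-cell count
(all unordered trip pairs, unweighted) by the mean per-trip cell count.
This literal ratio-of-means is the default; the mean of per-pair ratios
(|A∩B| / mean(|A|,|B|)) is available as `method="mean_of_ratios"`. One
subtlety found by property testing: *adding a duplicate of one trip* can
lower the ratio-of-means index when other trips overlap poorly (the
duplicate contributes many zero-overlap pairs), so monotonicity holds only
pairwise — the index is a population summary, not a per-trip score.

## Variance components and mixed models

The specialisation statistic is the percentage of total variance at the
individual level of y = μ + a_ind + b_trip(ind) + e (all effects Gaussian,
homoscedastic). Estimation is REML with β and σ²_resid profiled out
analytically and the variance ratios θ_k = σ²_k/σ²_resid maximised
numerically under θ ≥ 0 (L-BFGS-B from several starts, Nelder–Mead
polish). The covariance is block-diagonal by individual, so each likelihood
evaluation is O(Σ nᵢ³). Bounded optimisation truncates negative components
at zero (flagged `boundary`). On balanced designs with interior solutions
the estimates agree with the closed-form nested-ANOVA (method-of-moments)
estimators to ~10⁻⁷ relative, which the tests assert; statsmodels MixedLM
is a second, independent cross-check.

Degenerate layouts are resolved explicitly rather than left to the
optimiser: a constant response → all-zero decomposition; one observation
per trip → trip and residual coincide, the within-individual variance is
reported at the trip level (`trip-equals-residual`); one trip per
individual → the trip level is unidentifiable and dropped; exactly zero
within-trip variance → the likelihood is singular and moment estimates on
trip means are used (`singular`).

The same core fits random-intercept covariate models (Wald SEs from the
classical GLS formula σ̂²(XᵀW⁻¹X)⁻¹, conservative df = groups − p) and
maximum-likelihood versions for likelihood-ratio tests of a cluster factor.
The published analysis's heteroscedastic residual structures (power-of-mean
and per-group variances) and backward-stepwise selection are deliberately
not reimplemented: with a dozen groups they change point estimates little
and would multiply the estimator surface; stated models are fit directly.
Pairwise cluster contrasts are descriptive Welch t-tests rather than Tukey
HSD. A sampling caveat that matters when reading single runs: with a
individuals the variance-share estimate has irreducible sampling SD of
roughly p(1−p)·√(2/(a−1)) — about ±10 percentage points at a = 12 — so a
single colony's estimate can sit far from the generating parameter even
though the estimator exactly recovers the *realised* decomposition (the
test suite verifies both, the latter over 200 replicates).

## Clustering

Profiles are standardized per column (n−1 SD; zero-variance columns
dropped), with the circular mean heading encoded as a (cos, sin) pair
before z-scoring so that 359° and 1° are neighbours. Agglomeration is Ward
via scipy with heights converted to the within-cluster sum-of-squares
increase (ΔSS = d²/2), which makes heights sum exactly to the one-cluster
total within-SS — asserted as an invariant, and the merge sequence is
checked against a brute-force greedy-ΔSS oracle. The cluster count
maximises the relative jump between successive merge heights over
2…min(8, n−1) — a deliberately simple surrogate for factor-map-based
cluster selection (no PCA preprocessing, no k-means consolidation). Default
features are the spatial means and CVs plus heading dispersion and the
consistency index; the list is configurable.

## Isotopes and diet

Blood samples with C:N ≥ 3.5 are flagged for lipid bias (feathers are
keratin and exempt). Consistency regressions (late-on-early within a
season; feather-on-blood across seasons) use a pair-level random intercept
where pairs repeat and plain OLS otherwise, and also report Pearson r.

Diet composition reproduces the standard four-column table from long-format
sample × species counts. Percentages are half-up rounded at one decimal —
with 222 items several species sit at exactly 1/222 = 0.45%, where
round-half-even would print 0.4 instead of the published 0.5. "Individuals
associated" is counted at the sample level (denominator = number of
samples): with the published 26 samples this reproduces the printed
percentages exactly (21/26 = 80.8). The shipped fixture stores only the
published marginals; `reconstruct_prey_samples()` builds *a* synthetic
sample × species matrix consistent with them (documented as synthetic) so
the composition arithmetic can be exercised end to end.

## The synthetic colony

The generator emulates the statistical structure the estimators assume, at
the scale of the motivating study (defaults): 12 individuals, 4–10 trips
each, 1-min GPS fixes, 1-Hz depth records, one-way trip distances lognormal
around 10 km, travel at 1.5 m s⁻¹ (an effective over-ground speed mixing
flight and surface foraging, giving ~4-h trips), dive-depth variance
components (145, 100, 4) m² around a 25-m mean, isotope SD 1.2‰ with
between-tissue correlation 0.9 and a +0.56‰ incubation offset for blood
δ¹⁵N, and sparse Dirichlet(0.3) prey preferences over the 13-species prey
list. Trips are out-and-back straight walks with 15-m lateral jitter in
colony-anchored planar km, back-projected through the same equirectangular
transform the rasterizer uses; dives are V-shaped excursions placed in the
distal third of each trip with apex depths drawn from the nested model
(clipped at 1.6 m — about 2% of dives at the default variances, which
slightly compresses the realised individual component below its nominal
value). A planted-strategy mode assigns individuals to k strategies for
clustering-recovery experiments; a strategy is jointly a heading sector, a
distance regime and a consistency level (per-strategy von Mises κ and
within-individual distance spread), so planted clusters separate in every
clustered feature — means, CVs, heading dispersion and the consistency
index — with tight between-individual spread within a strategy. One design
lesson is baked in: a strategy defined by *extreme* inconsistency cannot
form a tight cluster, because its own realized consistency statistics
scatter; the dispersed strategy therefore uses a moderate κ. Recovery
experiments give each bird 6–10 trips, the upper half of the study range,
where estimated CVs and indices have the precision a fixed between-cluster
separation presumes. All randomness derives from one master seed via per-individual
substreams; outputs are bit-reproducible.

What the simulator does *not* emulate — and hence what passing tests do not
show about field data: tortuous search paths and area-restricted search
(tracks are near-straight, so consistency indices are driven by heading and
distance repeatability), location error beyond white jitter, bathymetry
(dive depths are statistical, not benthic), tidal or diel structure, and
prey-switching within a stage.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately reduced designs (4–30 individuals,
3–6 km or default 10 km trips, 4–20 dives per trip) chosen so each check
still has the statistical resolution it needs: e.g. grid-size robustness
uses the default 10-km range because a 5-km grid quantises shorter trips
into 1–3 cells and destroys rank resolution, while estimator-equivalence
checks run at 120–360 observations where REML/ANOVA agreement to 10⁻⁶ is
well inside optimiser precision. Tolerances: 1e-6 relative for
estimator-oracle identities, 0.1 m for dive-depth recovery (1-Hz sampling),
0.5° for heading recovery of noiseless walks (projection curvature), and
Monte-Carlo-scaled bounds for recovery studies. Ties in Ward merges are
broken by scipy's deterministic ordering; ties in dominant-prey counts are
broken alphabetically and flagged.

## Known limitations

Homoscedastic residuals throughout; no Satterthwaite/Kenward–Roger df; no
kernel home ranges or utilisation-distribution overlap (the grid index is
the point); no behavioural-state segmentation; the trip-boundary rule is a
declared surrogate, so absolute trip counts on real data depend on its
thresholds; single-colony geometry (one central place) only.
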