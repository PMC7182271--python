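# Methods

`geodose` simulates and executes an iterative geostatistical protocol for
mapping population-scale radiation exposures from a small number of dose
measurements. This note records the model, the choices that were genuinely
open, and what the synthetic experiments do and do not demonstrate.

## The protocol

1. **Initial sampling.** Every census-like subdivision that overlaps the
   plume, or shares a boundary with one that does, contributes uniform random
   locations equal to a fraction of its population (default 0.1%,
   round-half-up per subdivision). Locations outside the plume measure 0 Gy;
   these background points are essential — they bound the interpolated plume —
   but are deliberately restricted to the surrounding subdivisions so they do
   not depress it.
2. **Kriging.** The measured doses are interpolated onto a regular grid
   (default 200×200 over the sampled subdivisions plus a 10% margin),
   producing a dose prediction and a kriging standard error per cell.
   The default engine is the ensemble variant described below; ordinary,
   simple and universal kriging are available for method comparison.
3. **Densification.** Cells whose Gaussian upper-quartile dose
   (prediction + 0.6745·SE) reaches the 2 Gy treatment threshold are ranked
   by descending standard error; up to 200 become the next round of sampling
   locations, after greedy spacing suppression (2 cells), deduplication
   against every existing sample (tolerance one cell), and exclusion of the
   confirmed-background envelope (subdivisions whose every sample so far read
   0 Gy and which do not touch the current plume).
4. **Convergence.** Each new plume is compared with its predecessor on the
   eight dose bands <1, 1–2, …, 6–7, >7 Gy through the band-overlap heat
   matrix. Cell (i, j) holds the symmetric mean overlap
   ½(|Cᵢ∩Pⱼ|/|Cᵢ| + |Cᵢ∩Pⱼ|/|Pⱼ|); the matrix is the identity iff the plumes
   coincide. Two diagonal summaries are tested: BCD = Σ|1−Aᵢ| / Σ(1+Aᵢ) and
   RMSD = √(mean (1−Aᵢ)²). For a uniform diagonal a these equal (1−a)/(1+a)
   and 1−a, so the 90%-overlap stopping rule is BCD < 1/19 or RMSD < 0.1
   (strict; the 99% stringency mode uses 1/199 and 0.01). Iteration also
   stops when densification proposes nothing new (premature stabilization)
   or at the iteration cap (default 15). Iteration 1 is the initial kriging
   pass, so reported counts are kriging passes.
5. **Scoring.** The converged plume is scored against ground truth after
   projecting the truth into the same gridded representation (ordinary
   kriging of the contour vertices, zero nugget). Area overlaps become
   populations by uniform within-subdivision density:
   pop(region) = Σ area(region ∩ subdivision) · population/area. Reported are
   the population-weighted recall of the true ≥2 Gy and ≥3 Gy territory and
   the false-positive fraction of the derived ≥2 Gy population.

## Synthetic ground truth

Real deployments would take ground truth from an atmospheric dispersion
model; the package generates a stand-in whose *contour representation*
matches what the pipeline consumes: nested simple rings at 0.5 Gy increments
(0.5 … 8.0 Gy by default, so the ≥7 Gy invariant of detonation scenarios
holds), each traced by ~4000 equal-arc-length vertices.

The underlying field is a downwind-skewed anisotropic Gaussian "teardrop":
in plume-local coordinates (u downwind, v crosswind),
F = A·exp(−½(u²/s(u)² + v²/c(u)²)), with the downwind scale four times the
upwind scale and the crosswind scale widening from 45% to 100% of its nominal
value along the plume. The amplitude sits half a contour step above the
configured peak dose so the top ring is a genuine polygon. A seeded low-order
angular Fourier perturbation (default ±4%, suppressed near the epicenter)
roughens the rings; because superlevel sets of any scalar field nest, the
ring-nesting invariant survives it. Rain and snow variants rescale
length/width by fixed factors (0.85/0.90 and 0.80/0.85) — precipitation
scavenging shortens and narrows the footprint without changing its
morphology.

True dose at a point is the level of the innermost ring containing it — the
outer boundary of the band the point falls in. This step-function convention
is a deliberate, known source of systematic error in the simulated protocol.

Population maps tile the region with the Voronoi cells of seeded random
points. Each subdivision draws its density uniformly from the regime band —
urban 4200–7000 /km², rural 100–1000 /km², straddling the 10,000 per square
mile (3861 /km²) urban/rural boundary — and an explicitly configured total
population is apportioned by largest remainder, so totals conserve exactly.

**What the generator does not emulate:** terrain and deposition physics,
time-dependent plume evolution and decay, non-uniform within-subdivision
population, and infrastructure shielding. Passing tests therefore show that
the *protocol* reconstructs a plume of realistic shape and scale from sparse
samples; they do not validate transport physics, and accuracies against this
smooth synthetic truth run higher than against a rough dispersion-model
plume.

## Kriging engine

Classical variants solve the standard semivariogram-form systems densely:
ordinary (weights constrained to sum to 1), simple (known mean, default the
sample mean), universal (first-order coordinate drift). Semivariogram
families are exponential (default), spherical and Gaussian, parameterized by
nugget, partial sill and practical range; fitting is pair-count-weighted
least squares on the binned empirical semivariogram, with a flat-heuristic
fallback on optimizer failure. Up to 500 samples the system is factored once
and solved against all grid cells; beyond that a k-nearest neighborhood
(default k = 32) is solved per cell in batched stacked systems. Predictions
are clamped at 0 Gy and variances at 0. Duplicate coordinates are removed
before solving. An optional window mask restricts estimation to an expanded
box around the irradiated samples; outside it the prediction is 0 and the
standard error is the prior standard deviation.

The ensemble variant approximates empirical Bayesian kriging — the
proprietary GIS procedure is not publicly specified, so this is declared as
an approximation, not a reimplementation. Samples are partitioned into
spatial localities (default 10 for standalone use; the pipeline default is 8
localities × 6 models, chosen to keep a full scenario replicate near half a
minute on one core). Each locality receives a restricted-maximum-likelihood
base fit (REML integrates out the unknown mean) on at most 80 points, plus
n_sims − 1 models obtained by simulating Gaussian data from the base fit and
refitting by weighted least squares. Cells are predicted by their nearest
locality as a mixture of per-model ordinary-kriging predictions, weighted by
per-observation mean log-likelihood of the observed data; the mixture
variance adds the between-model spread to the within-model kriging variance,
so the ensemble standard error is never below the best member's. With one
locality and one model the variant reduces exactly to ordinary kriging with
the REML fit.

Three stabilization choices matter inside the iterative pipeline, where
consecutive surfaces must differ only through the added samples: the
ensemble seed and locality centroids are fixed per replicate rather than
re-drawn per iteration; the REML subsample is selected by a coordinate-keyed
priority so a growing sample set displaces only a few members; and raw
likelihood weights are tempered to per-observation means (over ~80 points
raw weights are winner-take-all, and the winning model flipping between
iterations masquerades as plume change).

## Numerical and design choices

- **Band extraction is pixel-exact:** a cell with predicted dose in
  [k, k+1) Gy belongs to band k; band polygons are unions of run-length cell
  rectangles. Bands therefore partition the >0 Gy region exactly and their
  polygon areas equal cell counts times cell area, at the cost of contour
  smoothness at sub-cell scale.
- **Empty bands:** a diagonal overlap where both bands are empty counts as 1
  (no disagreement — outer bands often vanish in weak plumes); an overlap
  where exactly one side is empty counts as 0.
- **Thresholds are strict inequalities** ("dropped below").
- **Quota rounding** is round-half-up; **rejection sampling** draws points
  strictly inside subdivision polygons; **adjacency** means a shared boundary
  segment, not a corner touch.
- **Negative measured doses** after error injection are clamped to 0 Gy.
- **Degenerate inputs:** fewer than 2 distinct sample locations, all-zero
  quotas, or a plume intersecting no subdivision raise typed errors; a
  replicate that draws zero irradiated samples is reported as a failed run,
  not an exception.
- **Determinism:** every stochastic component draws from a named substream
  of the replicate seed (sampling, error injection per iteration, ensemble),
  so a run is a pure function of configuration and seed, and perturbation
  variants are seed-comparable. The 99% stringency mode replays an identical
  iteration prefix and can therefore never stop earlier than the 90% mode.

## Default study conditions

The default urban scenario — epicenter at the origin, bearing 60°, 8 km ×
2.5 km plume footprint, 8 Gy peak, nine urban subdivisions over a
20 km × 20 km region, 0.1% sampling — was sized so that initial draws yield
roughly 60–170 irradiated samples out of ~2000 and converged runs accumulate
roughly 300–450, comparable in order of magnitude to published field-scale
simulations, while one replicate (200×200 grid, 8×6 ensemble) completes in
tens of seconds on a single core. Test ensembles use fixed seed sets; the
statistical checks (majority metric convergence in 3–10 iterations, mean
≥2 Gy recall above 60%, error-ordering trends) are computed over those
ensembles and are fully reproducible.

## Known limitations

- The ensemble variant is an approximation of proprietary EBK; subset sizes,
  overlaps and priors of the original are undocumented.
- Pixel-exact bands make small high-dose bands sensitive to single-cell
  changes; with very coarse grids this inflates BCD/RMSD jitter.
- Measurement error raises the fitted nugget, which smooths consecutive
  surfaces; error-laden runs can therefore stop *earlier* than error-free
  ones on smooth synthetic truth, even though their accuracy is worse.
- Multi-part (non-simply-connected) ground-truth contours are unsupported on
  import.
- Planar kilometres throughout; the lon/lat shim is equirectangular and only
  suitable for city-scale extents.
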