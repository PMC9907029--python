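# Methods

## The model

`centimix` models a cross-sectional distribution of global amyloid-PET
burden on the Centiloid (CL) scale — anchored at 0 CL (no amyloid, as in
young controls) and 100 CL (typical mild–moderate Alzheimer's dementia
load) — as a three-part mixture:

    f(x) = π_n · N(x; μ_n, σ_n²) + π_i · g(x) + π_p · N(x; μ_p, σ_p²)

The negative Gaussian describes amyloid-negative scans (centred near 0 CL),
the positive Gaussian established amyloid pathology (near 100 CL). The
intermediate component g is a partial-volume ("mixel") marginal borrowed
from MRI voxel classification: an intermediate scan is a convex mixture of
the two pure classes with mixing fraction α ~ U(0, 1), Gaussian
conditional on α with mean (1−α)μ_n + αμ_p and SD (1−α)σ_n + ασ_p,

    g(x) = ∫₀¹ N(x; (1−α)μ_n + αμ_p, ((1−α)σ_n + ασ_p)²) dα.

g is fully tied to the two Gaussians: the model has exactly seven free
parameters (π_n, π_i, π_p summing to 1; μ_n < μ_p; σ_n, σ_p). The linear
interpolation of the SD in α is the simplest tying consistent with the
mixel construction; the functional form is isolated behind
`intermediate_pdf` so an alternative tying can be swapped in at one place.
In the zero-noise limit g degenerates to the uniform density of height
1/(μ_p − μ_n) on [μ_n, μ_p].

## Fitting

Parameters are estimated by a constrained EM:

* **E-step** — responsibilities from the three weighted densities.
* **M-step** — all three proportions update from mean responsibilities;
  the Gaussian means/SDs update by responsibility-weighted moments using
  the *Gaussian* responsibilities only; the intermediate density is then
  recomputed from the updated Gaussians. The intermediate component
  therefore contributes nothing to the location/scale updates — only its
  proportion is estimated.

Because the tied component's density depends on the Gaussian parameters
but is ignored in their update, this is not a textbook EM step and
monotone ascent of the log-likelihood is not guaranteed in theory. The
fitter records the full log-likelihood trace and counts any decrease
beyond a 1e-8 relative slack (`monotone_violations`) instead of asserting
monotonicity; in practice we observe none on the preset cohort shapes.

Numerical choices:

* g(x) is evaluated by fixed-node Gauss–Legendre quadrature on α ∈ [0, 1]
  (`quad_nodes`, default 64). The quadrature resolves the integrand only
  when the node spacing mapped to CL (≈ (μ_p−μ_n)/nodes) is finer than the
  component SDs; for near-degenerate SDs use more nodes (the zero-noise
  tests use 512).
* During fitting g is recomputed once per iteration on a fixed 0.5-CL grid
  spanning the data and linearly interpolated at the data points; at this
  step the interpolation error is far below the density scale.
* Convergence: relative log-likelihood change < `rel_tol` (default 1e-6);
  iteration cap `max_iter` = 500.
* `sigma_floor` (default 0.5 CL) clamps both SDs; clamps are counted in
  the result, never fatal, so bootstrap loops survive degenerate
  resamples.
* Label switching is resolved by relabeling every result so μ_n < μ_p
  (the intermediate component is symmetric under the exchange).
* `n_starts` (default 5) random initializations; means drawn uniformly on
  the two median-split halves of the data range, SDs on [0.25, 1]× the
  sample SD, proportions flat on the simplex; best final log-likelihood
  wins. Failed starts are dropped; if no start converges the best-so-far
  result is returned flagged `converged=False`.

With `include_intermediate=False` the model reduces exactly to a
two-component GMM (π_i pinned at 0), which is cross-checked against
scikit-learn's `GaussianMixture` in the test suite.

## Bootstrap inference

Spread estimates are percentile bootstrap CIs: each replicate resamples
the cohort with replacement, draws one fresh random initialization, fits,
and is relabeled; the 95% CI is the 2.5th/97.5th empirical percentile of
the converged replicates (non-converged ones are excluded and counted; a
summary with fewer than half its replicates converged is flagged
unreliable). Percentile rather than BCa intervals are the minimal reading
of a "95% confidence interval", and B is a setting: the package default is
1,000, the validation suites run 150–500, and production analyses can use
100,000 — the estimator is identical, only quantile noise changes.
Per-replicate RNG streams derive from (master seed, replicate index), so
summaries are reproducible and order-independent.

Tracer (or any stratum) equivalence is declared mechanically: fit each
stratum separately under the same model settings and check per-parameter
CI overlap; the overall verdict is the conjunction over all seven
parameters.

## Classification and cut-points

Scans are labeled by posterior argmax over the three components;
cut-points are the CL values where adjacent weighted component densities
(equivalently, posteriors) cross, located by scanning plus Brent's method
inside the open interval (μ_n, μ_p) — crossings outside it are tail
artifacts and ignored. When π_i ≈ 0 a boundary may have no crossing; it is
reported absent. The three-class argmax rule is this package's
construction (clinical practice reads scans binary negative/positive); a
`collapse_intermediate` flag folds intermediate calls onto the nearest
side for a binary reading.

## Synthetic cohorts

The generator is the exact sampling inverse of the model. Two presets fix
the study conditions:

| preset | n | π_n, π_i, π_p | μ_n, μ_p (CL) | σ_n, σ_p (CL) |
|---|---|---|---|---|
| `dpms` | 840 | 0.45, 0.10, 0.45 | 0.42, 92.52 | 7, 30 |
| `pnhs` | 1600 | 0.73, 0.20, 0.07 | 0.00, 92.52 | 7, 30 |

The means for `dpms` and the intermediate/positive proportions for `pnhs`
are published point estimates for the corresponding populations; the
remaining values are package defaults chosen once to reproduce the
qualitative shapes of the two observed distributions (a clearly bimodal
memory-clinic distribution; a pre-dementia distribution dominated by a
near-zero Gaussian skewed toward higher values). All values live in one
editable `presets.yaml` so reported and default values stay separable.
Latent component labels are retained with every draw for accuracy scoring
but hidden from fitting. The generator emulates only the marginal CL
distribution: no covariates (age, APOE), no longitudinal structure, no
site or scanner effects, and tracer labels are assigned independently of
CL value — so passing recovery tests demonstrates correctness of the
estimator under the model, not robustness to real-data artifacts such as
tracer-dependent scaling or heavy-tailed measurement error.

## Identifiability limits

The mixel density at α near 0 or 1 is nearly indistinguishable from the
adjacent pure Gaussian, so (π_i, π_p, μ_p) sit on a flat likelihood ridge:
on a bimodal cohort of n = 10,000 a fit with π_i inflated by ~0.03 and μ_p
shifted by ~1.5 CL can exceed the generating parameters' log-likelihood.
This is a property of the model, not the optimizer (EM started at the
generating values stays there). Consequences: single-cohort estimates of
π_i and μ_p carry a few-percent/few-CL systematic spread beyond sampling
noise, while μ_n, σ_n and the negative proportion are sharply identified.
The validation tolerances (±1 CL on μ_n, ±3 CL on μ_p, ±0.02–0.04 on
proportions across 20 cohorts) reflect this.

## Validation suite scales

The test suite's summative experiments run at desk scale: 20 cohorts per
recovery study; 100 repetitions at B = 200 for CI coverage of μ_n; 100
repetition pairs at B = 150 for the strata-overlap mechanic. These sizes
keep the whole suite in the tens of minutes on one CPU while leaving the
binomial noise of the coverage/overlap counts well inside the asserted
margins.

## Known limitations

* The tied M-step is a heuristic fixed-point scheme; its stationary points
  need not be exact maximum-likelihood estimates (observed discrepancies
  are well below sampling noise at the preset scales).
* Percentile CIs are first-order; no BCa or studentized correction.
* No model selection: the number of components is fixed at three (or two).
* Cut-points are population-level summaries of the fitted model, not
  validated clinical thresholds.
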