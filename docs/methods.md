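# Methods

## Model

`hic3d` treats a binned intra-chromosomal Hi-C contact map as noisy pair
data generated by an unobserved 3D polymer conformation. For each track
(one restriction enzyme's map) c and each pair of available loci
i < j in G(c):

    n_ij ~ Poisson(mu_ij)
    ln mu_ij = beta_c0 + beta_c1 ln d_ij + sum_k beta_ck ln(x_ik x_jk)

with d_ij the Euclidean distance between coordinates S_i and S_j.
The log-linear distance term encodes the empirical power law between
contact frequency and spatial distance; `beta_c1` is fitted per track,
because different enzymes genuinely produce different decay exponents and
pooling maps with discordant exponents breaks additivity. The covariate
products absorb multiplicative per-locus biases (fragment length, GC,
mappability). Two modeling conventions worth stating explicitly:

* **Zero entries are data.** The Poisson sum runs over *all* available
  pairs; an unobserved contact contributes −mu_ij. Dropping zeros would
  bias structures toward uniform compaction.
* **Normalized maps** replace the count with the normalized intensity and
  drop the covariate term (quasi-Poisson: the score equations never use
  integrality). Raw maps require integer counts.

Consecutive modeled loci carry a Gaussian chain prior
S_i | S_{i−1} ~ N(A S_{i−1} + b, (1/λ) I₃), here with A = I₃ and b = 0,
whose log-density is the quadratic penalty
−λ · g(l_i − l_{i−1}) · ‖S_{l_i} − S_{l_{i−1}}‖². The penalty carries a
*negative* sign in the total log-likelihood — it is a prior density, and
treating it as a reward would make the likelihood unbounded; the package
implements it as a penalty throughout. Its additive constant
−3(n−1)/2 · ln 2π is dropped during optimization (it cannot affect the
argmax) but is reported in `LogLikTerms`.

The gap weight g is configurable because the intent of scaling the
penalty by the genomic gap between consecutive *modeled* loci is
ambiguous: `linear_gap` (g = Δl, the default) penalizes long-gap
jumps harder, `inverse_gap` (g = 1/Δl) encodes the polymer-physics view
that positional variance grows with genomic separation, and `uniform`
ignores gaps. On the simulated benchmarks all loci are contiguous
(Δl = 1) and the three modes coincide.

### Smoothing weight policy

λ = 0 recovers a pure GLM fit. The default (`lambda_policy="auto"`)
enables smoothing (λ = 1) when any track's signal coverage — the
fraction of non-zero upper-triangle entries — is below 10 %, and
disables it otherwise; the benchmarks show smoothing is decisively
helpful at 10 % coverage and mildly helpful at 30 %. During structure
initialization a much stronger weight, λ_init = ⌈√n⌉, keeps the chain
coherent while most loci are still unplaced. Both are exposed in
`FitConfig`.

## Fitting algorithm

1. **Coefficient initialization.** Per-track Poisson regression of
   counts on the log covariate products *without* the distance term,
   by iteratively reweighted least squares (IRLS) with step halving;
   `beta_c1` starts at −1.
2. **Sequential structure initialization.** S_{l_1} = 0; each subsequent
   locus maximizes the partial log-likelihood against its previous
   min(5, i−1) placed loci plus the chain penalty (λ_init), via L-BFGS-B
   from three starts jittered around the predecessor (jitter scale set to
   the median placed step so it adapts to the data's geometry). A locus
   with no usable pair data and no penalty is stepped one unit along the
   chain direction and flagged.
3. **Annealed exploration.** At temperature T the sampler targets
   exp(loglik/T). Each outer iteration makes one Hamiltonian (leapfrog)
   proposal on all coordinates jointly — the analytic gradient of the
   likelihood is cheap, O(pairs) — accepts it by Metropolis, then
   conditionally maximizes all coefficients by IRLS with ln d as a fixed
   regressor, and cools T ← ρT. Defaults: T₀ = 10, ρ = 0.95,
   T_min = 10⁻³, 10 leapfrog steps, unit mass. The step size is tuned
   during a short burn-in toward 60–80 % acceptance and adapted
   multiplicatively afterwards (×1.05 on accept, ×0.90 on reject), which
   tracks the gradient's 1/T growth as the system cools; a divergent
   trajectory (energy error > 10³) halves the step and retries, up to
   ten times. The best-ever (coordinates, coefficients) state is tracked;
   the run stops at T_min or after 10 outer iterations without relative
   improvement above `tol_rel_loglik`.
4. **Polish.** Deterministic alternation of L-BFGS-B on coordinates and
   IRLS on coefficients until the likelihood stops improving. The polish
   is run from *two* starting points — the best annealed state and the
   initial structure — and the higher-likelihood result is kept. The
   second start matters: the annealed trajectory occasionally commits to
   a basin worse than the sequential start (a compressed structure whose
   refitted decay coefficient is weak, which in turn removes the forces
   that would unfold it), and polishing the initial structure recovers
   those runs. It also lets small, well-determined instances reach the
   exact optimum: on 4-locus tests the fit matches a multistart
   Nelder–Mead profile optimum to 10⁻³.

All randomness flows from a single `numpy` Generator seeded by
`FitConfig.seed`; fits are reproducible bit for bit. The returned
structure is translated so its first locus sits at the origin; rotation,
reflection and scale remain unidentified, which is why the evaluation
statistics are similarity-aware.

Identifiability caveat: the structure's overall scale trades off against
`beta_c0`, so only the *shape* is estimated; `beta_c1` is invariant to
that trade-off.

### Coefficient refits under the sign constraint

With `beta1_sign_constraint` (default on), a refit that would drive a
track's decay coefficient non-negative — possible early in annealing when
the structure is still collapsed — instead pins it just below zero and
refits the remaining coefficients with the distance term as an offset.
At convergence on any real or simulated map the constraint is inactive.

### Numerical choices

* Pair distances are floored at ε = 10⁻⁸ inside ln d (and d² in the
  gradient) so line searches cannot produce −∞; a pair at the floor
  raises a degeneracy warning.
* IRLS declares convergence when the score norm falls below 10⁻⁸
  relative to ‖Xᵀy‖, uses a 10⁻¹² ridge on the weighted normal
  equations, and raises with diagnostics if it cannot reach 10⁻⁴.
* Linear predictors are clipped at ±500 inside IRLS only, as overflow
  protection for intermediate Newton iterates.

## Simulation benchmark

The synthetic-data module generates the study conditions the fits are
validated under:

* **Ground truths** (100 loci each): helix A
  (x = 2 sin(t/3), y = 2 cos(t/3), z = t/20), helix B
  (x = sin(t/3), y = cos(t/3), z = t/3), and an isotropic Gaussian random
  walk with unit step SD. The random walk's parameters are this package's
  choice (made once, for comparability with the 100-locus helices); its
  absolute RMSD values are therefore scale-dependent, and only scale-free
  distance-PCCs are asserted against reference values.
* **Maps**: n_ij ~ Poisson(c · Π_k (x_ik x_jk)^{e_k} / d_ij^α)
  independently on the upper triangle, with α = 1.5, covariates
  x_ik ~ Uniform(0,1), and exponents e_k ∈ {0 (none), 1 (unit bias), or
  (1/3, 1/4, 1/2) for the random-walk design}.
* **Coverage tuning**: the scale c is solved by bisection so the
  *expected* coverage, mean(1 − exp(−λ_ij)), is within 0.5 percentage
  points of the target (90/70/25 % for helix A, 10 % for helix B, 30/70 %
  for the random walk). Tuning on expectation rather than on one
  realization keeps the tuned c seed-independent; the realized coverage
  of the sampled map is reported alongside.
* The helix-A 70/25 % maps are generated covariate-free (λ = c/d^1.5)
  but fitted *with* independent uniform covariates supplied as noise
  regressors, so the bias-correction machinery runs without a planted
  signal — matching how those cells of the design feed every method the
  same inputs.

What the simulations do not emulate about real Hi-C: domain structure
(TADs/compartments), distance-dependent availability, ensemble
heterogeneity across cells, and ligation artifacts near the diagonal.
Passing benchmarks therefore demonstrates correct inference under the
stated generative model, not end-to-end accuracy on tissue data.

Benchmark reference points, recomputed by `scripts/acceptance.py` and
`tests/test_acceptance.py` (five seeds, 100 loci, a few seconds per
fit): mean distance-PCC ≈ 0.93 with smoothing and ≈ 0.91 without on the
30 %-coverage random-walk design; decay coefficient −1.5 ± 0.1 and
covariate coefficients (1/3, 1/4, 1/2) ± 0.1 recovered at 70 % coverage;
smoothing wins on 10 %-coverage helix maps; joint two-track fits at
least match the best single track.

## Evaluation statistics

* `distance_pcc` — Pearson correlation of the two condensed
  pairwise-distance vectors; invariant to similarity transforms.
* `superposition_rmsd` — Procrustes superposition via the SVD of the
  cross-covariance; reflection and uniform scaling are *allowed by
  default* because a contact map cannot resolve chirality or absolute
  scale (both toggles exposed; without scaling the statistic is not
  similarity-invariant, and the tests cover both behaviors).
* `fitted_map_pcc` — correlation between the input map and
  F_ij = exp(fitted linear predictor) over all available pairs; the
  goodness-of-fit measure used to compare raw and normalized fits.
* `fish_scale_fit` — no-intercept regression FISH_i ≈ Σ_k β_k·dist_i·δ_ik
  mapping reconstructions (arbitrary units) onto FISH physical
  distances; each probed end overlaps two candidate bins, and the four
  global end-combinations are enumerated to give a PCC range.
* `loop_distance_test` — one-sided Mann–Whitney U test that
  protein-mediated loop pairs are spatially closer than non-loop anchor
  pairs, on distances scaled by each structure's maximum anchor
  distance. A rank test is used deliberately: the claim is directional
  and no distributional form is defensible.
* `local_window_correlation` — per-locus Pearson/Spearman correlations
  of windowed (default 21 loci) distance vectors across structures;
  windows at chromosome ends are truncated and flagged, and zero-variance
  windows are excluded from both numerator and denominator of the
  ≥-threshold fraction (their count is reported).

## Known limitations

* Consensus-structure model: one conformation per map; no ensemble or
  population deconvolution, and no inter-chromosomal modeling.
* Availability is an input (or derived from having ≥ 1 contact), not
  computed from genome sequence; there is no notion of a mappability
  cutoff inside the package.
* The annealing schedule is heuristic; pathological maps may need a
  slower cooling rate or more outer iterations than the defaults.
* File formats are plain text (triplet/dense maps, BED-like covariates,
  TSV structures); binary formats (.hic, .cool) are out of scope.
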