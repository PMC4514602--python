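# Methods

## Model and assumptions

`occuchain` implements two single-season occupancy models for
detection–non-detection data collected on ordered spatial replicates
(trail segments) within sites (grid cells).

**Standard (closed-replicates) model.** A site is occupied with
probability ψ; given occupancy the species is available on every
replicate, and each replicate detects it independently with probability
p. The site likelihood is
ψ·∏ⱼ p^hⱼ(1−p)^(1−hⱼ) + (1−ψ)·𝟙{no detection}.

**Markov-replicates model.** Given occupancy, a latent presence state aⱼ
follows a first-order two-state Markov chain along the trail:
Pr(present | previous absent) = θ and Pr(present | previous present) = θ′.
Detection is Bernoulli(p) only on replicates where the species is locally
present; an absent replicate can never produce a detection. The first
replicate's presence probability θ₀ is taken as the chain's stationary
probability θ/(θ + 1 − θ′), appropriate when the trail's starting point is
arbitrary with respect to the animal's use of the cell. A ψ-weighted
alternative (θ₀ = ψθ′ + (1−ψ)θ) is available via
`ModelSpec(theta0_mode="psi_weighted")`; the stationary rule is the
default because it reproduces the reference study's published first-
replicate estimate (θ̂₀ = 0.683 at θ̂ = 0.082, θ̂′ = 0.962) while the
weighted average does not (0.643).

Assumptions shared by both models: sites are closed to occupancy change
over the season; sites are independent given covariates (no residual
spatial autocorrelation between cells); covariates act at the site level
only, through the logit link; θ and θ′ are constant across sites. The
Markov model relaxes only the within-site closure assumption, replacing
"present everywhere" with serial presence along the trail.

## Likelihood computation

The hidden presence chain is marginalised with a forward recursion over
the two states, rescaled to unit mass at every step so histories of any
length cannot underflow; the per-site log-normalising constants accumulate
into log Pr(history | occupied). Missing replicates emit weight 1 in both
states but still advance the chain — sites with unequal effort or gaps are
handled exactly, never dropped or padded with zeros. The recursion is
vectorised across sites (one pass over replicate index with per-site
masks), which keeps a 9-parameter fit on a 205-site survey around a
second. Correctness is certified in the test suite against an independent
oracle that enumerates all 2^K hidden paths, to a relative tolerance of
1e−10, together with exact normalisation over all histories and the two
reduction identities (θ=θ′=θ₀=t ⇒ standard model with detection t·p;
t = 1 ⇒ standard model with p).

## Estimation and numerical choices

- **Parameterisation.** All probabilities, including θ and θ′, are
  estimated on the logit scale, so the optimiser is unconstrained.
  Probabilities are clamped to (1e−12, 1−1e−12); site likelihoods are
  floored at 1e−300 before logging.
- **Optimiser.** L-BFGS-B with objective tolerance 1e−8, multi-start
  (zeros plus seeded N(0,1) perturbations; 5 starts by default) because
  the Markov likelihood can be multimodal. Fits are deterministic given
  the seed. The recovery harness defaults to a single start: truth-started
  and multi-started fits were verified to reach the same optima in this
  regime, and one start keeps 100-replicate experiments inside a few
  minutes.
- **Variance-covariance.** The Hessian of the negative log-likelihood is
  computed by high-accuracy central finite differences
  (`statsmodels.tools.numdiff.approx_hess3`; the `numdifftools`-style
  workflow without an extra dependency). Eigenvalues are floored at
  max_eig·1e−8 before inversion: a flat (weakly identified) likelihood
  direction then yields a large positive variance rather than a negative
  or truncated one, and the matrix stays positive semidefinite. A
  condition number above 1e8 is logged. The coarser `approx_hess2` scheme
  was observed to misread flat directions as slightly negative curvature,
  corrupting SEs; hence the stricter scheme.
- **Convergence flag.** Requires optimiser success and a gradient norm
  below 1e−2·max(1, |nll|); non-converged fits are excluded from AIC
  ranking with a warning, never silently used.
- **AIC bookkeeping.** AIC = −2·loglik + 2K with K counting ψ-block,
  p-block and (for the Markov model) the two transition parameters; θ₀ is
  derived, not free. Reported deviance is −2·loglik; ΔAIC-based
  comparisons are unaffected by any additive constant convention.

## Model selection

Covariate pairs with |Pearson r| > 0.7 never enter the same model
(the screen rejects candidate formulas containing a flagged pair).
Selection is two-step and detection-first: all detectability structures
are ranked by AIC under a fixed, moderately parameterised occupancy
structure (PropFor + NDVI + LVS by default); the minimum-AIC detection
structure is then held fixed while occupancy structures are ranked. The
default candidate sets are the reference study's 12 detection and 24
occupancy formulas. Interaction models always include their main effects.
Ties in AIC are broken by fewer parameters, then name. No model averaging
is performed.

Summed Akaike weights are the literal sum over all models containing a
predictor. For rainfall this gives 0.338 on the reference occupancy table,
whereas the study's printed value (0.1922) equals the sum over only two of
the three rain-containing models; the package computes the literal sum and
documents the discrepancy rather than reproducing it.

## Landscape-level estimation

Site-specific occupancy predictions ψ̂ᵢ = logit⁻¹(xᵢᵀβ̂_ψ) are combined
with weights wᵢ proportional to each cell's forest area. The SE of the
weighted estimate uses the displayed double-sum formula with cross-site
covariances from a parametric bootstrap: B (default 100) multivariate-
normal draws of β centred at β̂ with the fitted variance-covariance matrix
(repaired by eigenvalue clipping at zero if numerically non-PSD), pushed
through the inverse logit, covaried with divisor B−1. Per-site variances
default to the logit-scale delta method — the bootstrap exists in the
source analysis specifically to supply covariances — with
`variance_mode="bootstrap"` using the bootstrap sample variances instead;
the two agree within Monte-Carlo noise on well-conditioned fits (checked
in the test suite at aggregate level, ±25%). Occupied area is ψ̄ × total
forest area, reported alongside the naive (detection-ignorant) area and
their difference.

## Synthetic-data generator

The generator is the generative mirror of the Markov model and defines
the package's reference study conditions:

- **Truth preset** (`reference_truth()`): ψ-block (5.582, −2.181, −3.417,
  −2.831) on (1, LVS, NDVI, LVS·NDVI) — the published top-model
  coefficients — with θ = 0.082, θ′ = 0.962, 205 sites, and p-block
  (1.0, −0.9, 1.0) on (1, LVS, PropFor), chosen so site-level p spans
  roughly 0.55–0.88, the published detectability range.
- **Covariate marginals** (never published; chosen once as realistic
  stand-ins): PropFor ~ 0.055 + 0.945·Beta(2,2) (surveyed cells have at
  least ~10 km² of forest), LVS ~ Beta(2, 1.8), NDVI ~ Beta(4, 1.8),
  rainfall ~ 630 + 5253·Beta(2, 3.6) mm (the landscape's printed range and
  approximate mean), CV(NDVI) ~ Gamma(4, 0.05). These imply mean ψ ≈ 0.65,
  site ψ spanning ≈0.1–1 and mean effort ≈21 km, matching the published
  operating point. The NDVI spread was set wide deliberately: a narrow
  NDVI marginal makes LVS and LVS·NDVI nearly collinear and the
  interaction unidentifiable, contradicting the published coefficient SEs.
- **Rain–NDVI dependence**: a Gaussian copula whose normal-score
  correlation is calibrated by deterministic Gauss–Hermite quadrature and
  bisection so the final Pearson correlation hits the target (default
  0.81).
- **Effort rule**: Kᵢ = round(40·PropForᵢ) clamped to [4, 42] (40 km of
  trail for a fully forested cell), or a constant K for designed
  experiments.
- Unoccupied sites yield all-zero histories; occupied sites draw the
  presence chain from its stationary initial state. Everything is
  reproducible from a single seed, and `return_latent=True` exposes the
  latent chain for generator diagnostics.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: between-site spatial autocorrelation,
replicate-level covariate effects, observer heterogeneity, the empirical
(unpublished) distribution of replicate counts beyond its range and mean,
and the true joint covariate geometry of the landscape. On that last
point: no bounded [0,1] marginal configuration reproduces the published
coefficient-SE scale (≈0.5–2.0), whose small interaction SE implies a
covariate geometry not recoverable from printed summaries; synthetic fits
therefore have flatter ψ-likelihoods than the field data did.

A separate deterministic object, `synthetic_reference_survey()`,
reconstructs only the *marginal counts* of the reference survey (205
sites, 4,172 replicates within [4, 42], detections in 110 sites, 1,230
detected replicates) with schematic within-site patterns; it exists to
exercise naive summaries and data plumbing exactly and must not be used
for model fitting.

## Recovery experiment

`recovery_experiment` simulates, refits the generating structure and
reports per-parameter mean bias with Monte-Carlo SE, RMSE, 95% Wald
coverage and the fit-failure rate. At the reference truth with 500 sites
and K = 20 over 100 replicates, all nine parameters show mean bias within
2 Monte-Carlo SEs of zero and coverage between 0.92 and 0.98. The ψ-block
sampling distributions are heavy-tailed (RMSE 2.6–5.0) — a consequence of
the flat likelihood geometry discussed above, not an estimator defect;
the detection and transition parameters are tightly recovered
(RMSE ≤ 0.2).

## Problem sizes

Default analysis runs use the study-scale survey (205 sites, ~4,200
replicates); recovery experiments use 500 sites × 20 replicates × 100
simulate-refit cycles (30 in the acceptance script, which favours a
broader sweep of pipeline stages over replication); bootstrap draws
default to B = 100 with divisor B − 1. These sizes were chosen so a full
pipeline run completes in about two minutes on a single core.

## Known limitations

- θ and θ′ are intercept-only; replicate-level or site-level covariates on
  the transition probabilities are not supported (none of the candidate
  models use them).
- No goodness-of-fit machinery: absolute fit of the Markov-replicates
  model is not assessable with current methods, so only relative (AIC)
  comparisons are offered.
- No abundance-mediated detection (Royle–Nichols-type) models.
- The ψ-weighted θ₀ option uses the mean ψ across sites as the weight; a
  site-specific weighting would make θ₀ covariate-dependent, which the
  constant-θ model structure does not represent.
- Weakly identified covariate structures (e.g. an interaction over a
  narrow covariate range) produce honest but very large SEs; the Hessian
  eigenvalue floor prevents negative variances but cannot manufacture
  information that is not in the data.
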