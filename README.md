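# occuchain

Single-season site-occupancy modeling for **sign surveys with spatially
replicated, serially dependent detections**, with AIC model selection and a
landscape-level occupancy estimator.

Detection–non-detection surveys of wide-ranging mammals (the motivating
application is Asian elephant dung surveys across a 205-cell, 21,167-km²
forest landscape in the Western Ghats of Karnataka, India) often replace
repeat visits with *spatial* replicates: consecutive 1-km trail segments
inside each grid cell. Consecutive segments are not independent — an animal
present on one segment is very likely present on the next — and ignoring
that serial dependence biases both detectability and occupancy estimates.
`occuchain` implements the occupancy model in which replicate-level
presence follows a first-order two-state Markov chain, alongside the
classic closed-replicates model, so the two can be compared on equal
footing.

## The model

For site *i* with detection history $h_{i1},\dots,h_{iK_i}$:

- occupancy: $z_i \sim \mathrm{Bernoulli}(\psi_i)$,
  $\operatorname{logit}\psi_i = x_i^\top\beta_\psi$;
- given occupancy, latent presence along the trail:
  $\Pr(a_{ij}{=}1 \mid a_{i,j-1}{=}0) = \theta$,
  $\Pr(a_{ij}{=}1 \mid a_{i,j-1}{=}1) = \theta'$, with the first replicate
  initialised at the chain's stationary probability
  $\theta_0 = \theta/(\theta + 1 - \theta')$;
- detection: $h_{ij} \sim \mathrm{Bernoulli}(p_i\,a_{ij})$,
  $\operatorname{logit} p_i = v_i^\top\beta_p$.

The site likelihood marginalises the hidden chain with a scaled forward
recursion, so arbitrarily long histories (and missing replicates) are
handled exactly and stably. Setting $\theta=\theta'=\theta_0=1$ recovers
the standard single-season model. All parameters are estimated jointly by
maximum likelihood; candidate covariate structures are ranked by AIC with
a detection-first two-step protocol; the area-weighted overall occupancy
$\bar\psi = \sum_i w_i \hat\psi_i$ (weights $w_i$ proportional to each
cell's forest area) gets its standard error from

$$\mathrm{SE}^2(\bar\psi)=\sum_i w_i^2\widehat{\mathrm{var}}(\hat\psi_i)
 +\sum_{i\ne j} w_i w_j\, \widehat{\mathrm{cov}}(\hat\psi_i,\hat\psi_j),$$

with cross-site covariances from a parametric bootstrap (multivariate-
normal draws of $\hat\beta$) and per-site variances from the logit-scale
delta method (bootstrap variances optional).

A synthetic-survey generator mirrors this generative structure — including
the rainfall–NDVI correlation (Pearson r = 0.81) via a calibrated Gaussian
copula and effort proportional to forest cover (4–42 replicates per cell)
— so every stage of the pipeline is testable without field data.

## Worked example

```bash
occuchain simulate --n-sites 205 --seed 42 --outdir survey
# wrote 205 sites, 4414 replicates, naive occupancy 0.663 -> survey

occuchain landscape --detections survey/detections.csv \
    --covariates survey/covariates.csv --seed 42 --outdir out
# overall psi 0.743 (SE 0.047); occupied area 15416 km2 of 20756 km2; naive 13770 km2
```

The simulated survey's naive occupancy (fraction of sites with at least
one detection, 0.663) underestimates the model-based overall occupancy
(0.743) because detection is imperfect and presence is patchy along
trails: the landscape report quantifies the difference in km² of occupied
forest. Fitting the generating covariate structure,

```bash
occuchain fit --detections survey/detections.csv \
    --covariates survey/covariates.csv \
    --psi "LVS*NDVI" --p "LVS+PropFor" --outdir out
# psi(LVS*NDVI),thta0,thta1,p(LVS+PropFor): AIC 3411.06, 9 parameters, converged=True
```

writes a coefficient/SE table (`out/coefficients.csv`); the fitted
transition estimates (`logit_theta` = −2.57 → θ̂ = 0.071,
`logit_theta_prime` = 3.32 → θ̂′ = 0.965) show the strong serial dependence
the generator put in: presence is far more likely when the previous
segment was also occupied. `occuchain select` runs the full two-step AIC
selection and writes ranked model tables; `occuchain recover` runs a
simulate-and-refit bias/coverage experiment.

The same functions are available as a library (`occuchain.fit_model`,
`occuchain.two_step_selection`, `occuchain.landscape_estimate`, …) on any
survey supplied as two CSVs (long-format detections; site covariates).

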