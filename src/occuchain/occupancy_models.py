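"""Likelihood core: single-season occupancy models with and without
first-order Markov dependence of replicate-level presence.

Two observation models share the same site-occupancy layer
(z_site ~ Bernoulli(ψ), logit-linear in site covariates):

* ``standard`` — given occupancy, replicate detections are iid
  Bernoulli(p): the classic single-season model.  Its closure assumption
  (the species is available on every replicate of an occupied site) fails
  for spatial replicates walked sequentially along trails.

* ``markov`` — given occupancy, a hidden presence state follows a two-state
  Markov chain along the trail: Pr(present | previous absent) = θ,
  Pr(present | previous present) = θ′; detection is Bernoulli(p) only where
  the species is locally present.  The first replicate is initialised at
  θ0, by default the chain's stationary probability θ/(θ + 1 − θ′).

The site likelihood marginalises the hidden chain with a scaled forward
recursion, so histories of any length are numerically safe.  ψ and p are
logit-linear in site covariates; θ and θ′ are constants on the logit scale.
All parameters are estimated jointly by maximum likelihood; the
variance-covariance matrix comes from the numerically differentiated
Hessian at the optimum.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_fprime, approx_hess3

from .survey_data import SurveyDataset, build_design_matrix, parse_formula

__all__ = [
    "ModelSpec",
    "SiteParameters",
    "FittedModel",
    "FitOptions",
    "inv_logit",
    "logit",
    "stationary_theta0",
    "psi_weighted_theta0",
    "site_likelihood_standard",
    "site_likelihood_markov",
    "negative_log_likelihood",
    "fit_model",
    "compare_dependence",
]

logger = logging.getLogger(__name__)

_PCLIP = 1e-12  # probabilities clamped to the open interval (0, 1)
_HESS_CONDITION_WARN = 1e8


def inv_logit(x):
    """Inverse logit 1/(1+exp(−x)), clamped to the open unit interval."""
    return np.clip(expit(x), _PCLIP, 1.0 - _PCLIP)


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def stationary_theta0(theta: float, theta_prime: float) -> float:
    """Stationary presence probability of the two-state chain,
    θ/(θ + 1 − θ′): the default initial-replicate presence probability,
    appropriate because the first replicate may start anywhere in the cell.

    Undefined for the doubly absorbing chain θ=0, θ′=1.
    """
    denom = theta + 1.0 - theta_prime
    if denom <= 0.0:
        raise ValueError("stationary_theta0 undefined: theta=0 with theta_prime=1")
    return theta / denom


def psi_weighted_theta0(theta: float, theta_prime: float, psi: float) -> float:
    """Alternative initial-presence rule: ψ-weighted average of θ′ and θ."""
    return psi * theta_prime + (1.0 - psi) * theta


@dataclass
class SiteParameters:
    """Replicate-process parameters for one site; all in [0, 1]."""

    psi: float
    theta: float
    theta_prime: float
    theta0: float
    p: float

    def __post_init__(self):
        for name in ("psi", "theta", "theta_prime", "theta0", "p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# Per-site likelihoods (reference scalar implementations)
# ---------------------------------------------------------------------------

def _history_array(history) -> np.ndarray:
    if isinstance(history, str):
        return np.array([np.nan if c in ".-" else float(c) for c in history])
    return np.asarray(history, dtype=float)


def site_likelihood_standard(psi: float, p: float, history) -> float:
    """Closed-occupancy site likelihood:
    ψ·∏ p^h (1−p)^(1−h) over non-missing replicates, plus (1−ψ) if the
    history holds no detection.  An all-missing history carries no
    information and returns 1."""
    h = _history_array(history)
    obs = h[~np.isnan(h)]
    prod = float(np.prod(np.where(obs == 1.0, p, 1.0 - p)))
    like = psi * prod
    if not (obs == 1.0).any():
        like += (1.0 - psi)
    return like


def site_likelihood_markov(params: SiteParameters, history) -> float:
    """Markov-replicate site likelihood via the forward recursion.

    The hidden state z_j ∈ {absent, present} starts at weights
    (1−θ0, θ0), transitions with Pr(present|present)=θ′ and
    Pr(present|absent)=θ, and emits detections Bernoulli(p) only when
    present.  Missing replicates emit weight 1 in both states but still
    advance the chain.  The recursion is rescaled at every step, so long
    histories do not underflow.
    """
    h = _history_array(history)
    logf, _ = _forward_loglik(
        h[None, :],
        np.array([len(h)]),
        np.array([params.p]),
        params.theta,
        params.theta_prime,
        params.theta0,
    )
    like = params.psi * float(np.exp(logf[0]))
    if not (h[~np.isnan(h)] == 1.0).any():
        like += 1.0 - params.psi
    return like


def _forward_loglik(H, K, p, theta, theta_prime, theta0):
    """Vectorised scaled forward recursion over the hidden presence chain.

    Parameters
    ----------
    H : (n, Kmax) history matrix, NaN marks missing or padding.
    K : (n,) replicate slots per site.
    p : (n,) per-site detection probability given presence.
    theta, theta_prime, theta0 : scalars.

    Returns
    -------
    (n,) log Pr(history | occupied) and (n,) boolean "no detection" flags.
    """
    H = np.asarray(H, dtype=float)
    n, kmax = H.shape
    p = np.broadcast_to(np.asarray(p, dtype=float), (n,))

    def emis(j):
        h = H[:, j]
        miss = np.isnan(h)
        e_pres = np.where(miss, 1.0, np.where(h == 1.0, p, 1.0 - p))
        e_abs = np.where(miss | (h == 0.0), 1.0, 0.0)
        return e_abs, e_pres

    e_abs, e_pres = emis(0)
    a_abs = (1.0 - theta0) * e_abs
    a_pres = theta0 * e_pres
    c = a_abs + a_pres
    c = np.maximum(c, 1e-300)
    logf = np.log(c)
    a_abs, a_pres = a_abs / c, a_pres / c
    for j in range(1, kmax):
        active = K > j
        if not active.any():
            break
        e_abs, e_pres = emis(j)
        na = a_abs * (1.0 - theta) + a_pres * (1.0 - theta_prime)
        npres = a_abs * theta + a_pres * theta_prime
        na = na * e_abs
        npres = npres * e_pres
        c = np.maximum(na + npres, 1e-300)
        logf = np.where(active, logf + np.log(c), logf)
        a_abs = np.where(active, na / c, a_abs)
        a_pres = np.where(active, npres / c, a_pres)
    no_det = ~np.nansum(H == 1.0, axis=1).astype(bool)
    return logf, no_det


# ---------------------------------------------------------------------------
# Model specification and dataset-level likelihood
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Covariate structure for one candidate model.

    ``psi_formula`` and ``p_formula`` use the additive/interaction formula
    syntax of :func:`occuchain.survey_data.parse_formula`; ``dependence``
    selects the observation model.  θ and θ′ are always intercept-only
    constants (on the logit scale), matching the candidate sets this model
    family is used with.
    """

    psi_formula: str = "."
    p_formula: str = "."
    dependence: str = "markov"
    theta0_mode: str = "stationary"  # or "psi_weighted"

    def __post_init__(self):
        if self.dependence not in ("markov", "standard"):
            raise ValueError("dependence must be 'markov' or 'standard'")
        if self.theta0_mode not in ("stationary", "psi_weighted"):
            raise ValueError("theta0_mode must be 'stationary' or 'psi_weighted'")

    @property
    def psi_terms(self) -> list[str]:
        return parse_formula(self.psi_formula)

    @property
    def p_terms(self) -> list[str]:
        return parse_formula(self.p_formula)

    @property
    def n_theta(self) -> int:
        return 2 if self.dependence == "markov" else 0

    def n_params(self) -> int:
        return len(self.psi_terms) + len(self.p_terms) + self.n_theta

    @property
    def name(self) -> str:
        """Model label in the field's string convention,
        e.g. ``psi(LVS*NDVI),thta0,thta1,p(LVS+PropFor)``."""
        psi = self.psi_formula if self.psi_formula != "" else "."
        p = self.p_formula if self.p_formula != "" else "."
        mid = "thta0,thta1," if self.dependence == "markov" else ""
        return f"psi({psi}),{mid}p({p})"

    def beta_names(self) -> list[str]:
        names = [f"psi_{t}" for t in self.psi_terms] + [f"p_{t}" for t in self.p_terms]
        if self.dependence == "markov":
            names += ["logit_theta", "logit_theta_prime"]
        return names


def _design(spec: ModelSpec, dataset: SurveyDataset):
    return (
        build_design_matrix(dataset, spec.psi_terms),
        build_design_matrix(dataset, spec.p_terms),
    )


def _unpack(beta, spec: ModelSpec):
    beta = np.asarray(beta, dtype=float)
    npsi = len(spec.psi_terms)
    np_ = len(spec.p_terms)
    expected = npsi + np_ + spec.n_theta
    if beta.size != expected:
        raise ValueError(f"beta has length {beta.size}, expected {expected} for {spec.name}")
    return beta[:npsi], beta[npsi : npsi + np_], beta[npsi + np_ :]


def negative_log_likelihood(beta, spec: ModelSpec, dataset: SurveyDataset) -> float:
    """−Σ_i log L_i over sites, with ψ_i and p_i logit-linear in site
    covariates and (for the markov model) constant θ, θ′ on the logit scale.
    """
    b_psi, b_p, b_th = _unpack(beta, spec)
    X_psi, X_p = _design(spec, dataset)
    return _nll_from_design(beta, spec, X_psi, X_p, dataset.history_matrix(), dataset.replicate_counts)


def _nll_from_design(beta, spec, X_psi, X_p, H, K) -> float:
    b_psi, b_p, b_th = _unpack(beta, spec)
    psi = inv_logit(X_psi @ b_psi)
    p = inv_logit(X_p @ b_p)
    if spec.dependence == "markov":
        theta = float(inv_logit(b_th[0]))
        theta_prime = float(inv_logit(b_th[1]))
        logf, no_det = _forward_loglik(H, K, p, theta, theta_prime,
                                       _theta0_for(spec, theta, theta_prime, psi))
        like = psi * np.exp(logf)
    else:
        obs = ~np.isnan(H)
        d = np.nansum(H, axis=1)
        m = obs.sum(axis=1)
        logf = d * np.log(p) + (m - d) * np.log1p(-p)
        no_det = d == 0
        like = psi * np.exp(logf)
    like = like + np.where(no_det, 1.0 - psi, 0.0)
    like = np.maximum(like, 1e-300)
    ll = np.log(like)
    if not np.isfinite(ll).all():
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite site log-likelihood at site index {bad}")
    return float(-ll.sum())


def _theta0_for(spec, theta, theta_prime, psi):
    if spec.theta0_mode == "stationary":
        return stationary_theta0(theta, theta_prime)
    # ψ-weighted variant: a scalar rule needs a scalar ψ; use the mean.
    return psi_weighted_theta0(theta, theta_prime, float(np.mean(psi)))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimiser controls.  ``n_starts`` counts the zero start plus random
    perturbations (seeded, so fits are deterministic); ``start`` overrides
    the zero start."""

    start: np.ndarray | None = None
    n_starts: int = 5
    seed: int = 0
    tol: float = 1e-8
    maxiter: int = 1000
    start_scale: float = 1.0


@dataclass
class FittedModel:
    """A maximum-likelihood fit with its variance-covariance bookkeeping."""

    spec: ModelSpec
    beta: np.ndarray
    beta_names: list
    vcov: np.ndarray | None
    loglik: float
    n_params: int
    aic: float
    deviance: float
    converged: bool
    n_sites: int
    diagnostics: dict = field(default_factory=dict)

    # -- natural-scale accessors --------------------------------------
    @property
    def beta_psi(self) -> np.ndarray:
        return self.beta[: len(self.spec.psi_terms)]

    @property
    def beta_p(self) -> np.ndarray:
        k = len(self.spec.psi_terms)
        return self.beta[k : k + len(self.spec.p_terms)]

    @property
    def theta(self) -> float:
        if self.spec.dependence != "markov":
            raise AttributeError("standard model has no theta")
        return float(inv_logit(self.beta[-2]))

    @property
    def theta_prime(self) -> float:
        if self.spec.dependence != "markov":
            raise AttributeError("standard model has no theta_prime")
        return float(inv_logit(self.beta[-1]))

    @property
    def theta0(self) -> float:
        return stationary_theta0(self.theta, self.theta_prime)

    def se(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(self.beta.size, np.nan)
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    # -- serialisation -------------------------------------------------
    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.beta_names, "estimate": self.beta, "se": self.se()}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.spec.name,
                "dependence": self.spec.dependence,
                "beta": dict(zip(self.beta_names, self.beta.tolist())),
                "se": dict(zip(self.beta_names, self.se().tolist())),
                "vcov": None if self.vcov is None else self.vcov.tolist(),
                "loglik": self.loglik,
                "n_params": self.n_params,
                "aic": self.aic,
                "deviance": self.deviance,
                "converged": self.converged,
                "n_sites": self.n_sites,
                "diagnostics": self.diagnostics,
            },
            indent=2,
        )


def fit_model(spec: ModelSpec, dataset: SurveyDataset, options: FitOptions | None = None) -> FittedModel:
    """Maximum-likelihood fit by quasi-Newton (L-BFGS-B) with multi-start.

    Starts from zeros (all probabilities 0.5) plus seeded random
    perturbations; keeps the best optimum.  The variance-covariance matrix
    is the pseudo-inverse of the central-finite-difference Hessian at the
    optimum; ``converged`` reflects optimiser success, a finite gradient
    check and Hessian conditioning.
    """
    opts = options or FitOptions()
    k = spec.n_params()
    X_psi, X_p = _design(spec, dataset)
    H = dataset.history_matrix()
    K = dataset.replicate_counts

    def objective(beta):
        try:
            return _nll_from_design(beta, spec, X_psi, X_p, H, K)
        except FloatingPointError:
            return 1e12

    rng = np.random.default_rng(opts.seed)
    base = np.zeros(k) if opts.start is None else np.asarray(opts.start, dtype=float)
    starts = [base]
    for _ in range(max(opts.n_starts - 1, 0)):
        starts.append(base + rng.normal(scale=opts.start_scale, size=k))

    best = None
    any_success = False
    for s in starts:
        res = optimize.minimize(
            objective,
            s,
            method="L-BFGS-B",
            options={"maxiter": opts.maxiter, "ftol": opts.tol, "gtol": 1e-8},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    beta_hat = np.asarray(best.x, dtype=float)
    nll = float(best.fun)
    grad = approx_fprime(beta_hat, objective, centered=True).ravel()
    grad_norm = float(np.linalg.norm(grad))

    vcov = None
    hess_ok = False
    cond = np.inf
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess3(beta_hat, objective)
        hess = 0.5 * (hess + hess.T)
        eigvals, eigvecs = np.linalg.eigh(hess)
        if np.all(np.isfinite(hess)) and eigvals.max() > 0:
            hess_ok = eigvals.min() > 0
            cond = float(eigvals.max() / eigvals.min()) if hess_ok else np.inf
            # flat or numerically indefinite directions: floor the curvature
            # so the resulting vcov stays PSD with a large (not negative or
            # infinite) variance along the unidentified combination
            floor = eigvals.max() * 1e-8
            clipped = np.maximum(eigvals, floor)
            vcov = (eigvecs / clipped) @ eigvecs.T
            vcov = 0.5 * (vcov + vcov.T)
            if cond > _HESS_CONDITION_WARN:
                logger.warning("%s: Hessian condition number %.2e exceeds %.0e",
                               spec.name, cond, _HESS_CONDITION_WARN)
    except Exception as exc:  # Hessian failure must not void the point estimate
        logger.warning("%s: Hessian evaluation failed (%s); vcov unavailable", spec.name, exc)

    converged = bool(any_success and np.isfinite(nll) and grad_norm < 1e-2 * max(1.0, abs(nll)))
    if not converged:
        logger.warning("%s: fit flagged non-converged (grad norm %.3g)", spec.name, grad_norm)

    return FittedModel(
        spec=spec,
        beta=beta_hat,
        beta_names=spec.beta_names(),
        vcov=vcov,
        loglik=-nll,
        n_params=k,
        aic=2.0 * nll + 2.0 * k,
        deviance=2.0 * nll,
        converged=converged,
        n_sites=dataset.n_sites,
        diagnostics={
            "grad_norm": grad_norm,
            "hessian_pd": bool(hess_ok),
            "hessian_condition": float(cond),
            "optimizer_success": bool(any_success),
            "n_starts": len(starts),
        },
    )


def compare_dependence(dataset: SurveyDataset, options: FitOptions | None = None) -> dict:
    """Intercept-only fits of the standard and Markov models, with the AIC
    difference (standard minus markov).  A large positive ΔAIC indicates
    serial dependence of presence along the trail."""
    fit_std = fit_model(ModelSpec(".", ".", dependence="standard"), dataset, options)
    fit_mkv = fit_model(ModelSpec(".", ".", dependence="markov"), dataset, options)
    return {
        "fit_standard": fit_std,
        "fit_markov": fit_mkv,
        "delta_aic": fit_std.aic - fit_mkv.aic,
    }
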