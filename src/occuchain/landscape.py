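"""Landscape-level inference: site-specific occupancy prediction, the
area-weighted overall occupancy estimator, its parametric-bootstrap
standard error, and occupied-area conversion.

Overall occupancy is Σ_i w_i ψ̂_i with w_i the site's forest area as a
proportion of the landscape's forest area.  Its standard error is

    SE²(ψ̄) = Σ_i w_i² var(ψ̂_i) + Σ_{i≠j} w_i w_j cov(ψ̂_i, ψ̂_j),

with the cross-site covariances obtained by a parametric bootstrap: B
multivariate-normal draws of β around β̂ with the fitted
variance-covariance matrix, pushed through the inverse-logit to per-site
occupancy probabilities, covaried with divisor B−1.  The per-site
variances come from the logit-scale delta method by default, or from the
same bootstrap draws when ``variance_mode="bootstrap"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy_models import FittedModel, inv_logit
from .survey_data import SurveyDataset, build_design_matrix

__all__ = [
    "BetaDraws",
    "LandscapeEstimate",
    "AreaReport",
    "predict_site_psi",
    "predict_site_p",
    "area_weights",
    "overall_occupancy",
    "draw_beta",
    "psi_covariance",
    "delta_method_psi_variance",
    "overall_se",
    "occupied_area",
    "landscape_estimate",
]

logger = logging.getLogger(__name__)


def predict_site_psi(fitted: FittedModel, dataset: SurveyDataset) -> np.ndarray:
    """ψ̂_i = inv_logit(x_iᵀ β̂_ψ) for every site."""
    X = build_design_matrix(dataset, fitted.spec.psi_terms)
    return inv_logit(X @ fitted.beta_psi)


def predict_site_p(fitted: FittedModel, dataset: SurveyDataset) -> np.ndarray:
    """Site-level replicate detectability p̂_i given local presence."""
    X = build_design_matrix(dataset, fitted.spec.p_terms)
    return inv_logit(X @ fitted.beta_p)


def area_weights(dataset: SurveyDataset, total_forest_area: float | None = None) -> np.ndarray:
    """w_i = forest_area_i / total forest area (defaults to the sum over
    surveyed sites, so the weights sum to 1)."""
    total = float(total_forest_area) if total_forest_area else float(dataset.forest_area.sum())
    if total <= 0:
        raise ValueError("total forest area must be positive")
    return dataset.forest_area / total


def overall_occupancy(site_psi, weights, tol: float = 1e-6) -> float:
    """Area-weighted overall occupancy Σ w_i ψ̂_i."""
    psi = np.asarray(site_psi, dtype=float)
    w = np.asarray(weights, dtype=float)
    if psi.shape != w.shape:
        raise ValueError("site_psi and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError(f"weights sum to {w.sum():.6f}, not 1")
    return float(w @ psi)


@dataclass
class BetaDraws:
    """B multivariate-normal draws of the coefficient vector, with the
    model they belong to.  Reproducible given the seed."""

    beta: np.ndarray          # (B, k)
    fitted: FittedModel
    seed: int

    @property
    def B(self) -> int:
        return self.beta.shape[0]


def _psd_repair(vcov: np.ndarray) -> np.ndarray:
    sym = 0.5 * (vcov + vcov.T)
    eigval, eigvec = np.linalg.eigh(sym)
    if eigval.min() < 0:
        logger.warning("vcov not PSD (min eigenvalue %.3g); clipping at zero", eigval.min())
        eigval = np.clip(eigval, 0.0, None)
        sym = (eigvec * eigval) @ eigvec.T
    return sym


def draw_beta(fitted: FittedModel, B: int = 100, seed: int = 0) -> BetaDraws:
    """Parametric-bootstrap draws β^(b) ~ MVN(β̂, vcov), b = 1..B."""
    if fitted.vcov is None:
        raise ValueError("fitted model has no variance-covariance matrix")
    if B < 2:
        raise ValueError("need at least 2 draws")
    rng = np.random.default_rng(seed)
    cov = _psd_repair(fitted.vcov)
    draws = rng.multivariate_normal(fitted.beta, cov, size=B, method="eigh")
    return BetaDraws(beta=draws, fitted=fitted, seed=seed)


def _psi_draw_matrix(draws: BetaDraws, dataset: SurveyDataset) -> np.ndarray:
    X = build_design_matrix(dataset, draws.fitted.spec.psi_terms)
    k = X.shape[1]
    return inv_logit(draws.beta[:, :k] @ X.T)  # (B, n_sites)


def psi_covariance(draws: BetaDraws, dataset: SurveyDataset) -> np.ndarray:
    """Pairwise covariance of site occupancy estimates across the draws,
    cov(ψ_i, ψ_j) = Σ_b (ψ_i^b − ψ̄_i)(ψ_j^b − ψ̄_j) / (B − 1)."""
    psi = _psi_draw_matrix(draws, dataset)
    return np.atleast_2d(np.cov(psi, rowvar=False, ddof=1))


def delta_method_psi_variance(fitted: FittedModel, dataset: SurveyDataset) -> np.ndarray:
    """var(ψ̂_i) by the delta method on the logit scale:
    var(η_i) = x_iᵀ Σ_ψ x_i, var(ψ̂_i) = [ψ̂_i(1−ψ̂_i)]² var(η_i)."""
    if fitted.vcov is None:
        raise ValueError("fitted model has no variance-covariance matrix")
    X = build_design_matrix(dataset, fitted.spec.psi_terms)
    k = X.shape[1]
    sigma = fitted.vcov[:k, :k]
    var_eta = np.einsum("ij,jk,ik->i", X, sigma, X)
    psi = predict_site_psi(fitted, dataset)
    return (psi * (1.0 - psi)) ** 2 * np.clip(var_eta, 0.0, None)


def overall_se(
    fitted: FittedModel,
    dataset: SurveyDataset,
    B: int = 100,
    seed: int = 0,
    variance_mode: str = "delta",
    total_forest_area: float | None = None,
) -> float:
    """SE of the area-weighted overall occupancy.

    Cross-site covariances always come from the parametric bootstrap;
    per-site variances from the delta method (default) or from the
    bootstrap sample variances (``variance_mode="bootstrap"``).
    """
    if variance_mode not in ("delta", "bootstrap"):
        raise ValueError("variance_mode must be 'delta' or 'bootstrap'")
    w = area_weights(dataset, total_forest_area)
    cov = psi_covariance(draw_beta(fitted, B=B, seed=seed), dataset)
    if variance_mode == "delta":
        var = delta_method_psi_variance(fitted, dataset)
    else:
        var = np.diag(cov)
    off_diag = float(w @ cov @ w) - float(w**2 @ np.diag(cov))
    se2 = float(w**2 @ var) + off_diag
    return float(np.sqrt(max(se2, 0.0)))


@dataclass
class AreaReport:
    """Occupied-area conversion and the naive-estimate comparison."""

    overall_psi: float
    naive_occupancy: float
    total_forest_area_km2: float
    occupied_area_km2: float
    naive_area_km2: float
    underestimation_km2: float
    underestimation_pct: float


def occupied_area(overall_psi: float, total_forest_area: float, naive_occupancy: float) -> AreaReport:
    """Convert occupancy proportions to km² of occupied forest and quantify
    how far a detection-ignorant (naive) analysis underestimates it."""
    if total_forest_area <= 0:
        raise ValueError("total forest area must be positive")
    model_area = overall_psi * total_forest_area
    naive_area = naive_occupancy * total_forest_area
    diff = model_area - naive_area
    return AreaReport(
        overall_psi=overall_psi,
        naive_occupancy=naive_occupancy,
        total_forest_area_km2=total_forest_area,
        occupied_area_km2=model_area,
        naive_area_km2=naive_area,
        underestimation_km2=diff,
        underestimation_pct=100.0 * diff / model_area if model_area else 0.0,
    )


@dataclass
class LandscapeEstimate:
    """Full landscape-level result bundle."""

    site_psi: np.ndarray
    site_psi_se: np.ndarray
    site_p: np.ndarray
    weights: np.ndarray
    overall_psi: float
    overall_se: float
    total_forest_area_km2: float
    occupied_area_km2: float
    occupied_area_se_km2: float
    naive_occupancy: float
    naive_area_km2: float
    underestimation_km2: float
    B: int
    seed: int

    def site_table(self, dataset: SurveyDataset) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": dataset.site_ids,
                "psi_hat": self.site_psi,
                "psi_se": self.site_psi_se,
                "p_hat": self.site_p,
                "weight": self.weights,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall_psi": self.overall_psi,
                "overall_se": self.overall_se,
                "total_forest_area_km2": self.total_forest_area_km2,
                "occupied_area_km2": self.occupied_area_km2,
                "occupied_area_se_km2": self.occupied_area_se_km2,
                "naive_occupancy": self.naive_occupancy,
                "naive_area_km2": self.naive_area_km2,
                "underestimation_km2": self.underestimation_km2,
                "bootstrap_draws": self.B,
                "seed": self.seed,
            },
            indent=2,
        )


def landscape_estimate(
    fitted: FittedModel,
    dataset: SurveyDataset,
    B: int = 100,
    seed: int = 0,
    variance_mode: str = "delta",
    total_forest_area: float | None = None,
) -> LandscapeEstimate:
    """End-to-end landscape estimator for a fitted occupancy model."""
    from .survey_data import summarize_survey

    total = float(total_forest_area) if total_forest_area else float(dataset.forest_area.sum())
    w = area_weights(dataset, total)
    psi = predict_site_psi(fitted, dataset)
    p = predict_site_p(fitted, dataset)
    psi_bar = overall_occupancy(psi, w)
    se = overall_se(fitted, dataset, B=B, seed=seed, variance_mode=variance_mode,
                    total_forest_area=total)
    naive = summarize_survey(dataset).naive_occupancy
    rep = occupied_area(psi_bar, total, naive)
    return LandscapeEstimate(
        site_psi=psi,
        site_psi_se=np.sqrt(delta_method_psi_variance(fitted, dataset)),
        site_p=p,
        weights=w,
        overall_psi=psi_bar,
        overall_se=se,
        total_forest_area_km2=total,
        occupied_area_km2=rep.occupied_area_km2,
        occupied_area_se_km2=se * total,
        naive_occupancy=naive,
        naive_area_km2=rep.naive_area_km2,
        underestimation_km2=rep.underestimation_km2,
        B=B,
        seed=seed,
    )
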