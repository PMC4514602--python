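"""Candidate-set construction, collinearity screening, AIC ranking,
Akaike weights, and the two-step (detection-first) selection procedure.

The selection protocol mirrors common practice for sign-survey occupancy
analyses: covariate pairs with |Pearson r| above a threshold (default 0.7)
never enter the same model; detectability structures are ranked first under
a fixed, moderately parameterised occupancy structure; the minimum-AIC
detectability structure is then held fixed while occupancy structures are
ranked.  No model averaging is performed.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .occupancy_models import FitOptions, FittedModel, ModelSpec, fit_model
from .survey_data import SurveyDataset, parse_formula

__all__ = [
    "AICTable",
    "collinearity_screen",
    "aic_rank",
    "aic_table_from_values",
    "summed_weights",
    "predictor_membership",
    "two_step_selection",
]

logger = logging.getLogger(__name__)


@dataclass
class AICTable:
    """Ranked model-comparison table.

    ``table`` columns: model, AIC, delta_AIC, AIC_weight,
    model_likelihood, n_params, deviance — ascending in AIC, ties broken
    by fewer parameters then name.  Weights sum to 1 over the table.
    """

    table: pd.DataFrame

    def __post_init__(self):
        w = self.table["AIC_weight"].to_numpy()
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("Akaike weights must sum to 1")
        if abs(float(self.table["delta_AIC"].iloc[0])) > 1e-12:
            raise ValueError("first-row delta AIC must be 0")

    @property
    def top_model(self) -> str:
        return str(self.table.iloc[0]["model"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def aic_table_from_values(
    models: Sequence[str],
    aic: Sequence[float],
    n_params: Sequence[int] | None = None,
    deviance: Sequence[float] | None = None,
) -> AICTable:
    """Pure-arithmetic AIC table: ΔAIC, model likelihood exp(−ΔAIC/2) and
    normalized Akaike weights, from AIC values alone."""
    df = pd.DataFrame({"model": list(models), "AIC": np.asarray(aic, dtype=float)})
    df["n_params"] = np.asarray(n_params, dtype=int) if n_params is not None else -1
    df["deviance"] = np.asarray(deviance, dtype=float) if deviance is not None else np.nan
    df = df.sort_values(["AIC", "n_params", "model"], kind="mergesort").reset_index(drop=True)
    df["delta_AIC"] = df["AIC"] - df["AIC"].iloc[0]
    df["model_likelihood"] = np.exp(-df["delta_AIC"] / 2.0)
    df["AIC_weight"] = df["model_likelihood"] / df["model_likelihood"].sum()
    return AICTable(
        df[["model", "AIC", "delta_AIC", "AIC_weight", "model_likelihood", "n_params", "deviance"]]
    )


def aic_rank(fits: Iterable[FittedModel]) -> AICTable:
    """Rank fitted models by AIC.  Non-converged fits are excluded with a
    warning rather than contaminating the weights."""
    usable = []
    for f in fits:
        if f.converged:
            usable.append(f)
        else:
            logger.warning("aic_rank: excluding non-converged fit %s", f.spec.name)
    if not usable:
        raise ValueError("aic_rank: no converged fits")
    return aic_table_from_values(
        [f.spec.name for f in usable],
        [f.aic for f in usable],
        [f.n_params for f in usable],
        [f.deviance for f in usable],
    )


# ---------------------------------------------------------------------------
# Collinearity screen
# ---------------------------------------------------------------------------

def collinearity_screen(
    covariate_table: pd.DataFrame, threshold: float = 0.7
) -> list[tuple[str, str, float]]:
    """All covariate pairs with |Pearson r| > threshold, as
    (name_a, name_b, r) triples.  Candidate models containing a flagged
    pair must be rejected from the set."""
    cols = list(covariate_table.columns)
    if len(cols) < 2 or len(covariate_table) < 3:
        raise ValueError("collinearity screen needs >= 2 covariates and >= 3 sites")
    for c in cols:
        if np.std(covariate_table[c].to_numpy(dtype=float)) == 0.0:
            raise ValueError(f"covariate {c!r} has zero variance")
    flagged = []
    for a, b in itertools.combinations(cols, 2):
        r = float(np.corrcoef(covariate_table[a], covariate_table[b])[0, 1])
        if abs(r) > threshold:
            flagged.append((a, b, r))
    return flagged


def _formula_covariates(formula: str) -> set[str]:
    out = set()
    for t in parse_formula(formula):
        if t == "1":
            continue
        out.update(s.strip() for s in t.split("*"))
    return out


def _violates(formula: str, excluded_pairs: Sequence[tuple[str, str, float]]) -> bool:
    covs = _formula_covariates(formula)
    return any({a, b} <= covs for a, b, _ in excluded_pairs)


# ---------------------------------------------------------------------------
# Summed Akaike weights
# ---------------------------------------------------------------------------

def predictor_membership(models: Sequence[str], predictors: Sequence[str]) -> dict[str, list[str]]:
    """Which models contain each predictor, judged from the ψ(...) part of
    the model name (main effects and interactions both count)."""
    out: dict[str, list[str]] = {p: [] for p in predictors}
    for m in models:
        match = re.match(r"psi\(([^)]*)\)", m)
        covs = _formula_covariates(match.group(1)) if match else set()
        for p in predictors:
            if p in covs:
                out[p].append(m)
    return out


def summed_weights(aic_table: AICTable, membership: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Per-predictor sum of Akaike weights over the models containing it.

    This is the literal sum over *all* containing models; a predictor in no
    model gets 0.  Unknown model names in the membership map raise."""
    tab = aic_table.table.set_index("model")["AIC_weight"]
    out = {}
    for pred, models in membership.items():
        for m in models:
            if m not in tab.index:
                raise KeyError(f"model {m!r} not present in the AIC table")
        out[pred] = float(tab.loc[list(models)].sum()) if len(models) else 0.0
    return out


# ---------------------------------------------------------------------------
# Two-step selection
# ---------------------------------------------------------------------------

def two_step_selection(
    dataset: SurveyDataset,
    p_formulas: Sequence[str] = reference.DETECTION_STEP_P_FORMULAS,
    psi_formulas: Sequence[str] = reference.OCCUPANCY_STEP_PSI_FORMULAS,
    conditioning_psi: str = reference.CONDITIONING_PSI_FORMULA,
    collinearity_threshold: float = 0.7,
    screen_covariates: Sequence[str] = ("PropFor", "LVS", "AnnuRain", "NDVI", "CVNDVI"),
    options: FitOptions | None = None,
) -> dict:
    """Detection-first two-step AIC selection.

    Step 1 fits every detectability formula under the fixed conditioning
    occupancy structure and ranks by AIC; step 2 fixes the winning
    detectability formula and ranks the occupancy formulas.  Models whose
    formula joins a collinear covariate pair are dropped before fitting;
    per-model fit failures are collected and selection proceeds on the
    survivors.

    Returns a dict with ``detection_table``, ``occupancy_table``,
    ``top_model`` (FittedModel), ``excluded_pairs``, ``rejected_models``
    and ``failures``.
    """
    pairs = collinearity_screen(dataset.covariates[list(screen_covariates)], collinearity_threshold)
    rejected, failures = [], []

    def run(formulas, make_spec):
        fits = []
        for f in formulas:
            if _violates(f, pairs):
                rejected.append(f)
                logger.info("rejecting %r: contains a collinear covariate pair", f)
                continue
            spec = make_spec(f)
            try:
                fits.append(fit_model(spec, dataset, options))
            except Exception as exc:
                failures.append((spec.name, str(exc)))
                logger.warning("fit failed for %s: %s", spec.name, exc)
        if not fits:
            raise ValueError("no candidate model could be fitted")
        return fits

    step1 = run(p_formulas, lambda f: ModelSpec(conditioning_psi, f, dependence="markov"))
    detection_table = aic_rank(step1)
    best_p = re.search(r"p\(([^)]*)\)", detection_table.top_model).group(1)

    step2_fits = run(psi_formulas, lambda f: ModelSpec(f, best_p, dependence="markov"))
    occupancy_table = aic_rank(step2_fits)
    by_name = {f.spec.name: f for f in step2_fits}
    return {
        "detection_table": detection_table,
        "occupancy_table": occupancy_table,
        "best_p_formula": best_p,
        "top_model": by_name[occupancy_table.top_model],
        "excluded_pairs": pairs,
        "rejected_models": rejected,
        "failures": failures,
    }
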