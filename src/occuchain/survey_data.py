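"""Survey data containers, I/O, covariate scaling and design matrices.

Detection–non-detection sign surveys record, for each site (grid cell), an
ordered sequence of binary outcomes over 1-km trail replicates, together with
site-level covariates and the forest area of the cell.  Sites have unequal
effort (ragged histories), and individual replicates may be missing.

The canonical covariate names used in model formulas are::

    PropFor   proportion of the cell under forest, in [0, 1]
    LVS       proportion of replicates with livestock sign, in [0, 1]
    AnnuRain  mean annual rainfall, scaled (see :func:`scale_rainfall`)
    NDVI      mean dry-season NDVI over forest pixels
    NDVISQ    NDVI squared (quadratic response term)
    CVNDVI    coefficient of variation of NDVI within the cell
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurveyDataset",
    "SurveySummary",
    "COVARIATE_NAMES",
    "load_survey",
    "scale_rainfall",
    "parse_formula",
    "build_design_matrix",
    "summarize_survey",
]

#: Canonical model-formula covariate names, in display order.
COVARIATE_NAMES = ("PropFor", "LVS", "AnnuRain", "NDVI", "NDVISQ", "CVNDVI")

#: Default mapping from CSV column headers to canonical covariate names.
#: ``meanrain_mm`` is raw rainfall in mm/yr; ``AnnuRain`` is derived from it.
DEFAULT_COVARIATE_COLUMNS: Mapping[str, str] = {
    "propfor": "PropFor",
    "lvs": "LVS",
    "meanndvi": "NDVI",
    "cvndvi": "CVNDVI",
}

_MISSING_TOKENS = {"", "na", "nan", "-", "."}


@dataclass
class SurveyDataset:
    """Ragged detection histories plus site covariates and forest areas.

    ``histories`` holds one float array per site with entries 0.0, 1.0 or NaN
    (missing replicate); ``covariates`` is indexed like ``site_ids`` and
    carries the canonical covariate columns; ``forest_area`` is in km².
    """

    site_ids: list
    histories: list
    covariates: pd.DataFrame
    forest_area: np.ndarray

    def __post_init__(self):
        self.forest_area = np.asarray(self.forest_area, dtype=float)
        self.histories = [np.asarray(h, dtype=float) for h in self.histories]
        self._validate()

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        n = len(self.site_ids)
        if n == 0:
            raise ValueError("dataset has no sites")
        if len(set(self.site_ids)) != n:
            raise ValueError("site ids are not unique")
        if len(self.histories) != n or len(self.covariates) != n or len(self.forest_area) != n:
            raise ValueError("site_ids, histories, covariates and forest_area lengths differ")
        for sid, h in zip(self.site_ids, self.histories):
            if h.size < 1:
                raise ValueError(f"site {sid!r}: history must contain at least one replicate")
            finite = h[~np.isnan(h)]
            if not np.isin(finite, (0.0, 1.0)).all():
                raise ValueError(f"site {sid!r}: history entries must be 0, 1 or missing")
        if np.any(self.forest_area < 0):
            raise ValueError("forest_area must be non-negative")
        for col in ("PropFor", "LVS"):
            if col in self.covariates:
                v = self.covariates[col].to_numpy(dtype=float)
                if np.any((v < 0) | (v > 1)):
                    raise ValueError(f"{col} must lie in [0, 1]")

    # -- basic shape ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def replicate_counts(self) -> np.ndarray:
        """Number of replicate slots per site (missing slots included)."""
        return np.array([h.size for h in self.histories], dtype=int)

    def history_matrix(self) -> np.ndarray:
        """(n_sites, K_max) float matrix, NaN-padded past each site's K_i."""
        kmax = int(self.replicate_counts.max())
        out = np.full((self.n_sites, kmax), np.nan)
        for i, h in enumerate(self.histories):
            out[i, : h.size] = h
        return out

    # -- round-trip I/O ------------------------------------------------
    def to_long(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Export (detections, covariates) tables in the CSV interchange layout."""
        rows = []
        for sid, h in zip(self.site_ids, self.histories):
            for j, v in enumerate(h, start=1):
                rows.append((sid, j, "" if np.isnan(v) else int(v)))
        det = pd.DataFrame(rows, columns=["site_id", "replicate_index", "detection"])
        cov = pd.DataFrame(
            {
                "site_id": self.site_ids,
                "propfor": self.covariates["PropFor"].to_numpy(),
                "lvs": self.covariates["LVS"].to_numpy(),
                "meanrain_mm": self.covariates["RainMM"].to_numpy(),
                "meanndvi": self.covariates["NDVI"].to_numpy(),
                "cvndvi": self.covariates["CVNDVI"].to_numpy(),
                "forest_km2": self.forest_area,
            }
        )
        return det, cov

    def save(self, detections_path, covariates_path) -> None:
        det, cov = self.to_long()
        det.to_csv(detections_path, index=False)
        cov.to_csv(covariates_path, index=False)


@dataclass
class SurveySummary:
    """Naive (detection-ignorant) summaries of a survey."""

    n_sites: int
    total_replicates: int
    total_detected_replicates: int
    n_sites_with_detection: int
    naive_occupancy: float
    replicate_detection_proportion: float
    mean_effort_km: float


def scale_rainfall(raw_mm: Iterable[float]) -> np.ndarray:
    """Scale raw annual rainfall (mm) by subtracting the minimum and
    multiplying by 0.001, so the scaled covariate starts at 0.

    The minimum is taken from the supplied values, not hard-coded, so
    synthetic and field data scale consistently.
    """
    x = np.asarray(list(raw_mm), dtype=float)
    if x.size == 0:
        raise ValueError("scale_rainfall: empty input")
    if not np.isfinite(x).any():
        raise ValueError("scale_rainfall: no finite values")
    return (x - np.nanmin(x)) * 0.001


def _parse_detection_value(v) -> float:
    if isinstance(v, str):
        if v.strip().lower() in _MISSING_TOKENS:
            return np.nan
        v = float(v)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return np.nan
    f = float(v)
    if f not in (0.0, 1.0):
        raise ValueError(f"detection outcome must be 0, 1 or missing, got {v!r}")
    return f


def load_survey(
    detections,
    covariates,
    column_map: Mapping[str, str] | None = None,
) -> SurveyDataset:
    """Assemble a :class:`SurveyDataset` from long-format tables.

    Parameters
    ----------
    detections
        DataFrame or CSV path with columns ``site_id``, ``replicate_index``
        (1-based, consecutive within site) and ``detection`` (0/1, or one of
        the missing markers "", "NA", "-").
    covariates
        DataFrame or CSV path keyed by ``site_id`` with columns ``propfor``,
        ``lvs``, ``meanrain_mm``, ``meanndvi``, ``cvndvi``, ``forest_km2``.
        Header names can be remapped via ``column_map`` (worksheet exports of
        deposited data rarely agree on naming), given as
        ``{actual_header: canonical_header}``.

    Derived covariates are attached on load: ``AnnuRain`` from
    :func:`scale_rainfall` and ``NDVISQ`` as NDVI squared.  Replicate-level
    covariate columns in the detection table are rejected: this model family
    supports site-level covariates only.
    """
    det = pd.read_csv(detections, dtype={"detection": "object"}) if not isinstance(detections, pd.DataFrame) else detections.copy()
    cov = pd.read_csv(covariates) if not isinstance(covariates, pd.DataFrame) else covariates.copy()
    if column_map:
        det = det.rename(columns=column_map)
        cov = cov.rename(columns=column_map)
    det.columns = [c.lower() for c in det.columns]
    cov.columns = [c.lower() for c in cov.columns]

    required_det = {"site_id", "replicate_index", "detection"}
    if set(det.columns) != required_det:
        extra = set(det.columns) - required_det
        missing = required_det - set(det.columns)
        if missing:
            raise ValueError(f"detections table missing columns: {sorted(missing)}")
        raise ValueError(
            f"unexpected detection-table columns {sorted(extra)}: replicate-level "
            "covariates are not supported; covariates are site-level only"
        )
    required_cov = {"site_id", "propfor", "lvs", "meanrain_mm", "meanndvi", "cvndvi", "forest_km2"}
    missing = required_cov - set(cov.columns)
    if missing:
        raise ValueError(f"covariates table missing columns: {sorted(missing)}")

    if cov["site_id"].duplicated().any():
        raise ValueError("duplicate site_id in covariates table")
    if det.duplicated(["site_id", "replicate_index"]).any():
        raise ValueError("duplicate (site_id, replicate_index) in detections table")

    det_sites = set(det["site_id"])
    cov_sites = set(cov["site_id"])
    if det_sites - cov_sites:
        raise ValueError(f"detection sites missing from covariates: {sorted(det_sites - cov_sites)[:5]}")
    if cov_sites - det_sites:
        raise ValueError(f"covariate sites missing from detections: {sorted(cov_sites - det_sites)[:5]}")

    site_ids = list(cov["site_id"])
    histories = []
    grouped = det.groupby("site_id", sort=False)
    for sid in site_ids:
        g = grouped.get_group(sid).sort_values("replicate_index")
        idx = g["replicate_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError(f"site {sid!r}: replicate_index must be consecutive starting at 1")
        histories.append(np.array([_parse_detection_value(v) for v in g["detection"]]))

    table = pd.DataFrame(
        {
            "PropFor": cov["propfor"].to_numpy(dtype=float),
            "LVS": cov["lvs"].to_numpy(dtype=float),
            "RainMM": cov["meanrain_mm"].to_numpy(dtype=float),
            "NDVI": cov["meanndvi"].to_numpy(dtype=float),
            "CVNDVI": cov["cvndvi"].to_numpy(dtype=float),
        }
    )
    table["AnnuRain"] = scale_rainfall(table["RainMM"])
    table["NDVISQ"] = table["NDVI"] ** 2
    return SurveyDataset(
        site_ids=site_ids,
        histories=histories,
        covariates=table,
        forest_area=cov["forest_km2"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Model formulas and design matrices
# ---------------------------------------------------------------------------

def parse_formula(formula: str) -> list[str]:
    """Expand a model formula into an explicit term list.

    ``"."`` denotes the intercept-only model; ``"+"`` separates additive
    terms; ``"A*B"`` expands to both main effects plus the ``A*B``
    interaction (interaction models always include their main effects).
    Squared covariates are named terms in their own right (e.g. ``NDVISQ``).

    >>> parse_formula("LVS*NDVI")
    ['1', 'LVS', 'NDVI', 'LVS*NDVI']
    """
    terms: list[str] = ["1"]
    formula = formula.strip()
    if formula in (".", "", "1"):
        return terms
    for part in formula.split("+"):
        part = part.strip()
        if "*" in part:
            a, b = (s.strip() for s in part.split("*"))
            for main in (a, b):
                if main not in terms:
                    terms.append(main)
            terms.append(f"{a}*{b}")
        elif part not in terms:
            terms.append(part)
    return terms


def _column(dataset: SurveyDataset, name: str) -> np.ndarray:
    cov = dataset.covariates
    if name in cov.columns:
        return cov[name].to_numpy(dtype=float)
    # case-insensitive fallback
    for c in cov.columns:
        if c.lower() == name.lower():
            return cov[c].to_numpy(dtype=float)
    raise KeyError(f"unknown covariate {name!r}; available: {list(cov.columns)}")


def build_design_matrix(dataset: SurveyDataset, terms: Sequence[str]) -> np.ndarray:
    """(n_sites × n_terms) design matrix for a term list.

    Terms are the intercept (``"1"`` or ``"intercept"``), a covariate name,
    an interaction ``"A*B"`` (elementwise product), or a square ``"A^2"``.
    """
    n = dataset.n_sites
    cols = []
    for t in terms:
        t = t.strip()
        if t in ("1", "intercept", "."):
            cols.append(np.ones(n))
        elif "*" in t:
            a, b = (s.strip() for s in t.split("*"))
            cols.append(_column(dataset, a) * _column(dataset, b))
        elif t.endswith("^2"):
            cols.append(_column(dataset, t[:-2].strip()) ** 2)
        else:
            cols.append(_column(dataset, t))
    return np.column_stack(cols)


def summarize_survey(dataset: SurveyDataset) -> SurveySummary:
    """Naive summaries: missing replicates are excluded from replicate
    counts; a site counts as detected if any non-missing replicate is 1."""
    H = dataset.history_matrix()
    observed = ~np.isnan(H)
    total = int(observed.sum())
    detected = int(np.nansum(H))
    site_det = int((np.nansum(H, axis=1) > 0).sum())
    n = dataset.n_sites
    return SurveySummary(
        n_sites=n,
        total_replicates=total,
        total_detected_replicates=detected,
        n_sites_with_detection=site_det,
        naive_occupancy=site_det / n,
        replicate_detection_proportion=detected / total if total else 0.0,
        mean_effort_km=total / n,
    )
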