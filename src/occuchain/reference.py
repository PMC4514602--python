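"""Published reference estimates from the motivating field study.

The package re-implements the occupancy analysis of a landscape-scale Asian
elephant sign survey in the Western Ghats of Karnataka, India: 205 grid
cells (sites) of 188 km², 21,167 km² of forest, 4–42 one-km trail replicates
per cell.  The study's published model-selection tables and parameter
estimates are recorded here so that

* pure-arithmetic stages (ΔAIC, model likelihoods, Akaike weights, summed
  weights, the stationary first-replicate presence probability, occupied
  area) can be recomputed from the printed inputs, and
* the synthetic-survey generator can default to the published operating
  point.

Only printed numbers live here; nothing in this module is estimated.
"""

from __future__ import annotations

import pandas as pd

# -- survey description ------------------------------------------------
N_SITES = 205
TOTAL_REPLICATES = 4172          # total 1-km walk effort
DETECTED_REPLICATES = 1230       # replicates with >= 1 fresh dung detection
SITES_WITH_DETECTION = 110
TOTAL_DUNG_DETECTIONS = 2712
NAIVE_OCCUPANCY = 0.537          # 110 / 205
REPLICATE_DETECTION_PROPORTION = 0.295  # 1230 / 4172
MEAN_EFFORT_KM = 20.36
CELL_AREA_KM2 = 188.0
TOTAL_FOREST_AREA_KM2 = 21_167.0
REPLICATES_PER_SITE_RANGE = (4, 42)

# -- rainfall summaries (mm/yr, per-cell long-term means) ---------------
RAIN_MIN_MM = 630.0
RAIN_MEAN_MM = 2515.0
RAIN_MAX_MM = 5883.0
RAIN_NDVI_PEARSON_R = 0.81

# -- dependence test (intercept-only fits) ------------------------------
DELTA_AIC_DEPENDENCE = 641.7     # standard minus markov
THETA_NULL = 0.084               # markov fit, Pr(present | previous absent)
THETA_PRIME_NULL = 0.953         # markov fit, Pr(present | previous present)
P_MARKOV_NULL = 0.737            # detection given presence, markov fit
P_STANDARD_NULL = 0.511          # detection, standard fit (negatively biased)

# -- top model (psi(LVS*NDVI), p(LVS+PropFor)) --------------------------
THETA_TOP = 0.082
THETA_PRIME_TOP = 0.962
THETA0_TOP = 0.683               # stationary initial presence probability
TOP_MODEL_AIC = 2849.53
TOP_MODEL_N_PARAMS = 9
SITE_P_RANGE = (0.56, 0.88)
SITE_PSI_RANGE = (0.19, 0.98)

#: β estimates (SE) for the four occupancy models within ΔAIC < 10.
TOP_MODEL_BETA = {
    "psi_1": (5.582, 1.655),
    "psi_LVS": (-2.181, 1.014),
    "psi_NDVI": (-3.417, 1.973),
    "psi_LVS*NDVI": (-2.831, 0.467),
}

# -- landscape-level estimates ------------------------------------------
OVERALL_PSI = 0.637
OVERALL_PSI_SE = 0.04
OCCUPIED_AREA_KM2 = 13_483.0
OCCUPIED_AREA_SE_KM2 = 847.0
NAIVE_AREA_KM2 = 11_367.0
UNDERESTIMATION_KM2 = 2116.0
BOOTSTRAP_DRAWS = 100            # multivariate-normal deviates; divisor 99

# -- model-selection tables ---------------------------------------------
#: Step 1 — detectability structures under ψ(PropFor+NDVI+LVS): published
#: (model, AIC, n_params, deviance).
DETECTION_STEP_TABLE = pd.DataFrame(
    [
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(LVS+PropFor)", 2890.8, 9, 2872.8),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(LVS+PropFor+AnnuRain)", 2892.18, 10, 2872.18),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(LVS+PropFor+NDVI)", 2892.79, 10, 2872.79),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(LVS)", 2896.01, 8, 2880.01),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(LVS+AnnuRain)", 2897.11, 9, 2879.11),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(LVS+NDVI)", 2897.75, 9, 2879.75),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(.)", 2932.15, 7, 2918.15),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(AnnuRain)", 2933.19, 8, 2917.19),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(NDVI)", 2933.68, 8, 2917.68),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(AnnuRain+PropFor)", 2934.28, 9, 2916.28),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(NDVI+PropFor)", 2934.71, 9, 2916.71),
        ("psi(PropFor+NDVI+LVS),thta0,thta1,p(PropFor)", 2938.83, 8, 2922.83),
    ],
    columns=["model", "AIC", "n_params", "deviance"],
)

#: Step 2 — occupancy structures under p(LVS+PropFor): published
#: (model, AIC, n_params, deviance).
OCCUPANCY_STEP_TABLE = pd.DataFrame(
    [
        ("psi(LVS*NDVI),thta0,thta1,p(LVS+PropFor)", 2849.53, 9, 2831.53),
        ("psi(LVS+PropFor+AnnuRain),thta0,thta1,p(LVS+PropFor)", 2852.56, 9, 2834.56),
        ("psi(LVS+AnnuRain),thta0,thta1,p(LVS+PropFor)", 2852.63, 8, 2836.63),
        ("psi(LVS*AnnuRain),thta0,thta1,p(LVS+PropFor)", 2854.63, 9, 2836.63),
        ("psi(LVS+NDVI),thta0,thta1,p(LVS+PropFor)", 2889.23, 8, 2873.23),
        ("psi(NDVI+NDVISQ+LVS),thta0,thta1,p(LVS+PropFor)", 2889.85, 9, 2871.85),
        ("psi(LVS+PropFor+NDVI),thta0,thta1,p(LVS+PropFor)", 2890.8, 9, 2872.8),
        ("psi(PropFor*AnnuRain),thta0,thta1,p(LVS+PropFor)", 2899.57, 9, 2881.57),
        ("psi(PropFor+AnnuRain),thta0,thta1,p(LVS+PropFor)", 2899.73, 8, 2883.73),
        ("psi(LVS),thta0,thta1,p(LVS+PropFor)", 2901.53, 7, 2887.53),
        ("psi(LVS+CVNDVI),thta0,thta1,p(LVS+PropFor)", 2903.31, 8, 2887.31),
        ("psi(LVS+PropFor),thta0,thta1,p(LVS+PropFor)", 2903.45, 8, 2887.45),
        ("psi(LVS*PropFor),thta0,thta1,p(LVS+PropFor)", 2905.44, 9, 2887.44),
        ("psi(AnnuRain),thta0,thta1,p(LVS+PropFor)", 2906.13, 7, 2892.13),
        ("psi(NDVI+CVNDVI),thta0,thta1,p(LVS+PropFor)", 2931.58, 8, 2915.58),
        ("psi(NDVI+PropFor),thta0,thta1,p(LVS+PropFor)", 2931.71, 8, 2915.71),
        ("psi(NDVI+NDVISQ+PropFor),thta0,thta1,p(LVS+PropFor)", 2933.15, 9, 2915.15),
        ("psi(NDVI*PropFor),thta0,thta1,p(LVS+PropFor)", 2933.53, 9, 2915.53),
        ("psi(NDVI),thta0,thta1,p(LVS+PropFor)", 2933.56, 7, 2919.56),
        ("psi(NDVI+NDVISQ),thta0,thta1,p(LVS+PropFor)", 2935.19, 8, 2919.19),
        ("psi(PropFor+CVNDVI),thta0,thta1,p(LVS+PropFor)", 2935.31, 8, 2919.31),
        ("psi(.),thta0,thta1,p(LVS+PropFor)", 2935.92, 6, 2923.92),
        ("psi(PropFor),thta0,thta1,p(LVS+PropFor)", 2936.38, 7, 2922.38),
        ("psi(CVNDVI),thta0,thta1,p(LVS+PropFor)", 2936.92, 7, 2922.92),
    ],
    columns=["model", "AIC", "n_params", "deviance"],
)

#: Published summed Akaike weights over occupancy-step models (the rainfall
#: entry as printed; the literal sum over all rain-containing models is
#: 0.3378 — see docs/methods.md).
SUMMED_WEIGHTS_PUBLISHED = {"LVS": 1.0, "NDVI": 0.662, "AnnuRain": 0.1922, "PropFor": 0.1456}

# -- default candidate formula sets (the two selection steps) -----------
CONDITIONING_PSI_FORMULA = "PropFor+NDVI+LVS"
DETECTION_STEP_P_FORMULAS = (
    "LVS+PropFor",
    "LVS+PropFor+AnnuRain",
    "LVS+PropFor+NDVI",
    "LVS",
    "LVS+AnnuRain",
    "LVS+NDVI",
    ".",
    "AnnuRain",
    "NDVI",
    "AnnuRain+PropFor",
    "NDVI+PropFor",
    "PropFor",
)
OCCUPANCY_STEP_PSI_FORMULAS = (
    "LVS*NDVI",
    "LVS+PropFor+AnnuRain",
    "LVS+AnnuRain",
    "LVS*AnnuRain",
    "LVS+NDVI",
    "NDVI+NDVISQ+LVS",
    "LVS+PropFor+NDVI",
    "PropFor*AnnuRain",
    "PropFor+AnnuRain",
    "LVS",
    "LVS+CVNDVI",
    "LVS+PropFor",
    "LVS*PropFor",
    "AnnuRain",
    "NDVI+CVNDVI",
    "NDVI+PropFor",
    "NDVI+NDVISQ+PropFor",
    "NDVI*PropFor",
    "NDVI",
    "NDVI+NDVISQ",
    "PropFor+CVNDVI",
    ".",
    "PropFor",
    "CVNDVI",
)
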