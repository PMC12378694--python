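"""Feature-level cohort generator.

Bypasses the signal pipeline: patients' 12 CCEP features are drawn directly
from the per-group target Gaussians (independently by default, or through a
Gaussian copula when a correlation matrix is configured), clinical covariates
follow the cohort table's per-group distributions, and the outcome label is
the group itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig
from .errors import InvalidConfigError
from .schema import (
    CCEP_FEATURES,
    CLINICAL_BINARY,
    OUTCOME_COLUMN,
    PREDICTOR_COLUMNS,
)
from .seeds import stage_rng
from .targets import ClinicalParams, FeatureTargets


def generate_clinical(
    patient_groups: pd.Series, params: ClinicalParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical covariates for each patient id -> group mapping."""
    p = params.params
    rows = {}
    for pid, group in patient_groups.items():
        row = {}
        for col in CLINICAL_BINARY:
            row[col] = int(rng.random() < p["rates"][col][group])
        row["age_onset"] = float(p["age_onset"][group].sample(rng, 1)[0])
        row["age_surgery"] = float(p["age_surgery"][group].sample(rng, 1)[0])
        row["duration"] = float(p["duration"][group].sample(rng, 1)[0])
        mu, sd = p["asm"][group]
        row["asm_count"] = int(np.clip(np.round(rng.normal(mu, sd)), 1, 8))
        rows[pid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def patient_ids(config: CohortConfig) -> pd.Series:
    ids = [f"SF{i:03d}" for i in range(config.n_sf)] + [
        f"NSF{i:03d}" for i in range(config.n_nsf)
    ]
    groups = ["SF"] * config.n_sf + ["nSF"] * config.n_nsf
    return pd.Series(groups, index=ids, name="group")


def generate_feature_cohort(
    config: CohortConfig,
    targets: FeatureTargets,
    clinical_params: ClinicalParams,
    seed: int,
    feature_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Patient table: 12 CCEP features + 9 clinical covariates + outcome."""
    config.validate()
    targets.validate()
    groups = patient_ids(config)
    rng = stage_rng(seed, "feature_cohort")

    if feature_corr is not None:
        feature_corr = np.asarray(feature_corr, dtype=float)
        if feature_corr.shape != (len(CCEP_FEATURES),) * 2:
            raise InvalidConfigError("feature_corr must be 12x12")
        chol = np.linalg.cholesky(feature_corr)

    feat_rows = {}
    for pid, group in groups.items():
        z = rng.standard_normal(len(CCEP_FEATURES))
        if feature_corr is not None:
            z = chol @ z
        row = {}
        for k, feature in enumerate(CCEP_FEATURES):
            m = targets.feature_mean(feature, group)
            s = targets.feature_sd(feature, group)
            row[feature] = m + s * z[k]
        feat_rows[pid] = row
    feats = pd.DataFrame.from_dict(feat_rows, orient="index")

    clin_rng = stage_rng(seed, "clinical")
    clinical = generate_clinical(groups, clinical_params, clin_rng)

    table = feats.join(clinical)[list(PREDICTOR_COLUMNS)]
    table[OUTCOME_COLUMN] = groups
    return table
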