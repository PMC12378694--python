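"""Directional connectivity features from evoked waveforms.

Each retained directed edge (stimulated bipolar pair -> recording channel)
yields the RMS of its trial-averaged response in the N1 (10-50 ms) and N2
(80-250 ms) post-pulse windows.  RMS values are z-scored within patient and
per component over all retained edges, assigned to connectivity categories by
zone (IR: SOZ <-> in-resection, OR: SOZ <-> outside, IO: resection <->
outside, each split into OUT/IN by stimulation side; OR edges also count
toward IO because the SOZ lies inside the resection), and averaged per
category into the patient's 12 features.  The 9 clinical covariates complete
the fixed 21-column predictor table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    InvalidInputError,
    MissingCategoryError,
    MissingDataError,
)
from .schema import (
    CATEGORY_CLASSES,
    CCEP_FEATURES,
    CLINICAL_FEATURES,
    COMPONENT_WINDOWS_MS,
    OUTCOME_COLUMN,
    PREDICTOR_COLUMNS,
)


def rms(waveform: np.ndarray, window_ms: tuple, fs: float = 1000.0, pulse_sample: int = 500) -> float:
    """Root-mean-square over a half-open post-pulse window [lo, hi) ms."""
    lo = pulse_sample + int(round(window_ms[0] / 1000.0 * fs))
    hi = pulse_sample + int(round(window_ms[1] / 1000.0 * fs))
    if lo < 0 or hi > waveform.shape[-1] or lo >= hi:
        raise InvalidInputError(f"window {window_ms} outside waveform")
    seg = waveform[..., lo:hi]
    return float(np.sqrt(np.mean(np.square(seg), axis=-1))) if seg.ndim == 1 else np.sqrt(
        np.mean(np.square(seg), axis=-1)
    )


def component_rms(waveform: np.ndarray, fs: float = 1000.0, pulse_sample: int = 500) -> dict:
    return {
        comp: rms(waveform, win, fs=fs, pulse_sample=pulse_sample)
        for comp, win in COMPONENT_WINDOWS_MS.items()
    }


def _zone(row) -> str:
    if row["is_soz"]:
        if not row["in_resection"]:
            raise ConsistencyError(f"SOZ channel {row.get('channel_id')} outside resection")
        return "soz"
    return "ir" if row["in_resection"] else "or"


def classify_edge(stim_row, rec_row) -> list[tuple[str, str]]:
    """Categories (with direction) of a directed stimulation->recording edge.

    Returns a list of (category, direction) pairs; empty for edges entirely
    inside or entirely outside the resection with no SOZ endpoint.
    """
    cls = (_zone(stim_row), _zone(rec_row))
    out = []
    for key, classes in CATEGORY_CLASSES.items():
        if cls in classes:
            out.append(key)
    return out


def zscore_within_patient(values: np.ndarray) -> np.ndarray:
    """Z-scores over a patient's pooled retained edges (sample sd, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 edges to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance across edges")
    return (x - x.mean()) / sd


def edge_table(edge_records: list[dict]) -> pd.DataFrame:
    """Edge-level frame with z-scores added per component.

    Each record needs stim_channel, record_channel, stim_zone, rec_zone,
    rms_N1, rms_N2.
    """
    df = pd.DataFrame(edge_records)
    for comp in ("N1", "N2"):
        df[f"z_{comp}"] = zscore_within_patient(df[f"rms_{comp}"].to_numpy())
    return df


def aggregate_patient(edges: pd.DataFrame) -> dict:
    """Mean z-scored RMS per category -> the patient's 12 CCEP features."""
    feats = {}
    missing = []
    cls_col = list(zip(edges["stim_zone"], edges["rec_zone"]))
    for feature in CCEP_FEATURES:
        cat, comp, direction = feature.split("_")
        classes = set(CATEGORY_CLASSES[(cat, direction)])
        sel = np.array([c in classes for c in cls_col])
        if not sel.any():
            missing.append(feature)
            continue
        feats[feature] = float(edges.loc[sel, f"z_{comp}"].mean())
    if missing:
        raise MissingCategoryError(missing)
    return feats


def assemble_feature_table(
    ccep_features: pd.DataFrame, clinical: pd.DataFrame, outcomes: pd.Series
) -> pd.DataFrame:
    """Join per-patient CCEP features, clinical covariates and outcome.

    All frames are indexed by patient id.  Output columns follow the fixed
    21-column predictor schema plus the outcome.
    """
    for pid in ccep_features.index:
        if pid not in clinical.index:
            raise MissingDataError(f"patient {pid}: clinical record missing")
        row = clinical.loc[pid]
        for col in CLINICAL_FEATURES:
            if col not in clinical.columns or pd.isna(row[col]):
                raise MissingDataError(f"patient {pid}: clinical field {col!r} missing")
    table = ccep_features.join(clinical[list(CLINICAL_FEATURES)], how="inner")
    table = table[list(PREDICTOR_COLUMNS)]
    table[OUTCOME_COLUMN] = outcomes.reindex(table.index)
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise MissingDataError(f"missing values after assembly in {bad}")
    return table


def correlation_screen(table: pd.DataFrame, threshold: float = 0.8):
    """Pairwise Pearson correlations of the predictor columns.

    Returns (max_abs_r, flagged pair frame, correlation matrix).  Zero-variance
    columns are excluded with a warning.
    """
    import warnings

    preds = table[list(PREDICTOR_COLUMNS)]
    if len(preds) < 3:
        raise InvalidInputError("need at least 3 rows for a correlation screen")
    variances = preds.var()
    dead = variances[variances == 0].index.tolist()
    if dead:
        warnings.warn(f"zero-variance columns excluded from screen: {dead}", stacklevel=2)
        preds = preds.drop(columns=dead)
    corr = preds.corr()
    a = corr.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    max_abs = float(np.abs(a).max())
    flagged = []
    cols = corr.columns
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(a[i, j]) > threshold:
                flagged.append(dict(feature_a=cols[i], feature_b=cols[j], r=float(a[i, j])))
    return max_abs, pd.DataFrame(flagged, columns=["feature_a", "feature_b", "r"]), corr
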