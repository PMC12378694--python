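"""Univariate group statistics with normality-gated test selection.

Continuous comparisons run a Shapiro-Wilk normality check in each group and a
Levene (median-centred) variance-homogeneity check; if all pass at the gate
level, a two-sided Student's t-test is used, otherwise a two-sided
Mann-Whitney U (normal approximation with tie correction).  Categorical 2x2
tables use the Yates-corrected chi-square; multiple comparisons are adjusted
by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError


@dataclass
class GroupComparison:
    feature: str
    test: str
    statistic: float
    p_raw: float
    p_fdr: Optional[float] = None
    summaries: dict = field(default_factory=dict)


def compare_continuous(
    a: np.ndarray, b: np.ndarray, alpha_gate: float = 0.05, feature: str = ""
) -> GroupComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InvalidInputError("each group needs n >= 3")
    if np.array_equal(a, b):
        # identical groups: t statistic is exactly 0, SW gate irrelevant
        return GroupComparison(feature, "t", 0.0, 1.0, summaries=_summ(a, b))
    normal = (sps.shapiro(a).pvalue > alpha_gate) and (sps.shapiro(b).pvalue > alpha_gate)
    if normal:
        homo = sps.levene(a, b, center="median").pvalue > alpha_gate
    else:
        homo = False
    if normal and homo:
        res = sps.ttest_ind(a, b)
        return GroupComparison(feature, "t", float(res.statistic), float(res.pvalue),
                               summaries=_summ(a, b))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(feature, "mann-whitney", float(res.statistic), float(res.pvalue),
                           summaries=_summ(a, b))


def _summ(a, b) -> dict:
    return {
        "a": (float(np.mean(a)), float(np.std(a, ddof=1))),
        "b": (float(np.mean(b)), float(np.std(b, ddof=1))),
    }


def compare_categorical(table: np.ndarray, feature: str = "") -> GroupComparison:
    """Yates-corrected chi-square on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise InvalidInputError("need a 2x2 table of nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidInputError("zero margin in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=True)
    assert dof == 1
    return GroupComparison(feature, "chi-square-yates", float(chi2), float(p),
                           summaries={"counts": t.tolist()})


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_feature_table(table: pd.DataFrame, features, group_col: str = "outcome",
                          fdr: bool = True) -> pd.DataFrame:
    """Per-feature two-group comparison over a patient table, FDR-adjusted."""
    sf = table[table[group_col] == "SF"]
    nsf = table[table[group_col] == "nSF"]
    comps = [
        compare_continuous(sf[f].to_numpy(), nsf[f].to_numpy(), feature=f) for f in features
    ]
    out = pd.DataFrame(
        [
            dict(
                feature=c.feature,
                test=c.test,
                statistic=c.statistic,
                p_raw=c.p_raw,
                sf_mean=c.summaries["a"][0],
                sf_sd=c.summaries["a"][1],
                nsf_mean=c.summaries["b"][0],
                nsf_sd=c.summaries["b"][1],
            )
            for c in comps
        ]
    )
    if fdr:
        out["p_fdr"] = fdr_adjust(out["p_raw"].to_numpy())
    return out


def compare_distance_profiles(profiles: pd.DataFrame) -> dict:
    """Group comparison of per-patient median SOZ distances, per zone.

    ``profiles`` has columns patient_id, group, distance_mm, in_resection.
    Returns {"in_resection": GroupComparison, "out_of_resection": ...}.
    """
    out = {}
    for zone, inside in (("in_resection", True), ("out_of_resection", False)):
        sub = profiles[profiles["in_resection"] == inside]
        med = sub.groupby(["patient_id", "group"], observed=True)["distance_mm"].median().reset_index()
        a = med.loc[med["group"] == "SF", "distance_mm"].to_numpy()
        b = med.loc[med["group"] == "nSF", "distance_mm"].to_numpy()
        out[zone] = compare_continuous(a, b, feature=f"median_soz_distance_{zone}")
    return out
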