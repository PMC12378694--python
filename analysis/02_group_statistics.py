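#!/usr/bin/env python
"""Univariate group comparisons on the simulated cohort.

Reproduces the study's statistical surface: Yates-corrected chi-square tests
on the clinical 2x2 tables, normality-gated two-group tests on the 12 CCEP
features with Benjamini-Hochberg FDR correction, and the SOZ-distance
null comparison (electrode coverage is outcome-independent by construction,
so both zones should be non-significant).

Reads results/cohort/ (run 01 first); writes results/stats/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ccepflow.features import correlation_screen
from ccepflow.schema import CCEP_FEATURES
from ccepflow.stats import (
    compare_categorical,
    compare_distance_profiles,
    compare_feature_table,
)

IN = Path("results/cohort")
OUT = Path("results/stats")

CLINICAL_TABLES = {  # printed cohort 2x2 tables (SF row, nSF row)
    "sex_m_f": [[18, 12], [12, 14]],
    "lateral_l_r": [[18, 12], [10, 16]],
    "hs_y_n": [[16, 14], [13, 13]],
    "mri_pos_neg": [[19, 11], [13, 13]],
    "gtcs_y_n": [[11, 19], [18, 8]],
    "memory_normal_abnormal": [[13, 17], [7, 19]],
}


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, counts in CLINICAL_TABLES.items():
        cmp_ = compare_categorical(np.asarray(counts), feature=name)
        rows.append(dict(variable=name, chi2=cmp_.statistic, p=cmp_.p_raw))
    clin = pd.DataFrame(rows)
    clin.to_csv(OUT / "clinical_chi_square.csv", index=False)
    print("clinical chi-square (Yates):")
    print(clin.round(3).to_string(index=False))

    table = pd.read_csv(IN / "features_signal_level.csv", index_col=0)
    comp = compare_feature_table(table, CCEP_FEATURES)
    comp.to_csv(OUT / "ccep_feature_comparisons.csv", index=False)
    sig = comp[comp.p_fdr < 0.05]
    print(f"\nCCEP features significant after FDR: {sig.feature.tolist()}")

    max_r, flagged, corr = correlation_screen(table)
    corr.to_csv(OUT / "feature_correlations.csv")
    print(f"correlation screen: max |r| = {max_r:.3f}, "
          f"{len(flagged)} pairs above 0.8")

    distances = pd.read_csv(IN / "soz_distances.csv")
    res = compare_distance_profiles(distances)
    pd.DataFrame(
        [dict(zone=z, test=c.test, statistic=c.statistic, p=c.p_raw)
         for z, c in res.items()]
    ).to_csv(OUT / "soz_distance_comparison.csv", index=False)
    print("SOZ-distance group comparison p-values:",
          {z: round(c.p_raw, 3) for z, c in res.items()})


if __name__ == "__main__":
    main()
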