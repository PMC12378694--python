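# ccepflow

Effective-connectivity analysis of stimulation-evoked intracranial EEG
(CCEPs) for predicting the outcome of temporal-lobe-epilepsy surgery — built
as a tested, reusable pipeline over a calibrated synthetic cohort.

## The problem

After SEEG-guided resective surgery for temporal lobe epilepsy, only
~60–80% of patients become seizure-free (Engel I). One candidate predictor
is *effective connectivity*: single-pulse electrical stimulation (SPES) of
one electrode pair evokes a cortico-cortical evoked potential (CCEP) at
distant recording sites, and the amplitude of that response indexes directed
coupling between the stimulated and recording regions. The hypothesis this
package operationalizes: patients whose seizure-onset zone (SOZ) and
resection remain strongly coupled to cortex *outside* the planned resection
are more likely to relapse.

The pipeline turns raw inputs — contact coordinates, a gray-matter
probability volume, a binary resection mask, SOZ labels, and
stimulation-evoked recordings — into:

1. **12 directional connectivity features per patient.** Each directed edge
   (stimulated bipolar pair → recording channel, after excluding the
   stimulated shaft, white-matter channels, and anything within 10 mm) is
   summarized by the RMS of its trial-averaged response in the N1 (10–50 ms)
   and N2 (80–250 ms) windows, z-scored within patient across all retained
   edges. Edges fall into three zone categories — IR (SOZ↔in-resection),
   OR (SOZ↔outside), IO (resection↔outside) — each split into OUT/IN by
   stimulation side; features are the per-category mean z.
2. **Group statistics**: Shapiro–Wilk-gated t / Mann–Whitney tests,
   Yates-corrected chi-square for 2×2 clinical tables, Benjamini–Hochberg
   FDR.
3. **An interpretable outcome model**: 21 predictors (12 CCEP + 9 clinical),
   z-scored, stratified 3:1 split, linear SVM with C selected by 5-fold CV
   in the training set, CV-mean metrics plus held-out-test ROC/AUC.
4. **Shapley attribution** of the linear decision score (exact closed form
   φᵢ = wᵢ(xᵢ − E[background xᵢ]), plus a seeded Monte-Carlo permutation
   estimator validated against it).

Because the study's patient data are private, a first-class synthetic-data
module generates cohorts at two fidelity levels — raw evoked epochs with
geometry and masks, or feature vectors directly — whose pipeline outputs are
*calibrated* to reproduce the published cohort-level group profiles
(e.g. SF vs nSF OR-N1-OUT 0.72±0.30 vs 0.95±0.29). See `docs/methods.md`
for the model, the calibration algorithm, and what a green test does and
does not establish.

## Worked example

```python
from ccepflow.cohort import generate_feature_cohort
from ccepflow.config import CohortConfig, ModelConfig
from ccepflow.model import cross_validate_final
from ccepflow.targets import ClinicalParams, FeatureTargets

table = generate_feature_cohort(
    CohortConfig(), FeatureTargets.default(), ClinicalParams.default(), seed=0
)
report = cross_validate_final(table, ModelConfig(leakage_mode="study-literal"), seed=0)
print(f"cohort: {len(table)} patients, best C = {report.best_c}")
print(f"CV means: accuracy {report.cv_metrics['accuracy']:.3f}, "
      f"sensitivity {report.cv_metrics['sensitivity']:.3f}, "
      f"specificity {report.cv_metrics['specificity']:.3f}")
print(f"test set: AUC {report.auc:.3f}, confusion {report.test_metrics['confusion']}")
```

prints

```
cohort: 56 patients, best C = 1.0
CV means: accuracy 0.775, sensitivity 0.800, specificity 0.750
test set: AUC 0.918, confusion [[5, 2], [1, 6]]
```

i.e. one 56-patient replicate (30 seizure-free / 26 not) of the full
procedure: features drawn from the published group profiles, z-scored in the
study's order, split 42:14 stratified, C tuned by 5-fold CV in the training
set. Single replicates fluctuate (the CV accuracy here is 0.775; the
replicate mean over 50 seeds is ~0.78 with SD ~0.08); `analysis/03` averages
50 of them next to the published values.

## Repository layout

- `src/ccepflow/` — the library: `geometry`/`signal_sim`/`cohort`/`calibrate`
  (synthetic cohorts), `localization`, `preprocess`, `features`, `stats`,
  `model`, `interpret`, `pipeline`/`interface`/`cli` (orchestration).
- `analysis/01…04_*.py` — narrative drivers: simulate the cohort, group
  statistics, outcome model over 50 replicates, SHAP attribution; each
  writes tables under `results/`.
- `ccepflow` CLI — `simulate`, `localize`, `preprocess`, `stats`, `fit`,
  `explain`, `run-all`, `write-config`; thin wrappers over the library for
  file-based runs (YAML config, TSV/NIfTI/HDF5/CSV artifacts).
- `tests/` — unit and property suites per module plus
  `tests/test_acceptance.py`, the cohort-level reproduction checks.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch (~15 min on one CPU):

- **t3–t5** — three group means of the z-scored connectivity features
  (SF OR-N1-OUT, nSF OR-N2-OUT, nSF IO-N1-OUT) from a *signal-level* run:
  reduced geometry, amplitudes set by the calibration routine targeting the
  published profile, 30+26 patients × 20 seeds through the entire
  preprocessing → RMS → z-score → aggregation chain.
- **t6–t9** — CV-mean accuracy/sensitivity/specificity and held-out-test AUC
  of the linear SVM, averaged over 200 feature-level replicates of the
  published cohort design.

and writes one `{"value": …, "n": …}` entry per target.
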