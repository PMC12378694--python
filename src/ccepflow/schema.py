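"""Fixed column schema of the patient feature table.

The predictor set is 21 columns: 12 directional CCEP connectivity features
(three edge categories x two components x two directions) plus 9 clinical
covariates, binary ones encoded as single 0/1 columns.
"""

from __future__ import annotations

CATEGORIES = ("IR", "OR", "IO")
COMPONENTS = ("N1", "N2")
DIRECTIONS = ("out", "in")

#: 12 CCEP features, fixed order.
CCEP_FEATURES = tuple(
    f"{cat}_{comp}_{d}" for cat in CATEGORIES for comp in COMPONENTS for d in DIRECTIONS
)

#: numeric clinical covariates (years except asm_count).
CLINICAL_NUMERIC = ("age_onset", "age_surgery", "duration", "asm_count")

#: binary clinical covariates, single-column 0/1 coding (level coded as 1 noted).
CLINICAL_BINARY = ("lateral_left", "hs", "mri_positive", "gtcs", "memory_abnormal")

CLINICAL_FEATURES = CLINICAL_NUMERIC + CLINICAL_BINARY

#: the full 21-column predictor schema, fixed order.
PREDICTOR_COLUMNS = CCEP_FEATURES + CLINICAL_FEATURES

OUTCOME_COLUMN = "outcome"
GROUPS = ("SF", "nSF")  # Engel I vs Engel II-IV

#: directed edge classes by (stimulated zone, recorded zone); zones are
#: soz (seizure-onset channels), ir (in-resection non-SOZ), or (outside resection).
ZONES = ("soz", "ir", "or")
EDGE_CLASSES = tuple((s, r) for s in ZONES for r in ZONES)

#: mapping category/direction -> contributing directed edge classes.
#: OR edges (SOZ <-> outside) also belong to IO because the SOZ lies inside
#: the resection, so IO is a strict superset of OR.
CATEGORY_CLASSES = {
    ("IR", "out"): (("soz", "ir"),),
    ("IR", "in"): (("ir", "soz"),),
    ("OR", "out"): (("soz", "or"),),
    ("OR", "in"): (("or", "soz"),),
    ("IO", "out"): (("soz", "or"), ("ir", "or")),
    ("IO", "in"): (("or", "soz"), ("or", "ir")),
}

N1_WINDOW_MS = (10.0, 50.0)
N2_WINDOW_MS = (80.0, 250.0)
COMPONENT_WINDOWS_MS = {"N1": N1_WINDOW_MS, "N2": N2_WINDOW_MS}
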