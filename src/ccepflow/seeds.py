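"""Deterministic per-stage random substreams.

Every source of randomness in a run is derived from a single global seed via
``stage_seed(global_seed, stage, index)``.  Stage names are hashed through
``numpy.random.SeedSequence`` spawn keys, so adding a stage never perturbs the
streams of existing stages, and reruns with the same (seed, stage, index) are
bit-identical.
"""

from __future__ import annotations

import numpy as np

_STAGE_IDS = {
    "geometry": 1,
    "signal": 2,
    "calibrate": 3,
    "feature_cohort": 4,
    "clinical": 5,
    "split": 6,
    "cv": 7,
    "shap": 8,
    "misc": 9,
}


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """A 31-bit integer seed for one (stage, index) substream."""
    sid = _STAGE_IDS.get(stage)
    if sid is None:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(_STAGE_IDS)}")
    ss = np.random.SeedSequence([int(global_seed), sid, int(index)])
    return int(ss.generate_state(1)[0] >> 1)


def stage_rng(global_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage, index))
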