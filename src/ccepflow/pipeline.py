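"""End-to-end signal-level pipeline: geometry -> signals -> features.

``run_signal_patient`` executes the full per-patient chain (simulate every
stimulation session, preprocess, exclude, average, window RMS, within-patient
z-score, category aggregation); ``run_signal_cohort`` maps it over a cohort
and assembles the 21-column patient table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features as feat
from .cohort import generate_clinical, patient_ids
from .config import CohortConfig, EvokedModel, StimulationConfig
from .features import assemble_feature_table
from .geometry import Geometry, generate_geometry
from .localization import soz_distance_profile
from .preprocess import (
    BASELINE_MS,
    EpochSet,
    TARGET_FS,
    apply_exclusions,
    average_trials,
    preprocess_signals,
)
from .schema import COMPONENT_WINDOWS_MS
from .seeds import stage_rng, stage_seed
from .signal_sim import (
    SessionContext,
    attach_acquisition_meta,
    bipolar_contact_pairs,
    channel_zones,
    patient_class_multipliers,
    simulate_ccep_session,
)
from .targets import ClinicalParams


def _baseline_correct(w: np.ndarray, fs: float, t0_ms: float) -> np.ndarray:
    t_ms = t0_ms + np.arange(w.shape[-1]) / fs * 1000.0
    sel = (t_ms >= BASELINE_MS[0]) & (t_ms < BASELINE_MS[1])
    return w - w[..., sel].mean(axis=-1, keepdims=True)


def run_signal_patient(
    geometry: Geometry,
    stim_cfg: StimulationConfig,
    evoked: EvokedModel,
    group: str,
    seed: int,
    collapse_trials: bool = True,
    filter_method: str = "fft",
) -> tuple[dict, pd.DataFrame]:
    """Simulate and analyze one patient; returns (12 features, edge table)."""
    labels = geometry.labels
    pairs = bipolar_contact_pairs(geometry)
    zones = channel_zones(geometry)
    n_ch = len(geometry.channels)
    fs_in = geometry.meta.get("raw_fs_hz", 2000.0)
    line = geometry.meta.get("line_freq_hz", 50.0)
    jitter = patient_class_multipliers(
        evoked, np.random.default_rng(np.random.SeedSequence([int(seed), 7000]))
    )

    ctx = SessionContext(geometry, stim_cfg, evoked)
    if collapse_trials:
        # batch all sessions: one pseudo-trial each, filter in one pass
        raw = np.empty((n_ch, ctx.n_contacts, ctx.n_samples), dtype=np.float32)
        for s in range(n_ch):
            raw[s] = simulate_ccep_session(
                geometry, stim_cfg, evoked, group, seed, s,
                collapse_trials=True, jitter=jitter, context=ctx,
            ).data[0]
        cleaned = preprocess_signals(raw, fs_in, line, pairs, method=filter_method)
        waveforms = _baseline_correct(cleaned, TARGET_FS, -500.0)  # (S, n_ch, 1500)
    else:
        per_session = []
        for s in range(n_ch):
            ep = simulate_ccep_session(
                geometry, stim_cfg, evoked, group, seed, s, jitter=jitter, context=ctx
            )
            cleaned = preprocess_signals(ep.data, fs_in, line, pairs, method=filter_method)
            avg = average_trials(
                EpochSet(cleaned, TARGET_FS, -500.0, s, [c.channel_id for c in geometry.channels])
            )
            per_session.append(avg)
        waveforms = np.stack(per_session)

    # window RMS for every (stim, record) pair at once; pulse at sample 500
    rms_by_comp = {}
    for comp, (lo_ms, hi_ms) in COMPONENT_WINDOWS_MS.items():
        lo = 500 + int(round(lo_ms))
        hi = 500 + int(round(hi_ms))
        rms_by_comp[comp] = np.sqrt(np.mean(waveforms[..., lo:hi] ** 2, axis=-1))

    records = []
    for s in range(n_ch):
        retained, _counts = apply_exclusions(s, labels)
        for r in retained:
            records.append(
                dict(
                    stim_channel=s,
                    record_channel=int(r),
                    stim_zone=zones[s],
                    rec_zone=zones[int(r)],
                    rms_N1=float(rms_by_comp["N1"][s, r]),
                    rms_N2=float(rms_by_comp["N2"][s, r]),
                )
            )
    edges = feat.edge_table(records)
    return feat.aggregate_patient(edges), edges


def exclusion_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulation-pair exclusion counts (stim_pair, rule, n_excluded)."""
    rows = []
    for s in range(len(labels)):
        _, counts = apply_exclusions(s, labels)
        for rule, n in counts.items():
            rows.append(dict(stim_pair=s, rule=rule, n_excluded=n))
    return pd.DataFrame(rows)


def run_signal_cohort(
    cohort_cfg: CohortConfig,
    stim_cfg: StimulationConfig,
    evoked: EvokedModel,
    seed: int,
    clinical_params: ClinicalParams | None = None,
    collapse_trials: bool = True,
    filter_method: str = "fft",
    keep_geometry: bool = False,
    keep_edges: bool = False,
):
    """Run the full signal-level pipeline over a cohort.

    Returns (patient feature table, SOZ distance profiles, per-patient info).
    With ``keep_edges`` each info entry carries the patient's edge-level audit
    table and per-stimulation-pair exclusion counts.
    """
    cohort_cfg.validate()
    groups = patient_ids(cohort_cfg)
    clinical_params = clinical_params or ClinicalParams.default()
    feat_rows = {}
    distance_frames = []
    info = []
    for i, (pid, group) in enumerate(groups.items()):
        geom = generate_geometry(cohort_cfg, stage_seed(seed, "geometry", i), group)
        geom.patient_id = pid
        attach_acquisition_meta(geom, cohort_cfg)
        features, edges = run_signal_patient(
            geom, stim_cfg, evoked, group, stage_seed(seed, "signal", i),
            collapse_trials=collapse_trials, filter_method=filter_method,
        )
        feat_rows[pid] = features
        prof = soz_distance_profile(geom.labels)
        prof.insert(0, "patient_id", pid)
        prof.insert(1, "group", group)
        distance_frames.append(prof)
        entry = dict(patient_id=pid, **geom.meta)
        if keep_geometry:
            entry["geometry"] = geom
        if keep_edges:
            entry["edges"] = edges.assign(patient_id=pid)
            entry["exclusions"] = exclusion_table(geom.labels).assign(patient_id=pid)
        info.append(entry)
    feats = pd.DataFrame.from_dict(feat_rows, orient="index")
    clinical = generate_clinical(groups, clinical_params, stage_rng(seed, "clinical"))
    table = assemble_feature_table(feats, clinical, groups)
    distances = pd.concat(distance_frames, ignore_index=True)
    return table, distances, info
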