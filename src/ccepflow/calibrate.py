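"""Amplitude calibration: invert feature targets to evoked amplitudes.

The final features are within-patient z-scores of window RMS values, so the
map from per-class evoked amplitudes to group feature means is nonlinear and
coupled through the pooled mean/SD of each patient's edges.  Calibration runs
a damped fixed-point iteration on the six feature-relevant directed-class
amplitudes (per component and outcome group), using a fast surrogate of the
pipeline that is exact up to Monte-Carlo error: the preprocessed unit
templates are pushed through the real filter chain once, giving the window
Gram matrices, and the noise floor is measured from a zero-amplitude run of
the real pipeline; per-edge and per-patient lognormal spreads are drawn just
as the simulator draws them.  Background classes (SOZ->SOZ, within-resection,
outside-outside) keep their configured amplitudes and anchor the z reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import CohortConfig, EvokedModel, StimulationConfig, default_amp_by_class
from .errors import CalibrationError
from .geometry import generate_geometry
from .pipeline import run_signal_patient
from .preprocess import (
    EPOCH_POST_S,
    EPOCH_PRE_S,
    TARGET_FS,
    apply_exclusions,
    filter_cascade,
    zero_phase_filter,
)
from .schema import CATEGORY_CLASSES, CCEP_FEATURES, COMPONENT_WINDOWS_MS, GROUPS
from .seeds import stage_seed
from .signal_sim import attach_acquisition_meta, channel_zones, evoked_templates

#: directed classes whose amplitudes calibration adjusts, and the feature
#: (category, direction) each is primarily pinned by.
FEATURE_CLASSES = (
    ("soz", "ir"),
    ("ir", "soz"),
    ("soz", "or"),
    ("or", "soz"),
    ("ir", "or"),
    ("or", "ir"),
)


@dataclass
class GeometryStats:
    """Expected edge-class composition plus measured chain constants."""

    class_counts: list  # one dict {(stim_zone, rec_zone): n} per sample patient
    gram: dict  # {comp: 2x2 window Gram matrix of the unit N1/N2 templates}
    noise_floor: dict  # {comp: E[rms^2] of the averaged noise in the window}
    meta: dict = field(default_factory=dict)

    def mean_counts(self) -> dict:
        keys = set().union(*self.class_counts)
        return {k: float(np.mean([c.get(k, 0) for c in self.class_counts])) for k in keys}


def template_gram(cohort_cfg: CohortConfig, evoked: EvokedModel) -> dict:
    """Window Gram matrices of the unit-amplitude templates after the chain."""
    fs = cohort_cfg.raw_fs_hz
    n = int(round((EPOCH_PRE_S + EPOCH_POST_S) * fs))
    t0 = -EPOCH_PRE_S * 1000.0
    _, u1, u2, _ = evoked_templates(evoked, fs, n, t0)
    sos = filter_cascade(float(fs), float(cohort_cfg.line_freq_hz))
    u = zero_phase_filter(np.stack([u1, u2]), sos, fs)[:, :: int(fs // TARGET_FS)]
    t_ms = t0 + np.arange(u.shape[-1]) / TARGET_FS * 1000.0
    base = (t_ms >= -500.0) & (t_ms < -10.0)
    u = u - u[:, base].mean(axis=1, keepdims=True)
    gram = {}
    for comp, (lo, hi) in COMPONENT_WINDOWS_MS.items():
        sel = (t_ms >= lo) & (t_ms < hi)
        w = u[:, sel]
        gram[comp] = w @ w.T / sel.sum()
    return gram


def collect_geometry_stats(
    cohort_cfg: CohortConfig,
    stim_cfg: StimulationConfig,
    evoked: EvokedModel,
    seed: int = 0,
    n_patients: int = 24,
) -> GeometryStats:
    """Sample geometries for class composition; measure the noise floor from a
    zero-amplitude run of the actual pipeline (keeps artifact residuals)."""
    counts_list = []
    silent = replace(evoked, amp_by_class=default_amp_by_class(0.0, 0.0))
    noise_sq = {comp: [] for comp in COMPONENT_WINDOWS_MS}
    for i in range(n_patients):
        geom = generate_geometry(cohort_cfg, stage_seed(seed, "calibrate", i), "SF")
        attach_acquisition_meta(geom, cohort_cfg)
        zones = channel_zones(geom)
        counts: dict = {}
        for s in range(len(geom.channels)):
            retained, _ = apply_exclusions(s, geom.labels)
            for r in retained:
                key = (zones[s], zones[int(r)])
                counts[key] = counts.get(key, 0) + 1
        counts_list.append(counts)
        if i < 3:  # noise floor: a few patients give thousands of edges
            _, edges = _edges_for(geom, stim_cfg, silent, seed=stage_seed(seed, "calibrate", 100 + i))
            for comp in noise_sq:
                noise_sq[comp].append(np.mean(edges[f"rms_{comp}"].to_numpy() ** 2))
    floor = {comp: float(np.mean(v)) for comp, v in noise_sq.items()}
    return GeometryStats(
        class_counts=counts_list,
        gram=template_gram(cohort_cfg, evoked),
        noise_floor=floor,
        meta=dict(cohort=cohort_cfg, stim=stim_cfg, seed=seed),
    )


def _edges_for(geom, stim_cfg, evoked, seed):
    try:
        return run_signal_patient(geom, stim_cfg, evoked, "SF", seed)
    except Exception:
        # zero-amplitude runs can degenerate only if noise is off too
        raise


def _surrogate_group(amp: dict, stats: GeometryStats, evoked: EvokedModel,
                     rng: np.random.Generator, n_virtual: int = 480):
    """Expected feature means for one group's amplitude table.

    Returns (feature means dict, per-class mean r dict, pooled (mu, sd) per comp).
    """
    sig_m = np.sqrt(np.log1p(evoked.amp_cv**2)) if evoked.amp_cv > 0 else 0.0
    sig_j = (
        np.sqrt(np.log1p(evoked.patient_class_jitter**2))
        if evoked.patient_class_jitter > 0
        else 0.0
    )
    comps = list(COMPONENT_WINDOWS_MS)
    n_dicts = len(stats.class_counts)
    per_patient_feats = []
    class_r = {comp: {} for comp in comps}
    pooled_stats = {comp: [] for comp in comps}
    nv_each = max(n_virtual // n_dicts, 40)
    for counts in stats.class_counts:
        classes = [c for c, n in counts.items() if n > 0]
        ns = [counts[c] for c in classes]
        total = sum(ns)
        r_all = {comp: np.empty((nv_each, total)) for comp in comps}
        col = 0
        for c, n_c in zip(classes, ns):
            a1, a2 = amp[c]
            j = np.exp(sig_j * rng.standard_normal((nv_each, 1, 2)) - sig_j**2 / 2)
            m = np.exp(sig_m * rng.standard_normal((nv_each, n_c, 2)) - sig_m**2 / 2)
            eff = m * j  # (nv, n_c, 2) effective per-component multipliers
            a = np.stack([a1 * eff[..., 0], a2 * eff[..., 1]], axis=-1)
            for comp in comps:
                G = stats.gram[comp]
                r2 = (
                    a[..., 0] ** 2 * G[0, 0]
                    + 2 * a[..., 0] * a[..., 1] * G[0, 1]
                    + a[..., 1] ** 2 * G[1, 1]
                    + stats.noise_floor[comp]
                )
                r_all[comp][:, col : col + n_c] = np.sqrt(r2)
                class_r[comp].setdefault(c, []).append(np.sqrt(r2).mean())
            col += n_c
        feats = {}
        z = {}
        for comp in comps:
            mu = r_all[comp].mean(axis=1, keepdims=True)
            sd = r_all[comp].std(axis=1, ddof=1, keepdims=True)
            z[comp] = (r_all[comp] - mu) / sd
            pooled_stats[comp].append((mu.mean(), sd.mean()))
        # category means per virtual patient
        starts = np.cumsum([0] + ns)
        for feature in CCEP_FEATURES:
            cat, comp, direction = feature.split("_")
            want = set(CATEGORY_CLASSES[(cat, direction)])
            cols = [
                np.arange(starts[k], starts[k + 1])
                for k, c in enumerate(classes)
                if c in want
            ]
            if not cols:
                continue
            sel = np.concatenate(cols)
            feats.setdefault(feature, []).append(z[comp][:, sel].mean(axis=1).mean())
        per_patient_feats.append(feats)
    means = {}
    for feature in CCEP_FEATURES:
        vals = [f[feature][0] for f in per_patient_feats if feature in f]
        means[feature] = float(np.mean(vals)) if vals else np.nan
    mean_class_r = {
        comp: {c: float(np.mean(v)) for c, v in class_r[comp].items()} for comp in comps
    }
    pooled = {comp: tuple(np.mean(pooled_stats[comp], axis=0)) for comp in comps}
    return means, mean_class_r, pooled


def _class_z_targets(mean_of, stats: GeometryStats) -> dict:
    """Required per-class z for each component, from category mean targets.

    ``mean_of`` maps a feature name to its target mean for one group.
    """
    mc = stats.mean_counts()
    out = {}
    for comp in COMPONENT_WINDOWS_MS:
        z = {
            ("soz", "ir"): mean_of[f"IR_{comp}_out"],
            ("ir", "soz"): mean_of[f"IR_{comp}_in"],
            ("soz", "or"): mean_of[f"OR_{comp}_out"],
            ("or", "soz"): mean_of[f"OR_{comp}_in"],
        }
        for direction, soz_cls, mix_cls in (
            ("out", ("soz", "or"), ("ir", "or")),
            ("in", ("or", "soz"), ("or", "ir")),
        ):
            n_s = mc.get(soz_cls, 0.0)
            n_m = mc.get(mix_cls, 0.0)
            io = mean_of[f"IO_{comp}_{direction}"]
            if n_m > 0:
                z[mix_cls] = ((n_s + n_m) * io - n_s * z[soz_cls]) / n_m
            else:
                z[mix_cls] = io
        out[comp] = z
    return out


def _solve_surrogate(
    amp: dict,
    mean_targets: dict,
    geometry_stats: GeometryStats,
    evoked: EvokedModel,
    crn_seed: int,
    tol: float,
    max_iter: int,
    damping: float,
):
    """Inner fixed point: drive the surrogate's feature means to the targets.

    ``amp`` is mutated in place; returns (iterations used, residuals).
    Common random numbers: the same ``crn_seed`` is used for every iteration
    (and every solve within one calibration), making the inner map
    deterministic so it converges below the Monte-Carlo noise level, and
    keeping the surrogate's frozen sampling error constant so the outer
    pipeline-refinement rounds can correct it.
    """
    comps = list(COMPONENT_WINDOWS_MS)
    residuals: dict = {}
    # sign-adaptive per-class step sizes (Rprop-style): accelerate while the
    # update direction persists, back off when it flips
    gain = {(g, c, k): damping for g in GROUPS for c in FEATURE_CLASSES for k in (0, 1)}
    last_sign = {k: 0.0 for k in gain}
    for it in range(1, max_iter + 1):
        worst = 0.0
        state = {}
        for g in GROUPS:
            amp_g = {c: tuple(v) for c, v in amp[g].items()}
            means, class_r, pooled = _surrogate_group(
                amp_g, geometry_stats, evoked, np.random.default_rng(crn_seed)
            )
            state[g] = (class_r, pooled, _class_z_targets(mean_targets[g], geometry_stats))
            for feature in CCEP_FEATURES:
                resid = means[feature] - mean_targets[g][feature]
                residuals[(feature, g)] = resid
                worst = max(worst, abs(resid))
        if worst <= tol:
            return it, residuals
        for g in GROUPS:
            class_r, pooled, z_need = state[g]
            for comp_i, comp in enumerate(comps):
                mu, sd = pooled[comp]
                floor = geometry_stats.noise_floor[comp]
                G = geometry_stats.gram[comp]
                for c in FEATURE_CLASSES:
                    if c not in class_r[comp]:
                        continue
                    r_target = mu + z_need[comp][c] * sd
                    r_now = class_r[comp][c]
                    # subtract the other component's leak into this window
                    # (zero-phase filter ringing smears N2 into the N1 window),
                    # so the ratio acts on this component's own signal energy
                    a_self = amp[g][c][comp_i]
                    a_other = amp[g][c][1 - comp_i]
                    i, o = comp_i, 1 - comp_i
                    leak = a_other**2 * G[o, o] + 2.0 * a_self * a_other * G[i, o]
                    s_target = np.sqrt(max(r_target**2 - floor - leak, 1e-6))
                    s_now = np.sqrt(max(r_now**2 - floor - leak, 1e-6))
                    ratio = np.clip(s_target / s_now, 0.2, 5.0)
                    step = np.log(ratio)
                    key = (g, c, comp_i)
                    if step * last_sign[key] > 0:
                        gain[key] = min(gain[key] * 1.2, 2.5)
                    elif step * last_sign[key] < 0:
                        gain[key] = max(gain[key] * 0.5, 0.2)
                    last_sign[key] = np.sign(step)
                    amp[g][c][comp_i] = max(
                        amp[g][c][comp_i] * float(np.exp(gain[key] * step)), 0.5
                    )
    raise CalibrationError(
        f"surrogate fixed point did not converge in {max_iter} iterations "
        f"(worst residual {max(abs(v) for v in residuals.values()):.3f})",
        residuals=residuals,
    )


def measure_pipeline_means(
    amp_by_class: dict,
    geometry_stats: GeometryStats,
    evoked: EvokedModel,
    seed: int,
    n_per_group: int = 64,
):
    """Full-pipeline group feature means (and their SEs) at given amplitudes."""
    cohort_cfg: CohortConfig = geometry_stats.meta["cohort"]
    stim_cfg: StimulationConfig = geometry_stats.meta["stim"]
    ev = replace(evoked, amp_by_class=amp_by_class)
    means: dict = {}
    ses: dict = {}
    for gi, g in enumerate(GROUPS):
        rows = []
        for i in range(n_per_group):
            ss = np.random.SeedSequence([int(seed), 808, gi, i])
            gseed, sseed = (int(x >> 1) for x in ss.generate_state(2))
            geom = generate_geometry(cohort_cfg, gseed, g)
            attach_acquisition_meta(geom, cohort_cfg)
            feats, _ = run_signal_patient(geom, stim_cfg, ev, g, sseed)
            rows.append(feats)
        arr = {f: np.array([r[f] for r in rows]) for f in CCEP_FEATURES}
        means[g] = {f: float(v.mean()) for f, v in arr.items()}
        ses[g] = {f: float(v.std(ddof=1) / np.sqrt(n_per_group)) for f, v in arr.items()}
    return means, ses


def calibrate_amplitudes(
    targets,
    geometry_stats: GeometryStats,
    tol: float = 0.05,
    evoked: EvokedModel | None = None,
    max_iter: int = 100,
    seed: int = 0,
    damping: float = 0.8,
    refine_rounds: int = 3,
    refine_patients: int = 96,
    bias_scale: float = 0.08,
    outer_damping: float = 0.5,
):
    """Fixed-point calibration of ``amp_by_class`` against the feature targets.

    Two nested loops: an inner fixed point on the fast surrogate, and
    ``refine_rounds`` outer rounds that measure the group means with the real
    signal pipeline and shift the surrogate's targets by the observed bias
    (shrunk toward zero in proportion to the measurement's standard error, so
    noisy estimates - e.g. the one-edge IR categories - do not inject noise).
    Returns (amp_by_class, info); info carries convergence status, iteration
    count, surrogate residuals, and the last full-pipeline residuals with
    their Monte-Carlo SEs.  Raises ``CalibrationError`` if the iteration
    budget is exhausted.
    """
    targets.validate()
    evoked = evoked or EvokedModel()
    amp = {g: {c: list(v) for c, v in evoked.amp_by_class[g].items()} for g in GROUPS}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4242]))
    crn_seed = int(rng.integers(2**31))
    wanted = {
        g: {f: targets.feature_mean(f, g) for f in CCEP_FEATURES} for g in GROUPS
    }
    adjusted = {g: dict(wanted[g]) for g in GROUPS}
    budget = max_iter
    total_iters = 0
    it, surr_res = _solve_surrogate(
        amp, adjusted, geometry_stats, evoked, crn_seed, 0.6 * tol, budget, damping
    )
    total_iters += it
    pipe_res: dict = {}
    pipe_se: dict = {}
    for round_i in range(refine_rounds):
        means, ses = measure_pipeline_means(
            {g: {c: tuple(v) for c, v in amp[g].items()} for g in GROUPS},
            geometry_stats,
            evoked,
            seed=seed + 31 * round_i,
            n_per_group=refine_patients,
        )
        pipe_res = {
            (f, g): means[g][f] - wanted[g][f] for g in GROUPS for f in CCEP_FEATURES
        }
        pipe_se = {(f, g): ses[g][f] for g in GROUPS for f in CCEP_FEATURES}
        for g in GROUPS:
            for f in CCEP_FEATURES:
                se = ses[g][f]
                shrink = outer_damping * bias_scale**2 / (bias_scale**2 + se**2)
                adjusted[g][f] -= shrink * (means[g][f] - wanted[g][f])
        it, surr_res = _solve_surrogate(
            amp, adjusted, geometry_stats, evoked, crn_seed, 0.6 * tol, budget, damping
        )
        total_iters += it
    amp_final = {
        g: {c: (float(v[0]), float(v[1])) for c, v in amp[g].items()} for g in GROUPS
    }
    info = dict(
        converged=True,
        n_iter=total_iters,
        residuals=surr_res,
        pipeline_residuals=pipe_res,
        pipeline_se=pipe_se,
        adjusted_targets=adjusted,
    )
    return amp_final, info
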