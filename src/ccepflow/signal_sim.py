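"""Stimulation-evoked signal simulator at the contact level.

Each adjacent contact pair is stimulated in turn; every bipolar channel of the
montage receives an evoked response whose N1/N2 amplitudes are drawn from the
per-edge-class table (optionally calibrated), scaled by a per-patient class
jitter and a per-edge lognormal spread.  Contact traces are constructed as
cumulative sums of the bipolar evoked responses along each shaft, so that the
bipolar montage recovers the intended edge waveforms exactly, plus independent
pink noise per contact, line-frequency sinusoids with random phase, and a
brief decaying stimulus artifact.

``collapse_trials=True`` emits the trial average directly (one pseudo-trial
with noise scaled by 1/sqrt(n_trials)).  Because the preprocessing chain is
linear and RMS is computed on the trial average, this is statistically
identical to simulating and averaging the full trial count, at a fraction of
the cost.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .config import CohortConfig, EvokedModel, StimulationConfig
from .errors import InvalidConfigError
from .geometry import Geometry
from .preprocess import EPOCH_POST_S, EPOCH_PRE_S, EpochSet
from .schema import EDGE_CLASSES

LINE_HARMONICS = (1, 2, 3)


def bipolar_contact_pairs(geometry: Geometry) -> list[tuple[int, int]]:
    """(lo, hi) contact indices for each bipolar channel, in channel order."""
    index = {c: i for i, c in enumerate(geometry.contacts)}
    return [(index[ch.contact_lo], index[ch.contact_hi]) for ch in geometry.channels]


def channel_zones(geometry: Geometry) -> list[str]:
    lab = geometry.labels
    soz = lab["is_soz"].to_numpy()
    inr = lab["in_resection"].to_numpy()
    return ["soz" if s else ("ir" if r else "or") for s, r in zip(soz, inr)]


def evoked_templates(evoked: EvokedModel, fs: float, n_samples: int, t0_ms: float):
    """Unit-amplitude N1/N2 templates and the stimulus-artifact kernel.

    N1 is a negative Gaussian bump (peak 25 ms, sigma 8 ms).  N2 is a broader
    Gaussian (centre 160 ms, sigma 45 ms) whose onset is tapered to zero with
    a raised cosine over 60-80 ms: the late component's energy must stay
    inside its 80-250 ms analysis window, otherwise its (much larger)
    calibrated amplitude floods the early window and the two components
    cannot be calibrated independently.
    """
    t_ms = t0_ms + np.arange(n_samples) / fs * 1000.0
    n1 = -np.exp(-0.5 * ((t_ms - evoked.n1_peak_ms) / evoked.n1_width_ms) ** 2)
    n2 = np.exp(-0.5 * ((t_ms - evoked.n2_center_ms) / evoked.n2_width_ms) ** 2)
    onset = np.clip((t_ms - 60.0) / 20.0, 0.0, 1.0)
    n2 = n2 * 0.5 * (1.0 - np.cos(np.pi * onset))
    art = np.where(
        (t_ms >= 0) & (t_ms <= evoked.artifact_ms), np.exp(-np.maximum(t_ms, 0) / 2.0), 0.0
    )
    return t_ms, n1, n2, art


def pink_noise(rng: np.random.Generator, shape: tuple, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape, dtype=np.float32)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale /= np.sqrt(np.mean(scale[1:] ** 2))
    return np.fft.irfft(spec * scale.astype(np.float32), n=n, axis=-1)


def patient_class_multipliers(
    evoked: EvokedModel, rng: np.random.Generator
) -> dict[tuple, tuple[float, float]]:
    """Per-patient mean-1 lognormal jitter for each directed class/component."""
    s = evoked.patient_class_jitter
    if s <= 0:
        return {c: (1.0, 1.0) for c in EDGE_CLASSES}
    sig = np.sqrt(np.log1p(s**2))
    draws = rng.standard_normal((len(EDGE_CLASSES), 2))
    return {
        c: tuple(np.exp(sig * draws[i] - sig**2 / 2.0)) for i, c in enumerate(EDGE_CLASSES)
    }


def _edge_amplitudes(
    geometry: Geometry,
    evoked: EvokedModel,
    group: str,
    stim_index: int,
    zones: list[str],
    jitter: dict,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (a1, a2) amplitudes for one stimulated pair."""
    n_ch = len(zones)
    a1 = np.zeros(n_ch)
    a2 = np.zeros(n_ch)
    sig = np.sqrt(np.log1p(evoked.amp_cv**2)) if evoked.amp_cv > 0 else 0.0
    table = evoked.amp_by_class[group]
    z = rng.standard_normal((n_ch, 2))
    for j in range(n_ch):
        if j == stim_index:
            continue
        cls = (zones[stim_index], zones[j])
        base1, base2 = table[cls]
        j1, j2 = jitter[cls]
        m1 = np.exp(sig * z[j, 0] - sig**2 / 2.0) if sig > 0 else 1.0
        m2 = np.exp(sig * z[j, 1] - sig**2 / 2.0) if sig > 0 else 1.0
        a1[j] = base1 * j1 * m1
        a2[j] = base2 * j2 * m2
    return a1, a2


class SessionContext:
    """Per-patient constants shared by all stimulation sessions."""

    def __init__(self, geometry: Geometry, stim_cfg: StimulationConfig, evoked: EvokedModel):
        stim_cfg.validate()
        evoked.validate()
        self.fs = geometry.meta.get("raw_fs_hz", 2000.0)
        self.line_freq = geometry.meta.get("line_freq_hz", 50.0)
        self.n_samples = int(round((EPOCH_PRE_S + EPOCH_POST_S) * self.fs))
        self.t0_ms = -EPOCH_PRE_S * 1000.0
        if (
            evoked.n2_center_ms + evoked.n2_width_ms > EPOCH_POST_S * 1000.0
            or evoked.n1_peak_ms < 0
        ):
            raise InvalidConfigError("evoked windows incompatible with epoch length")
        self.zones = channel_zones(geometry)
        self.pairs = bipolar_contact_pairs(geometry)
        self.n_contacts = len(geometry.contacts)
        _, self.t1, self.t2, art = evoked_templates(
            evoked, self.fs, self.n_samples, self.t0_ms
        )
        cpos = np.array([c.position for c in geometry.contacts])
        mids = np.array([ch.midpoint for ch in geometry.channels])
        self.contact_pos = cpos
        self.channel_mids = mids
        self.artifact = art
        # sin/cos bases for line noise: random phase realized as a random mix
        t_s = np.arange(self.n_samples) / self.fs
        rows = []
        for k in LINE_HARMONICS:
            w = 2 * np.pi * k * self.line_freq
            rows += [np.sin(w * t_s) / k, np.cos(w * t_s) / k]
        self.line_basis = np.asarray(rows, dtype=np.float32)
        # shaft bookkeeping for the cumulative-sum contact construction
        shaft_of = [ch.shaft_id for ch in geometry.channels]
        self.shaft_channel_idx = []
        for shaft in sorted(set(shaft_of)):
            ch_idx = [j for j, s in enumerate(shaft_of) if s == shaft]
            hi = [self.pairs[j][1] for j in ch_idx]
            self.shaft_channel_idx.append((np.asarray(ch_idx), np.asarray(hi)))


def simulate_ccep_session(
    geometry: Geometry,
    stim_cfg: StimulationConfig,
    evoked: EvokedModel,
    group: str,
    seed: int,
    stim_index: int,
    collapse_trials: bool = False,
    jitter: dict | None = None,
    context: SessionContext | None = None,
) -> EpochSet:
    """Raw contact-level epochs for one stimulated bipolar pair."""
    ctx = context or SessionContext(geometry, stim_cfg, evoked)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7001, int(stim_index)]))
    if jitter is None:
        jitter = patient_class_multipliers(
            evoked, np.random.default_rng(np.random.SeedSequence([int(seed), 7000]))
        )
    n_trials = 1 if collapse_trials else stim_cfg.n_trials
    noise_scale = 1.0 / np.sqrt(stim_cfg.n_trials) if collapse_trials else 1.0

    a1, a2 = _edge_amplitudes(geometry, evoked, group, stim_index, ctx.zones, jitter, rng)
    bip_evoked = a1[:, None] * ctx.t1[None, :] + a2[:, None] * ctx.t2[None, :]

    # contact potentials: cumulative sums of bipolar evoked along each shaft
    contact_evoked = np.zeros((ctx.n_contacts, ctx.n_samples), dtype=np.float32)
    for ch_idx, hi_contacts in ctx.shaft_channel_idx:
        contact_evoked[hi_contacts] += np.cumsum(bip_evoked[ch_idx], axis=0)

    # stimulus artifact, decaying with distance from the stimulation site
    dist = np.linalg.norm(ctx.contact_pos - ctx.channel_mids[stim_index], axis=1)
    contact_evoked += (
        (evoked.artifact_amp_uv / (1.0 + dist / 10.0))[:, None] * ctx.artifact[None, :]
    ).astype(np.float32)

    data = np.broadcast_to(contact_evoked, (n_trials, ctx.n_contacts, ctx.n_samples)).copy()
    if evoked.noise_sd_uv > 0:
        data += np.float32(evoked.noise_sd_uv * noise_scale) * pink_noise(
            rng, (n_trials, ctx.n_contacts, ctx.n_samples), evoked.pink_exponent
        )
    if evoked.line_amp_uv > 0:
        # random phase per trial/contact/harmonic: unit-norm (cos, sin) mix
        n_h = ctx.line_basis.shape[0] // 2
        mix = rng.standard_normal((n_trials, ctx.n_contacts, n_h, 2))
        mix /= np.linalg.norm(mix, axis=-1, keepdims=True)
        mix = mix.reshape(n_trials, ctx.n_contacts, 2 * n_h).astype(np.float32)
        data += np.float32(evoked.line_amp_uv * noise_scale) * (mix @ ctx.line_basis)
    return EpochSet(
        data=data,
        fs=ctx.fs,
        t0_ms=ctx.t0_ms,
        stim_channel=stim_index,
        channel_ids=[f"c{i}" for i in range(ctx.n_contacts)],
    )


def iter_sessions(
    geometry: Geometry,
    stim_cfg: StimulationConfig,
    evoked: EvokedModel,
    group: str,
    seed: int,
    collapse_trials: bool = False,
) -> Iterator[tuple[int, EpochSet]]:
    """One session per adjacent same-shaft contact pair (= bipolar channel)."""
    jitter = patient_class_multipliers(
        evoked, np.random.default_rng(np.random.SeedSequence([int(seed), 7000]))
    )
    ctx = SessionContext(geometry, stim_cfg, evoked)
    for stim_index in range(len(geometry.channels)):
        yield stim_index, simulate_ccep_session(
            geometry,
            stim_cfg,
            evoked,
            group,
            seed,
            stim_index,
            collapse_trials=collapse_trials,
            jitter=jitter,
            context=ctx,
        )


def attach_acquisition_meta(geometry: Geometry, config: CohortConfig) -> Geometry:
    geometry.meta["raw_fs_hz"] = config.raw_fs_hz
    geometry.meta["line_freq_hz"] = config.line_freq_hz
    return geometry
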