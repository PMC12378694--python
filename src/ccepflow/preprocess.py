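"""Signal conditioning for stimulation-evoked recordings.

The chain follows the acquisition protocol: notch filtering of the line
frequency and its harmonics (Q = 30, zero-phase), bipolar re-referencing of
adjacent contacts, zero-phase 4th-order Butterworth bandpass 1-300 Hz, and
integer-factor downsampling to 1000 Hz; epochs span -500..+1000 ms around each
pulse.  All filters are linear and time-invariant, so the notch and the
bipolar subtraction commute; the implementation re-references first and
applies a single combined cascade, which is mathematically identical and much
cheaper.  The default zero-phase application multiplies the squared magnitude
response in the frequency domain (the textbook meaning of forward-backward
filtering); ``method="sos"`` uses ``scipy.signal.sosfiltfilt`` with its edge
padding instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .errors import InvalidInputError

TARGET_FS = 1000.0
BANDPASS_HZ = (1.0, 300.0)
NOTCH_Q = 30.0
EPOCH_PRE_S = 0.5
EPOCH_POST_S = 1.0
BASELINE_MS = (-500.0, -10.0)
MIN_STIM_DISTANCE_MM = 10.0


@dataclass
class EpochSet:
    """Per-stimulation-pair trial data: trials x channels x samples."""

    data: np.ndarray
    fs: float
    t0_ms: float
    stim_channel: int  # index of the stimulated bipolar channel
    channel_ids: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def pulse_sample(self) -> int:
        return int(round(-self.t0_ms / 1000.0 * self.fs))


@dataclass
class EvokedResponse:
    """Trial-averaged, baseline-corrected waveform of one directed edge."""

    stim_channel: int
    record_channel: int
    waveform: np.ndarray
    fs: float
    t0_ms: float
    n_trials_used: int


@lru_cache(maxsize=8)
def filter_cascade(fs: float, line_freq: float) -> np.ndarray:
    """Stacked SOS: notches at the line frequency and harmonics (<= 300 Hz)
    plus the 1-300 Hz 4th-order Butterworth bandpass."""
    sections = []
    k = 1
    while k * line_freq <= BANDPASS_HZ[1] and k * line_freq < fs / 2:
        b, a = signal.iirnotch(k * line_freq, NOTCH_Q, fs=fs)
        sections.append(signal.tf2sos(b, a))
        k += 1
    sections.append(signal.butter(4, BANDPASS_HZ, btype="bandpass", fs=fs, output="sos"))
    return np.vstack(sections)


def zero_phase_filter(x: np.ndarray, sos: np.ndarray, fs: float, method: str = "fft") -> np.ndarray:
    """Apply the cascade with zero phase along the last axis."""
    if method == "sos":
        return signal.sosfiltfilt(sos, x, axis=-1)
    if method != "fft":
        raise InvalidInputError(f"unknown filter method {method!r}")
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
    gain = np.abs(h) ** 2  # forward-backward: squared magnitude, zero phase
    if x.dtype == np.float32:
        gain = gain.astype(np.float32)
    spec = np.fft.rfft(x, axis=-1)
    return np.fft.irfft(spec * gain, n=n, axis=-1)


def bipolar_reference(contact_data: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Adjacent-contact differences (hi - lo) along the channel axis."""
    lo = np.asarray([p[0] for p in pairs])
    hi = np.asarray([p[1] for p in pairs])
    return contact_data[..., hi, :] - contact_data[..., lo, :]


def preprocess_signals(
    raw: np.ndarray,
    fs_in: float,
    line_freq: float,
    bipolar_pairs: list[tuple[int, int]],
    method: str = "fft",
) -> np.ndarray:
    """Contact-level trials -> cleaned bipolar trials at 1000 Hz."""
    if fs_in < 2 * TARGET_FS:
        raise InvalidInputError("input sampling rate must be >= 2000 Hz")
    factor = fs_in / TARGET_FS
    if abs(factor - round(factor)) > 1e-9:
        raise InvalidInputError(
            f"fs_in={fs_in} is not an integer multiple of {TARGET_FS:.0f} Hz"
        )
    factor = int(round(factor))
    raw = np.asarray(raw)
    if raw.dtype not in (np.float32, np.float64):
        raw = raw.astype(np.float64)
    x = bipolar_reference(raw, bipolar_pairs)
    sos = filter_cascade(float(fs_in), float(line_freq))
    x = zero_phase_filter(x, sos, fs_in, method=method)
    return x[..., ::factor]


def epoch(
    continuous: np.ndarray,
    fs: float,
    stim_times_s: np.ndarray,
    t_pre_s: float = EPOCH_PRE_S,
    t_post_s: float = EPOCH_POST_S,
    stim_channel: int = -1,
    channel_ids: list | None = None,
) -> EpochSet:
    """Segment continuous channels x samples into pulse-locked epochs."""
    n_pre = int(round(t_pre_s * fs))
    n_post = int(round(t_post_s * fs))
    n_samples = continuous.shape[-1]
    trials = []
    for t in np.atleast_1d(stim_times_s):
        i = int(round(t * fs))
        if i - n_pre < 0 or i + n_post > n_samples:
            warnings.warn(f"epoch at t={t:.3f}s exceeds record bounds, dropped", stacklevel=2)
            continue
        trials.append(continuous[..., i - n_pre : i + n_post])
    if not trials:
        raise InvalidInputError("no epochs fit inside the recording")
    return EpochSet(
        data=np.stack(trials, axis=0),
        fs=fs,
        t0_ms=-t_pre_s * 1000.0,
        stim_channel=stim_channel,
        channel_ids=channel_ids or [],
    )


def apply_exclusions(stim_index: int, labels) -> tuple[np.ndarray, dict]:
    """Retained recording channels for one stimulated pair.

    Removes (a) every channel on the stimulated shaft, (b) non-gray channels,
    (c) channels strictly closer than 10 mm (Euclidean) to the stimulated
    pair's midpoint.  Order-independent set intersection; returns retained
    channel indices plus per-rule exclusion counts.
    """
    stim = labels.iloc[stim_index]
    xyz = labels[["x_mm", "y_mm", "z_mm"]].to_numpy()
    d = np.linalg.norm(xyz - xyz[stim_index], axis=1)
    same_shaft = (labels["shaft_id"] == stim["shaft_id"]).to_numpy()
    non_gray = ~labels["is_gray"].to_numpy()
    too_close = d < MIN_STIM_DISTANCE_MM
    keep = ~(same_shaft | non_gray | too_close)
    keep[stim_index] = False
    counts = dict(
        same_shaft=int(same_shaft.sum()),
        non_gray=int(non_gray.sum()),
        within_10mm=int(too_close.sum()),
    )
    retained = np.flatnonzero(keep)
    if len(retained) == 0:
        warnings.warn(f"no channels retained for stim pair {stim_index}", stacklevel=2)
    return retained, counts


def average_trials(epochs: EpochSet, baseline_ms: tuple = BASELINE_MS) -> np.ndarray:
    """Pointwise trial mean with pre-pulse baseline-mean subtraction.

    Returns channels x samples.
    """
    if epochs.n_trials < 1:
        raise InvalidInputError("no trials to average")
    avg = epochs.data.mean(axis=0)
    t_ms = epochs.t0_ms + np.arange(avg.shape[-1]) / epochs.fs * 1000.0
    sel = (t_ms >= baseline_ms[0]) & (t_ms < baseline_ms[1])
    if not sel.any():
        raise InvalidInputError("baseline window outside the epoch")
    return avg - avg[..., sel].mean(axis=-1, keepdims=True)
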