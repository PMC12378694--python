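"""Configuration objects for the synthetic cohort and the outcome model.

Defaults encode the study conditions: a 56-patient cohort (30 seizure-free,
26 not), ~12 electrode shafts of 8-16 contacts at 3.5 mm pitch (2 mm contact +
1.5 mm gap), ~17 cm^3 resections, 6 mA / 300 us biphasic single pulses repeated
40x at 0.5 Hz, and 50 Hz line noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Tuple

from .errors import InvalidConfigError
from .schema import EDGE_CLASSES, GROUPS

EdgeClass = Tuple[str, str]
AmpByClass = Dict[str, Dict[EdgeClass, Tuple[float, float]]]


@dataclass
class CohortConfig:
    """Cohort geometry and acquisition parameters."""

    n_sf: int = 30
    n_nsf: int = 26
    shafts_mean: float = 11.96
    shafts_sd: float = 2.00
    shafts_range: Tuple[int, int] = (4, 16)
    contacts_range: Tuple[int, int] = (8, 16)
    contact_pitch_mm: float = 3.5
    resection_volume_mean_cm3: float = 17.08
    resection_volume_sd_cm3: float = 4.19
    line_freq_hz: float = 50.0
    raw_fs_hz: float = 2000.0
    volume_shape: Tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 1.0
    n_soz_channels: int = 2
    n_ir_channels: int = 2
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if min(self.n_sf, self.n_nsf, self.n_soz_channels) < 1:
            raise InvalidConfigError("all counts must be >= 1")
        if self.n_sf + self.n_nsf < 8:
            raise InvalidConfigError("cohort must have at least 8 patients")
        if self.contact_pitch_mm <= 0:
            raise InvalidConfigError("contact pitch must be positive")
        if self.contacts_range[0] < 2:
            raise InvalidConfigError("shafts need at least 2 contacts")
        if self.shafts_range[0] < 1 or self.shafts_range[0] > self.shafts_range[1]:
            raise InvalidConfigError("invalid shaft count range")
        if self.contacts_range[0] > self.contacts_range[1]:
            raise InvalidConfigError("invalid contacts range")
        if self.raw_fs_hz < 2 * 300.0:
            raise InvalidConfigError("raw_fs must be >= twice the 300 Hz bandpass edge")
        if any(s < 3 for s in self.volume_shape):
            raise InvalidConfigError("volume dims must each be >= 3")
        return self

    @classmethod
    def reduced(cls, **overrides) -> "CohortConfig":
        """Reduced desk-scale geometry: 5-6 shafts of exactly 8 contacts.

        The upper half of the 4-6 shaft band is used: the fraction of
        resection-crossing edges must stay small enough for the target z-score
        magnitudes to be reachable (see the methods note), which a 4-shaft
        montage cannot satisfy.
        """
        base = dict(shafts_mean=5.6, shafts_sd=0.6, shafts_range=(5, 6),
                    contacts_range=(8, 8), volume_shape=(96, 96, 96),
                    n_soz_channels=1, n_ir_channels=1)
        base.update(overrides)
        return cls(**base)


@dataclass
class StimulationConfig:
    """Single-pulse stimulation protocol (current/phase are metadata only)."""

    pulse_current_ma: float = 6.0
    phase_us: float = 300.0
    n_trials: int = 40
    trial_rate_hz: float = 0.5

    def validate(self) -> "StimulationConfig":
        if self.n_trials < 1:
            raise InvalidConfigError("n_trials must be >= 1")
        if 1.0 / self.trial_rate_hz < 1.5:
            raise InvalidConfigError("trial interval must cover the 1.5 s epoch")
        return self


@dataclass
class EvokedModel:
    """Shape and noise model of the simulated evoked response.

    The early (N1) component is a Gaussian bump peaking at 25 ms (sigma 8 ms),
    the late (N2) component a broader Gaussian centred at 160 ms (sigma 45 ms);
    only their analysis windows (10-50 ms and 80-250 ms) are constrained by the
    protocol, the shapes are a modelling choice.  Background noise is pink
    (1/f^exponent) plus line-frequency sinusoids with per-contact phase;
    between-edge amplitude heterogeneity is multiplicative lognormal.
    """

    n1_peak_ms: float = 25.0
    n1_width_ms: float = 8.0
    n2_center_ms: float = 160.0
    n2_width_ms: float = 45.0
    artifact_ms: float = 5.0
    artifact_amp_uv: float = 150.0
    noise_sd_uv: float = 15.0
    pink_exponent: float = 1.0
    line_amp_uv: float = 20.0
    amp_cv: float = 0.30
    patient_class_jitter: float = 0.15
    amp_by_class: AmpByClass = field(default_factory=lambda: default_amp_by_class())

    def validate(self) -> "EvokedModel":
        if not (10.0 <= self.n1_peak_ms <= 50.0):
            raise InvalidConfigError("N1 template energy must sit in the 10-50 ms window")
        if not (80.0 <= self.n2_center_ms <= 250.0):
            raise InvalidConfigError("N2 template energy must sit in the 80-250 ms window")
        for group, per_class in self.amp_by_class.items():
            if group not in GROUPS:
                raise InvalidConfigError(f"unknown outcome group {group!r}")
            for cls_, (a1, a2) in per_class.items():
                if a1 < 0 or a2 < 0:
                    raise InvalidConfigError(f"negative amplitude for class {cls_}")
        if self.noise_sd_uv < 0 or self.line_amp_uv < 0 or self.amp_cv < 0:
            raise InvalidConfigError("noise/spread parameters must be >= 0")
        return self

    def with_amplitudes(self, amp_by_class: AmpByClass) -> "EvokedModel":
        return replace(self, amp_by_class=amp_by_class)


def default_amp_by_class(n1_uv: float = 40.0, n2_uv: float = 30.0) -> AmpByClass:
    """Uniform amplitudes for every directed class and group (pre-calibration)."""
    return {g: {c: (n1_uv, n2_uv) for c in EDGE_CLASSES} for g in GROUPS}


@dataclass
class ModelConfig:
    """Outcome-classifier settings: 3:1 stratified split, linear SVM, 5-fold CV."""

    c_grid: Tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    n_folds: int = 5
    split_ratio: float = 0.75
    stratified: bool = True
    leakage_mode: str = "train-only"  # or "study-literal" (scale before splitting)
    positive_class: str = "nSF"
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if not self.c_grid:
            raise InvalidConfigError("C grid must be nonempty")
        if self.n_folds < 2:
            raise InvalidConfigError("need at least 2 CV folds")
        if not (0.0 < self.split_ratio < 1.0):
            raise InvalidConfigError("split ratio must lie in (0, 1)")
        if self.leakage_mode not in ("train-only", "study-literal"):
            raise InvalidConfigError(f"unknown leakage_mode {self.leakage_mode!r}")
        if self.positive_class not in GROUPS:
            raise InvalidConfigError(f"unknown positive class {self.positive_class!r}")
        return self


def config_to_dict(cfg) -> dict:
    return asdict(cfg)
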