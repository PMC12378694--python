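"""Calibration targets for the synthetic cohort.

``FeatureTargets`` holds, per connectivity category and outcome group, the mean
and SD of the final within-patient z-scored RMS feature.  Defaults are the
study's printed group profiles: the four OUT features of the OR (SOZ <->
outside-resection) and IO (resection <-> outside) categories differ between
seizure-free (SF) and non-seizure-free (nSF) patients; the IN counterparts are
given half the OUT group difference (reported as relevant to the model but not
univariately significant); the four IR (SOZ <-> in-resection) features are
equal across groups.

``ClinicalParams`` holds the clinical covariate distributions: binary
prevalences per group, scaled-Beta age/duration distributions matching the
per-group medians and ranges, and Gaussian anti-seizure-medication counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .errors import InvalidConfigError
from .schema import CATEGORIES, COMPONENTS, DIRECTIONS, GROUPS

FeatureKey = Tuple[str, str, str]  # (category, component, direction)


def _default_target_table() -> Dict[FeatureKey, Dict[str, Tuple[float, float]]]:
    # printed group profiles (mean, sd) of the z-scored features
    printed_out = {
        ("OR", "N1"): {"SF": (0.72, 0.30), "nSF": (0.95, 0.29)},
        ("OR", "N2"): {"SF": (0.96, 0.26), "nSF": (1.30, 0.34)},
        ("IO", "N1"): {"SF": (1.43, 0.78), "nSF": (1.90, 0.90)},
        ("IO", "N2"): {"SF": (1.77, 0.86), "nSF": (2.33, 1.11)},
    }
    ir_defaults = {"N1": (1.00, 0.40), "N2": (1.30, 0.50)}
    table: Dict[FeatureKey, Dict[str, Tuple[float, float]]] = {}
    for cat in CATEGORIES:
        for comp in COMPONENTS:
            for direction in DIRECTIONS:
                if cat == "IR":
                    m, s = ir_defaults[comp]
                    table[(cat, comp, direction)] = {g: (m, s) for g in GROUPS}
                else:
                    sf, nsf = printed_out[(cat, comp)]["SF"], printed_out[(cat, comp)]["nSF"]
                    if direction == "out":
                        table[(cat, comp, direction)] = {"SF": sf, "nSF": nsf}
                    else:
                        # IN: same SF mean, half the OUT group difference, SF sd
                        half = (sf[0] + 0.5 * (nsf[0] - sf[0]), max(sf[1], 0.05))
                        table[(cat, comp, direction)] = {"SF": sf, "nSF": half}
    return table


@dataclass
class FeatureTargets:
    """Per-(category, component, direction, group) mean and sd of the z features."""

    table: Dict[FeatureKey, Dict[str, Tuple[float, float]]] = field(
        default_factory=_default_target_table
    )

    def validate(self) -> "FeatureTargets":
        for key, per_group in self.table.items():
            for g, (m, s) in per_group.items():
                if s < 0:
                    raise InvalidConfigError(f"negative sd for {key}/{g}")
        return self

    def mean(self, cat: str, comp: str, direction: str, group: str) -> float:
        return self.table[(cat, comp, direction)][group][0]

    def sd(self, cat: str, comp: str, direction: str, group: str) -> float:
        return self.table[(cat, comp, direction)][group][1]

    def feature_mean(self, feature: str, group: str) -> float:
        cat, comp, direction = feature.split("_")
        return self.mean(cat, comp, direction, group)

    def feature_sd(self, feature: str, group: str) -> float:
        cat, comp, direction = feature.split("_")
        return self.sd(cat, comp, direction, group)

    @classmethod
    def default(cls) -> "FeatureTargets":
        return cls()

    @classmethod
    def null(cls) -> "FeatureTargets":
        """Both groups get the SF profile: no between-group differences."""
        base = _default_target_table()
        table = {k: {g: v["SF"] for g in GROUPS} for k, v in base.items()}
        return cls(table=table)

    def with_sd_zero_replaced(self, sd: float) -> "FeatureTargets":
        table = {k: {g: (m_s[0], sd) for g, m_s in v.items()} for k, v in self.table.items()}
        return replace(self, table=table)


def _beta_params_for(median: float, lo: float, hi: float, alpha: float = 2.0):
    """Beta(alpha, beta) scaled to [lo, hi] whose median matches the target."""
    q = (median - lo) / (hi - lo)
    if not (0.0 < q < 1.0):
        raise InvalidConfigError("median must lie strictly inside the range")
    f = lambda b: beta_dist.median(alpha, b) - q
    b = brentq(f, 1e-3, 1e3)
    return alpha, b


@dataclass
class ScaledBeta:
    """A Beta distribution scaled to a closed interval (ages, durations)."""

    lo: float
    hi: float
    a: float
    b: float

    @classmethod
    def from_median_range(cls, median: float, lo: float, hi: float) -> "ScaledBeta":
        a, b = _beta_params_for(median, lo, hi)
        return cls(lo=lo, hi=hi, a=a, b=b)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * rng.beta(self.a, self.b, size=n)


def _default_clinical() -> dict:
    # per-group binary prevalences and continuous distributions (cohort table)
    return {
        "rates": {
            "lateral_left": {"SF": 18 / 30, "nSF": 10 / 26},
            "hs": {"SF": 16 / 30, "nSF": 13 / 26},
            "mri_positive": {"SF": 19 / 30, "nSF": 13 / 26},
            "gtcs": {"SF": 11 / 30, "nSF": 18 / 26},
            "memory_abnormal": {"SF": 17 / 30, "nSF": 19 / 26},
        },
        "age_onset": {
            "SF": ScaledBeta.from_median_range(11.8, 0.5, 26.0),
            "nSF": ScaledBeta.from_median_range(12.5, 1.0, 30.0),
        },
        "age_surgery": {
            "SF": ScaledBeta.from_median_range(24.5, 8.5, 36.0),
            "nSF": ScaledBeta.from_median_range(24.0, 12.0, 42.0),
        },
        "duration": {
            "SF": ScaledBeta.from_median_range(9.5, 1.0, 24.0),
            "nSF": ScaledBeta.from_median_range(10.5, 2.5, 32.0),
        },
        "asm": {"SF": (3.0, 1.0), "nSF": (3.5, 2.5)},
    }


@dataclass
class ClinicalParams:
    """Clinical covariate distributions, per outcome group."""

    params: dict = field(default_factory=_default_clinical)

    @classmethod
    def default(cls) -> "ClinicalParams":
        return cls()

    @classmethod
    def pooled(cls) -> "ClinicalParams":
        """No group differences: every covariate follows the whole-cohort rates."""
        pooled_rates = {
            "lateral_left": 28 / 56,
            "hs": 29 / 56,
            "mri_positive": 32 / 56,
            "gtcs": 29 / 56,
            "memory_abnormal": 36 / 56,
        }
        p = _default_clinical()
        p["rates"] = {k: {g: v for g in GROUPS} for k, v in pooled_rates.items()}
        for key, med, lo, hi in (
            ("age_onset", 12.0, 0.5, 30.0),
            ("age_surgery", 24.0, 8.5, 42.0),
            ("duration", 10.0, 1.0, 32.0),
        ):
            dist = ScaledBeta.from_median_range(med, lo, hi)
            p[key] = {g: dist for g in GROUPS}
        p["asm"] = {g: (3.0, 1.0) for g in GROUPS}
        return cls(params=p)
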