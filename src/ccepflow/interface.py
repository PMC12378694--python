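"""Run configuration and end-to-end orchestration.

A run is described by a YAML file (or an in-memory ``RunConfig``): synthetic
mode ("signal" runs geometry -> signals -> features; "feature" samples the
patient table directly), the component configurations, an output directory
and one global seed from which every stage derives its own substream.  All
protocol constants (gray-matter threshold 0.1, 24/27 cube rule, 10 mm
exclusion radius, N1/N2 windows, C grid, 5 folds, 3:1 split) are surfaced on
the configuration objects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import calibrate_amplitudes, collect_geometry_stats
from .cohort import generate_feature_cohort
from .config import CohortConfig, EvokedModel, ModelConfig, StimulationConfig
from .errors import InvalidConfigError
from .interpret import force_decomposition, rank_features, shap_matrix
from .model import cross_validate_final
from .pipeline import run_signal_cohort
from .schema import CCEP_FEATURES
from .seeds import stage_seed
from .stats import compare_distance_profiles, compare_feature_table
from .targets import ClinicalParams, FeatureTargets

logger = logging.getLogger(__name__)

_SECTION_TYPES = {
    "cohort": CohortConfig,
    "stim": StimulationConfig,
    "evoked": EvokedModel,
    "model": ModelConfig,
}
_TOP_KEYS = {"mode", "seed", "out_dir", "log_level", "targets", "clinical",
             "calibrate"} | set(_SECTION_TYPES)


@dataclass
class RunConfig:
    mode: str = "feature"  # "signal" or "feature"
    seed: int = 0
    out_dir: str = "results/run"
    log_level: str = "INFO"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stim: StimulationConfig = field(default_factory=StimulationConfig)
    evoked: EvokedModel = field(default_factory=EvokedModel)
    model: ModelConfig = field(default_factory=ModelConfig)
    targets: str = "default"  # "default" or "null"
    clinical: str = "default"  # "default" or "pooled"
    calibrate: bool = True  # signal mode: calibrate amplitudes to the targets

    def validate(self) -> "RunConfig":
        if self.mode not in ("signal", "feature"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.targets not in ("default", "null"):
            raise InvalidConfigError(f"unknown targets preset {self.targets!r}")
        if self.clinical not in ("default", "pooled"):
            raise InvalidConfigError(f"unknown clinical preset {self.clinical!r}")
        self.cohort.validate()
        self.stim.validate()
        self.evoked.validate()
        self.model.validate()
        return self

    def feature_targets(self) -> FeatureTargets:
        return FeatureTargets.null() if self.targets == "null" else FeatureTargets.default()

    def clinical_params(self) -> ClinicalParams:
        return ClinicalParams.pooled() if self.clinical == "pooled" else ClinicalParams.default()


def load_and_validate_config(path) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are a hard error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError("config root must be a mapping")
    errors = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for section, typ in _SECTION_TYPES.items():
        sub = raw.get(section, {}) or {}
        names = {f.name for f in dataclasses.fields(typ)}
        bad = set(sub) - names
        if bad:
            errors.append(f"unknown keys in {section!r}: {sorted(bad)}")
            sub = {k: v for k, v in sub.items() if k in names}
        sub = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in sub.items()
            if k != "amp_by_class"
        }
        kwargs[section] = typ(**sub)
    for key in ("mode", "seed", "out_dir", "log_level", "targets", "clinical", "calibrate"):
        if key in raw:
            kwargs[key] = raw[key]
    if errors:
        raise InvalidConfigError("; ".join(errors))
    cfg = RunConfig(**kwargs)
    return cfg.validate()


def dump_config(cfg: RunConfig, path) -> Path:
    """Write a YAML representation that round-trips through the loader."""
    out = dict(
        mode=cfg.mode, seed=cfg.seed, out_dir=cfg.out_dir, log_level=cfg.log_level,
        targets=cfg.targets, clinical=cfg.clinical, calibrate=cfg.calibrate,
    )
    for section, typ in _SECTION_TYPES.items():
        d = dataclasses.asdict(getattr(cfg, section))
        d.pop("amp_by_class", None)
        out[section] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    path = Path(path)
    path.write_text(yaml.safe_dump(out, sort_keys=True))
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured end-to-end run and persist its artifacts.

    Signal mode: calibrate -> simulate/localize/preprocess/feature ->
    statistics -> model -> attribution.  Feature mode skips the signal stages.
    Reruns with the same configuration and seed are bit-identical.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}
    targets = cfg.feature_targets()
    clinical = cfg.clinical_params()

    if cfg.mode == "signal":
        evoked = cfg.evoked
        if cfg.calibrate:
            logger.info("calibrating evoked amplitudes to the feature targets")
            stats_g = collect_geometry_stats(
                cfg.cohort, cfg.stim, evoked, seed=stage_seed(cfg.seed, "calibrate")
            )
            amps, cal_info = calibrate_amplitudes(
                targets, stats_g, evoked=evoked, seed=stage_seed(cfg.seed, "calibrate", 1)
            )
            evoked = evoked.with_amplitudes(amps)
            results["calibration"] = cal_info
        table, distances, info = run_signal_cohort(
            cfg.cohort, cfg.stim, evoked, cfg.seed, clinical_params=clinical,
            keep_edges=True,
        )
        distances.to_csv(out / "soz_distances.csv", index=False)
        written.append(out / "soz_distances.csv")
        edges = pd.concat([e["edges"] for e in info], ignore_index=True)
        edges.to_csv(out / "edges.csv", index=False)
        written.append(out / "edges.csv")
        exclusions = pd.concat([e["exclusions"] for e in info], ignore_index=True)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        written.append(out / "exclusions.csv")
        results["distance_comparison"] = {
            zone: dataclasses.asdict(c)
            for zone, c in compare_distance_profiles(distances).items()
        }
        results["cohort_info"] = [
            {k: v for k, v in e.items() if k not in ("geometry", "edges", "exclusions")}
            for e in info
        ]
    else:
        table = generate_feature_cohort(cfg.cohort, targets, clinical, cfg.seed)

    table.to_csv(out / "features.csv")
    written.append(out / "features.csv")

    comparisons = compare_feature_table(table, CCEP_FEATURES)
    comparisons.to_csv(out / "group_comparisons.csv", index=False)
    written.append(out / "group_comparisons.csv")
    results["comparisons"] = comparisons

    report = cross_validate_final(table, cfg.model, seed=cfg.seed)
    (out / "model_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    written.append(out / "model_report.json")
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        out / "roc_points.csv", index=False
    )
    written.append(out / "roc_points.csv")
    results["model_report"] = report

    shap_vals = shap_matrix(
        report.weights, report.bias, report.X_train, report.X_train.to_numpy()
    )
    ranking, long = rank_features(shap_vals, report.X_train)
    shap_vals.to_csv(out / "shap_matrix.csv")
    ranking.to_csv(out / "shap_ranking.csv", index=False)
    long.to_csv(out / "shap_long.csv", index=False)
    base = float(
        (report.X_train.to_numpy() @ report.weights + report.bias).mean()
    )
    force_decomposition(shap_vals, base).to_csv(out / "shap_force.csv")
    written += [out / "shap_matrix.csv", out / "shap_ranking.csv",
                out / "shap_long.csv", out / "shap_force.csv"]
    results["shap_ranking"] = ranking

    manifest = dict(
        version=__version__,
        seed=cfg.seed,
        mode=cfg.mode,
        numpy=np.__version__,
        files={p.name: _sha256(p) for p in written},
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
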