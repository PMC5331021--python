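"""End-to-end orchestration: simulate → slice → extract → features → DFA.

One config and one seed fully determine a run. Every stage persists its
output as CSV/JSON in the output directory so each stage can be re-run
and tested independently, and a manifest records the configuration hash,
seed, package version, exclusion lists and stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .actigraphy_io import EVENING, MORNING, read_minute_series, slice_window
from .active_period import ActiveSegment, find_active_segment
from .canonical_dfa import (
    bootstrap_dfa,
    classification_table,
    classify,
    fit_dfa,
    leave_one_out_cv,
    manova_screen,
    standardized_residual_scores,
    structure_matrix_report,
)
from .errors import ConfigurationError, InsufficientDataError
from .features import build_feature_table
from .synthetic_cohort import GeneratorConfig, default_profiles

logger = logging.getLogger("actiphase")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "actiphase_run"
    #: path to an existing cohort CSV; when None the generator is used
    input_counts: str | None = None
    #: path to a subject table CSV (required with input_counts)
    input_subjects: str | None = None
    seed: int = 17
    n_subjects: int = 34
    day_rule: str = "prefer_maximal_coverage"
    segment_length: int = 64
    start_tolerance: int = 2
    priors: str = "proportional"
    n_boot: int = 1000
    structure_threshold: float = 0.3
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "gender")
    generator: GeneratorConfig | None = None

    def validate(self) -> None:
        if self.segment_length < 2 or self.segment_length & (self.segment_length - 1):
            raise ConfigurationError(
                f"segment_length={self.segment_length} must be a power of two "
                "(required by the spectral analysis)"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.start_tolerance < 0:
            raise ConfigurationError("start_tolerance must be non-negative")
        if self.priors not in ("proportional", "equal"):
            raise ConfigurationError(f"unknown priors {self.priors!r}")
        if (self.input_counts is None) != (self.input_subjects is None):
            raise ConfigurationError("input_counts and input_subjects go together")


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file; unknown keys are rejected."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    generator = raw.pop("generator", None)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig(**raw)
    if generator is not None:
        config.generator = GeneratorConfig(**generator)
    return config


def _config_hash(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    payload = json.dumps(encode(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _segments_to_frame(segments: list[ActiveSegment]) -> pd.DataFrame:
    rows = []
    for seg in segments:
        row = {
            "subject_id": seg.subject_id,
            "window_label": seg.window_label,
            "start_time": seg.start_time.strftime("%Y-%m-%dT%H:%M"),
            "tolerance_used": seg.tolerance_used,
        }
        row.update({f"c{i}": int(v) for i, v in enumerate(seg.counts)})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest.

    Stages: cohort acquisition (generator or files), day-window slicing,
    active-period extraction, feature computation, standardized residual
    scores, MANOVA screen, DFA with apparent + leave-one-out
    classification, stratified bootstrap. All intermediate artifacts are
    written to ``config.output_dir``; on stage failure a FAILED marker
    naming the stage is left beside the partial outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        # --- acquire cohort -------------------------------------------------
        stage = "simulate" if config.input_counts is None else "load"
        tic = time.perf_counter()
        if config.input_counts is None:
            from .synthetic_cohort import generate_cohort, write_cohort_csv

            gen_cfg = config.generator or GeneratorConfig(
                n_subjects=config.n_subjects,
                seed=config.seed,
                phase_profiles=default_profiles(),
            )
            series_list, subjects = generate_cohort(gen_cfg)
            write_cohort_csv(series_list, out / "cohort_counts.csv")
            subjects.to_csv(out / "subjects.csv", index=False)
        else:
            series_list = read_minute_series(config.input_counts)
            subjects = pd.read_csv(config.input_subjects)
        timings[stage] = time.perf_counter() - tic
        logger.info("%s: %d subjects", stage, len(series_list))

        # --- slice + extract ------------------------------------------------
        stage = "extract"
        tic = time.perf_counter()
        segments: list[ActiveSegment] = []
        extraction_failures: list[dict] = []
        for series in series_list:
            for window, direction in ((MORNING, "forward"), (EVENING, "backward")):
                sliced = slice_window(series, window, config.day_rule)
                try:
                    segments.append(
                        find_active_segment(
                            sliced,
                            direction,
                            window_label=window.label,
                            length=config.segment_length,
                            start_tolerance=config.start_tolerance,
                        )
                    )
                except InsufficientDataError as err:
                    extraction_failures.append(
                        {"subject_id": series.subject_id, "window": window.label, "error": str(err)}
                    )
        _segments_to_frame(segments).to_csv(out / "segments.csv", index=False)
        timings[stage] = time.perf_counter() - tic

        # --- features -------------------------------------------------------
        stage = "features"
        tic = time.perf_counter()
        features, exclusions = build_feature_table(segments, subjects)
        features.to_csv(out / "features.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        timings[stage] = time.perf_counter() - tic
        logger.info("features: %d rows, %d exclusions", len(features), len(exclusions))

        # --- DFA ------------------------------------------------------------
        stage = "dfa"
        tic = time.perf_counter()
        predictor_cols = [c for c in features.columns if c not in ("subject_id", "phase", "age", "gender")]
        covariate_frame = features[list(config.covariates)].copy()
        if "gender" in covariate_frame:
            covariate_frame["gender"] = (covariate_frame["gender"] == "female").astype(float)
        predictors = standardized_residual_scores(features[predictor_cols], covariate_frame)
        groups = features["phase"].to_numpy()

        manova = manova_screen(predictors, groups)
        model = fit_dfa(predictors, groups, priors=config.priors)
        apparent = classification_table(
            groups, classify(model, predictors), groups=model.groups, mode="apparent"
        )
        loocv = leave_one_out_cv(predictors, groups, priors=config.priors)
        boot = bootstrap_dfa(
            predictors, groups, n_boot=config.n_boot, seed=config.seed, priors=config.priors
        )
        full, filtered = structure_matrix_report(model, config.structure_threshold)

        with open(out / "model.json", "w") as handle:
            json.dump(
                {
                    "manova": dataclasses.asdict(manova),
                    "model": model.to_dict(),
                    "apparent_accuracy_pct": apparent.overall_accuracy,
                    "loocv_accuracy_pct": loocv.overall_accuracy,
                    "bootstrap": {
                        "n_boot": boot.n_boot,
                        "n_dropped": boot.n_dropped,
                        "eigenvalue_ci": boot.eigenvalue_ci.tolist(),
                        "canonical_correlation_ci": boot.canonical_correlation_ci.tolist(),
                        "accuracy_ci": boot.accuracy_ci.tolist(),
                    },
                },
                handle,
                indent=2,
            )
        full.to_csv(out / "structure_matrix.csv")
        filtered.to_csv(out / "structure_matrix_filtered.csv")
        apparent.to_frame().to_csv(out / "classification_apparent.csv")
        loocv.to_frame().to_csv(out / "classification_loocv.csv")
        boot.to_frame().to_csv(out / "bootstrap.csv", index=False)
        timings[stage] = time.perf_counter() - tic

        manifest["stages"] = timings
        manifest["n_subjects"] = len(series_list)
        manifest["n_feature_rows"] = len(features)
        manifest["extraction_failures"] = extraction_failures
        manifest["n_excluded"] = len(exclusions)
        manifest["apparent_accuracy_pct"] = apparent.overall_accuracy
        manifest["loocv_accuracy_pct"] = loocv.overall_accuracy
        manifest["manova_p"] = manova.p_value
        with open(out / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2)
        return manifest
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage} failed: {err}\n")
        raise
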