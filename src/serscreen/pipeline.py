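"""Configured, logged, reproducible pipeline runs.

A run is described by a YAML/JSON-style mapping (see :func:`validate_config`)
and executes any subset of the four stages, each reading and writing plain
CSV/JSON artifacts so stages can also be run independently:

    simulate    cohort spectra CSVs + manifest.csv
    preprocess  processed_matrix.csv   (samples × wavenumbers)
    stats       peak_matrix.csv, comparisons.csv, difference_spectra.csv
    classify    msep_curve.csv, loadings.csv, grid_surface.csv,
                confusion_matrix.csv, roc_points.csv, metrics.json

Every numeric artifact is a pure function of the run configuration and the
root seed; the run manifest records parameter snapshots and SHA-256 hashes
of all outputs so a rerun can be verified byte-for-byte (metrics.json
contains no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import (
    ChemometricsConfig,
    LabeledSpectraMatrix,
    PipelineResult,
    run_pls_svm,
)
from .exceptions import ConfigError, SerscreenError
from .preprocess import (
    PreprocessingConfig,
    frame_to_samples,
    preprocess_cohort,
    samples_to_frame,
)
from .stats import (
    build_peak_matrix,
    compare_peak_matrix,
    default_peak_table,
    mean_and_difference_spectra,
)
from .synthetic import (
    GroupEffectProfile,
    PeakTemplate,
    SpectralGrid,
    SyntheticCohortConfig,
    generate_cohort,
    write_cohort,
)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run", "STAGES"]

log = logging.getLogger("serscreen")

STAGES = ("simulate", "preprocess", "stats", "classify")


@dataclass(frozen=True)
class RunConfig:
    """Validated, defaulted description of one pipeline run."""

    outdir: Path = Path("serscreen-run")
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    alpha: float = 0.05
    window_halfwidth: float = 5.0
    p_adjust: str | None = None
    chemometrics: ChemometricsConfig = field(default_factory=ChemometricsConfig)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record of one run: parameters, outputs, hashes."""

    version: str
    seed: int
    stages: tuple[str, ...]
    parameters: Mapping[str, Any]
    outputs: Mapping[str, str]  # artifact name -> sha256
    started: str
    finished: str


def _require(mapping: Mapping[str, Any], key: str, kind, path: str):
    value = mapping[key]
    if kind is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if not isinstance(value, kind) or isinstance(value, bool) and kind is not bool:
        raise ConfigError(
            f"config key {path}.{key}: expected {getattr(kind, '__name__', kind)}, "
            f"got {type(value).__name__} ({value!r})"
        )
    return value


def _take_section(raw: Mapping[str, Any], name: str, known: Sequence[str]) -> dict:
    section = raw.get(name, {})
    if section is None:
        section = {}
    if not isinstance(section, Mapping):
        raise ConfigError(f"config key {name}: expected a mapping")
    for key in section:
        if key not in known:
            warnings.warn(f"unknown config key {name}.{key} ignored", stacklevel=3)
    return dict(section)


def _build_cohort_config(raw: Mapping[str, Any], seed: int) -> SyntheticCohortConfig:
    known = ("grid", "n_samples_per_group", "n_replicates", "noise_sd",
             "sample_sd", "replicate_sd", "baseline_coefficients", "effects",
             "peak_amplitudes", "seed")
    sec = _take_section(raw, "cohort", known)
    kwargs: dict[str, Any] = {"seed": int(sec.get("seed", seed))}

    for key, kind in (("n_samples_per_group", int), ("n_replicates", int),
                      ("noise_sd", float), ("sample_sd", float),
                      ("replicate_sd", float)):
        if key in sec:
            kwargs[key] = _require(sec, key, kind, "cohort")
    if "grid" in sec:
        g = sec["grid"]
        if not isinstance(g, Mapping):
            raise ConfigError("config key cohort.grid: expected a mapping")
        kwargs["grid"] = SpectralGrid(
            start=float(g.get("start", 400.0)),
            stop=float(g.get("stop", 1800.0)),
            step=float(g.get("step", 2.0)),
        )
    if "baseline_coefficients" in sec:
        coeffs = sec["baseline_coefficients"]
        if not isinstance(coeffs, Sequence) or isinstance(coeffs, str):
            raise ConfigError("config key cohort.baseline_coefficients: expected a list")
        kwargs["baseline_coefficients"] = tuple(float(c) for c in coeffs)
    if "effects" in sec:
        eff = sec["effects"]
        if not isinstance(eff, Mapping):
            raise ConfigError("config key cohort.effects: expected a mapping group -> {position: multiplier}")
        kwargs["effects"] = tuple(
            GroupEffectProfile(str(g), {float(k): float(v) for k, v in (m or {}).items()})
            for g, m in eff.items()
        )
    base = SyntheticCohortConfig()
    if "peak_amplitudes" in sec:
        amps = sec["peak_amplitudes"]
        if not isinstance(amps, Mapping):
            raise ConfigError("config key cohort.peak_amplitudes: expected a mapping position -> amplitude")
        amp_map = {float(k): float(v) for k, v in amps.items()}
        kwargs["peaks"] = tuple(
            PeakTemplate(p.center, amp_map.get(p.center, p.amplitude), p.width, p.assignment)
            for p in base.peaks
        )
    try:
        return dataclasses.replace(base, **kwargs)
    except SerscreenError as exc:
        raise ConfigError(f"config section cohort: {exc}") from exc


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse, default and schema-check a run configuration.

    ``source`` may be a YAML/JSON file path or an already-parsed mapping.
    Unknown keys warn and are ignored; type errors raise :class:`ConfigError`
    naming the offending key path.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.is_file():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise ConfigError("top-level config must be a mapping")

    top_known = ("outdir", "seed", "stages", "cohort", "preprocessing",
                 "statistics", "chemometrics")
    for key in raw:
        if key not in top_known:
            warnings.warn(f"unknown config key {key} ignored", stacklevel=2)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"config key seed: expected int, got {seed!r}")

    stages_raw = raw.get("stages", list(STAGES))
    if isinstance(stages_raw, str):
        stages_raw = [stages_raw]
    stages = tuple(stages_raw)
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"config key stages: unknown stage {s!r}; valid: {STAGES}")

    pre_sec = _take_section(raw, "preprocessing", (
        "polynomial_order", "tolerance", "max_iterations",
        "normalize_before_average", "clip_negative"))
    pre_kwargs = {}
    for key, kind in (("polynomial_order", int), ("tolerance", float),
                      ("max_iterations", int), ("normalize_before_average", bool),
                      ("clip_negative", bool)):
        if key in pre_sec:
            pre_kwargs[key] = _require(pre_sec, key, kind, "preprocessing")

    stat_sec = _take_section(raw, "statistics", ("alpha", "window_halfwidth", "p_adjust"))
    alpha = float(stat_sec.get("alpha", 0.05))
    if not (0 < alpha < 1):
        raise ConfigError(f"config key statistics.alpha: must be in (0, 1), got {alpha}")

    chem_sec = _take_section(raw, "chemometrics", (
        "n_components_max", "selection_threshold", "selection_form", "folds",
        "c_grid", "sigma_grid", "positive_class", "binary_tasks",
        "refit_pls_per_fold", "seed"))
    chem_kwargs: dict[str, Any] = {"seed": int(chem_sec.get("seed", seed))}
    for key, kind in (("n_components_max", int), ("selection_threshold", float),
                      ("selection_form", str), ("folds", int),
                      ("positive_class", str), ("binary_tasks", bool),
                      ("refit_pls_per_fold", bool)):
        if key in chem_sec:
            chem_kwargs[key] = _require(chem_sec, key, kind, "chemometrics")
    for key in ("c_grid", "sigma_grid"):
        if key in chem_sec:
            grid_vals = chem_sec[key]
            if not isinstance(grid_vals, Sequence) or isinstance(grid_vals, str):
                raise ConfigError(f"config key chemometrics.{key}: expected a list")
            chem_kwargs[key] = tuple(float(v) for v in grid_vals)

    try:
        return RunConfig(
            outdir=Path(raw.get("outdir", "serscreen-run")),
            seed=seed,
            stages=stages,
            cohort=_build_cohort_config(raw, seed),
            preprocessing=PreprocessingConfig(**pre_kwargs),
            alpha=alpha,
            window_halfwidth=float(stat_sec.get("window_halfwidth", 5.0)),
            p_adjust=stat_sec.get("p_adjust"),
            chemometrics=ChemometricsConfig(**chem_kwargs),
        )
    except SerscreenError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> list[Path]:
    log.info("simulate: %d groups × %d samples × %d replicates, seed %d",
             len(config.cohort.effects), config.cohort.n_samples_per_group,
             config.cohort.n_replicates, config.cohort.seed)
    records = generate_cohort(config.cohort)
    manifest = write_cohort(records, config.outdir)
    return [manifest]


def stage_preprocess(config: RunConfig) -> list[Path]:
    manifest = config.outdir / "manifest.csv"
    if not manifest.is_file():
        raise ConfigError(f"preprocess stage: cohort manifest not found at {manifest}")
    log.info("preprocess: baseline order %d, tol %g",
             config.preprocessing.polynomial_order, config.preprocessing.tolerance)
    samples = preprocess_cohort(manifest, config.preprocessing)
    out = config.outdir / "processed_matrix.csv"
    samples_to_frame(samples).to_csv(out, index=False, float_format="%.10g")
    return [out]


def _load_samples(config: RunConfig):
    matrix_path = config.outdir / "processed_matrix.csv"
    if not matrix_path.is_file():
        raise ConfigError(f"stage input not found: {matrix_path}")
    return frame_to_samples(pd.read_csv(matrix_path))


def stage_stats(config: RunConfig) -> list[Path]:
    samples = _load_samples(config)
    table = default_peak_table(config.window_halfwidth)
    matrix = build_peak_matrix(samples, table)
    comparisons = compare_peak_matrix(matrix, alpha=config.alpha, adjust=config.p_adjust)
    log.info("stats: %d bands, %d significant at alpha=%g",
             len(table), int(comparisons["significant"].sum()), config.alpha)

    outputs = []
    peak_path = config.outdir / "peak_matrix.csv"
    matrix.to_frame().to_csv(peak_path, index=False, float_format="%.10g")
    outputs.append(peak_path)

    comp_path = config.outdir / "comparisons.csv"
    comparisons.to_csv(comp_path, index=False, float_format="%.10g")
    outputs.append(comp_path)

    groups = list(dict.fromkeys(s.group for s in samples))
    diff_frame = pd.DataFrame({"wavenumber": samples[0].spectrum.grid.wavenumbers()})
    pairs = []
    if "OVX" in groups and "Sham" in groups:
        pairs.append(("OVX", "Sham"))
    if "ICA" in groups and "OVX" in groups:
        pairs.append(("ICA", "OVX"))
    if not pairs and len(groups) >= 2:
        pairs.append((groups[1], groups[0]))
    for a, b in pairs:
        _, diff = mean_and_difference_spectra(samples, a, b)
        diff_frame[f"{a}_minus_{b}"] = diff.difference
    diff_path = config.outdir / "difference_spectra.csv"
    diff_frame.to_csv(diff_path, index=False, float_format="%.10g")
    outputs.append(diff_path)
    return outputs


def _metrics_payload(result: PipelineResult, config: RunConfig) -> dict:
    tasks = {}
    for name, task in result.tasks.items():
        rep = task.report
        tasks[name] = {
            "n_components": task.n_components,
            "best_C": task.cv.best_params.C,
            "best_sigma": task.cv.best_params.sigma,
            "cv_accuracy_percent": round(100.0 * task.cv.best_accuracy, 4),
            "accuracy_percent": round(rep.accuracy_percent, 4),
            "positive_class": rep.positive_class,
            "sensitivity_percent": {
                c: round(rep.sensitivity_percent(c), 4) for c in rep.labels
            },
            "specificity_percent": {
                c: round(rep.specificity_percent(c), 4) for c in rep.labels
            },
            "auc": None if rep.auc is None else round(rep.auc, 6),
            "confusion_labels": list(rep.labels),
            "confusion": rep.confusion.astype(int).tolist(),
        }
    return {
        "seed": config.seed,
        "folds": config.chemometrics.folds,
        "selection_threshold": config.chemometrics.selection_threshold,
        "tasks": tasks,
    }


def stage_classify(config: RunConfig) -> list[Path]:
    samples = _load_samples(config)
    data = LabeledSpectraMatrix.from_samples(samples)
    log.info("classify: %d samples × %d wavenumbers, %d classes",
             data.X.shape[0], data.X.shape[1], len(data.classes))
    result = run_pls_svm(data, config.chemometrics)
    all_task = result.three_class

    outputs = []
    msep_path = config.outdir / "msep_curve.csv"
    pd.DataFrame({
        "n_components": np.arange(all_task.selection.msep_curve.size),
        "msep": all_task.selection.msep_curve,
    }).to_csv(msep_path, index=False, float_format="%.10g")
    outputs.append(msep_path)

    load_path = config.outdir / "loadings.csv"
    grid = samples[0].spectrum.grid
    loadings = pd.DataFrame(
        result.pls.loadings[:, :all_task.n_components],
        columns=[f"PC{k + 1}" for k in range(all_task.n_components)],
    )
    loadings.insert(0, "wavenumber", grid.wavenumbers())
    loadings.to_csv(load_path, index=False, float_format="%.10g")
    outputs.append(load_path)

    grid_path = config.outdir / "grid_surface.csv"
    all_task.cv.grid.to_csv(grid_path, index=False, float_format="%.10g")
    outputs.append(grid_path)

    conf_path = config.outdir / "confusion_matrix.csv"
    rep = all_task.report
    conf = pd.DataFrame(rep.confusion.astype(int),
                        index=[f"true_{c}" for c in rep.labels],
                        columns=[f"pred_{c}" for c in rep.labels])
    conf.to_csv(conf_path)
    outputs.append(conf_path)

    roc_path = config.outdir / "roc_points.csv"
    roc_rows = []
    for name, task in result.tasks.items():
        for fpr, tpr in task.report.roc_points:
            roc_rows.append({"task": name, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(roc_rows).to_csv(roc_path, index=False, float_format="%.10g")
    outputs.append(roc_path)

    metrics_path = config.outdir / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(_metrics_payload(result, config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs.append(metrics_path)
    return outputs


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run(config: RunConfig) -> RunManifest:
    """Execute the configured stages in order and write the run manifest."""
    started = datetime.now(timezone.utc).isoformat()
    config.outdir.mkdir(parents=True, exist_ok=True)
    stage_fns = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "stats": stage_stats,
        "classify": stage_classify,
    }
    outputs: dict[str, str] = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s starting", stage)
        try:
            for path in stage_fns[stage](config):
                outputs[str(path.relative_to(config.outdir))] = _sha256(path)
        except SerscreenError as exc:
            raise type(exc)(f"stage {stage}: {exc}") from exc
        log.info("stage %s done", stage)

    parameters = {
        "seed": config.seed,
        "stages": list(config.stages),
        "cohort": {
            "n_samples_per_group": config.cohort.n_samples_per_group,
            "n_replicates": config.cohort.n_replicates,
            "noise_sd": config.cohort.noise_sd,
            "sample_sd": config.cohort.sample_sd,
            "replicate_sd": config.cohort.replicate_sd,
            "grid": [config.cohort.grid.start, config.cohort.grid.stop,
                     config.cohort.grid.step],
            "seed": config.cohort.seed,
        },
        "preprocessing": dataclasses.asdict(config.preprocessing),
        "statistics": {"alpha": config.alpha,
                       "window_halfwidth": config.window_halfwidth,
                       "p_adjust": config.p_adjust},
        "chemometrics": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config.chemometrics).items()
        },
    }
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        stages=config.stages,
        parameters=parameters,
        outputs=outputs,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    manifest_path = config.outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
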