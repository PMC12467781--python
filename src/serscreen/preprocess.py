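"""Raw-acquisition preprocessing: baseline removal, normalization, averaging.

The processing chain per serum sample is

    raw replicate -> fluorescence baseline removal (iterative modified
    polynomial fitting, the Vancouver Raman Algorithm) -> area normalization
    (divide by the trapezoidal integral so spectra become densities per cm⁻¹)
    -> pointwise average of the sample's replicates.

Baseline removal and normalization are applied per replicate before
averaging by default, so one unusually bright acquisition cannot dominate a
sample's mean; the order is switchable via ``PreprocessingConfig``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import PreprocessingError
from .synthetic import CohortRecord, RawSpectrum, SpectralGrid

__all__ = [
    "BaselineResult",
    "ProcessedSpectrum",
    "SampleSpectrum",
    "PreprocessingConfig",
    "vancouver_baseline",
    "remove_baseline",
    "normalize_area",
    "average_replicates",
    "preprocess_records",
    "preprocess_cohort",
    "read_spectrum_csv",
    "read_manifest",
    "samples_to_frame",
    "frame_to_samples",
]


@dataclass(frozen=True)
class BaselineResult:
    """Outcome of iterative polynomial baseline estimation."""

    baseline: np.ndarray
    corrected: np.ndarray
    iterations: int
    converged: bool
    polynomial_order: int


@dataclass(frozen=True)
class ProcessedSpectrum:
    """Area-normalized spectrum: trapezoidal integral over the grid is 1."""

    grid: SpectralGrid
    intensities: np.ndarray


@dataclass(frozen=True)
class SampleSpectrum:
    """Replicate-averaged processed spectrum for one serum sample."""

    sample_id: str
    group: str
    spectrum: ProcessedSpectrum
    n_replicates_used: int


@dataclass(frozen=True)
class PreprocessingConfig:
    """Tunable preprocessing parameters.

    ``normalize_before_average`` switches between per-replicate normalization
    (default) and normalizing only the replicate-averaged spectrum.
    ``clip_negative`` zeroes negative baseline-corrected values before
    normalization (off by default, keeping normalization linear).
    """

    polynomial_order: int = 5
    tolerance: float = 1e-3
    max_iterations: int = 100
    normalize_before_average: bool = True
    clip_negative: bool = False


# Cache of (Vandermonde, pseudo-inverse) per grid/order: the design matrix is
# identical for every spectrum of a cohort, and the fit inside the stripping
# loop reuses it every iteration.
_VANDER_CACHE: dict[tuple[bytes, int], tuple[np.ndarray, np.ndarray]] = {}


def _design(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    key = (x.tobytes(), order)
    hit = _VANDER_CACHE.get(key)
    if hit is None:
        # scale to [-1, 1] for conditioning
        xi = (2.0 * x - (x[0] + x[-1])) / (x[-1] - x[0])
        V = np.polynomial.polynomial.polyvander(xi, order)
        hit = (V, np.linalg.pinv(V))
        if len(_VANDER_CACHE) > 32:
            _VANDER_CACHE.clear()
        _VANDER_CACHE[key] = hit
    return hit


def vancouver_baseline(
    x: np.ndarray,
    y: np.ndarray,
    order: int = 5,
    tolerance: float = 1e-3,
    max_iterations: int = 100,
) -> BaselineResult:
    """Iterative modified polynomial fit stripping peaks from a baseline.

    Each iteration least-squares-fits a polynomial of ``order`` to the
    working signal over the points not yet identified as peak (so stripped
    peak regions stop pulling the polynomial up), estimates the residual
    noise level as the standard deviation of (signal − fit) over those same
    points, and replaces every working-signal point above ``fit + noise``
    with the fit value.  Iteration stops when the fitted curve's maximum
    change relative to its dynamic range falls below ``tolerance`` or
    nothing remains to strip; non-convergence within ``max_iterations`` is
    reported via ``converged=False``, not an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.shape != x.shape:
        raise PreprocessingError("x and y must be 1-D arrays of equal length")
    if not np.all(np.isfinite(y)):
        raise PreprocessingError("baseline removal requires finite intensities")
    if order < 1:
        raise PreprocessingError(f"polynomial order must be >= 1, got {order}")
    if x.size < order + 2:
        raise PreprocessingError(
            f"need at least order+2={order + 2} points, got {x.size}"
        )

    V, pinv = _design(x, order)
    work = y.copy()
    stripped = np.zeros(x.size, dtype=bool)
    prev_fit: np.ndarray | None = None
    converged = False
    iterations = 0

    for iterations in range(1, max_iterations + 1):
        if stripped.any():
            keep = ~stripped
            coef, *_ = np.linalg.lstsq(V[keep], work[keep], rcond=None)
            fit = V @ coef
        else:
            keep = ~stripped
            fit = V @ (pinv @ work)
        resid = work - fit
        noise = float(resid[keep].std()) if keep.any() else float(resid.std())
        above = resid > noise
        if prev_fit is not None:
            span = float(fit.max() - fit.min())
            change = float(np.max(np.abs(fit - prev_fit)))
            if change / (span if span > 0 else 1.0) < tolerance:
                converged = True
                break
        if not above.any():
            converged = True
            break
        work[above] = fit[above]
        stripped |= above
        prev_fit = fit

    return BaselineResult(
        baseline=fit,
        corrected=y - fit,
        iterations=iterations,
        converged=converged,
        polynomial_order=order,
    )


def remove_baseline(
    spectrum: RawSpectrum,
    order: int = 5,
    tolerance: float = 1e-3,
    max_iterations: int = 100,
) -> BaselineResult:
    """Vancouver baseline removal on a :class:`RawSpectrum`."""
    return vancouver_baseline(
        spectrum.grid.wavenumbers(), spectrum.intensities,
        order=order, tolerance=tolerance, max_iterations=max_iterations,
    )


def normalize_area(
    intensities: np.ndarray | ProcessedSpectrum,
    grid: SpectralGrid | None = None,
    label: str | None = None,
) -> ProcessedSpectrum:
    """Divide by the trapezoidal integral so the spectrum integrates to 1."""
    if isinstance(intensities, ProcessedSpectrum):
        grid = intensities.grid
        values = intensities.intensities
    else:
        if grid is None:
            raise PreprocessingError("grid is required when passing a bare intensity vector")
        values = np.asarray(intensities, dtype=float)
    if values.shape != (grid.n_points,):
        raise PreprocessingError("intensity vector does not match the grid")
    area = float(np.trapezoid(values, grid.wavenumbers()))
    if area <= 0:
        name = f" ({label})" if label else ""
        raise PreprocessingError(
            f"cannot area-normalize spectrum{name}: integrated intensity {area:g} <= 0"
        )
    return ProcessedSpectrum(grid=grid, intensities=values / area)


def average_replicates(
    replicates: Sequence[ProcessedSpectrum],
    sample_id: str = "",
    group: str = "",
) -> SampleSpectrum:
    """Pointwise arithmetic mean of replicate spectra on one common grid."""
    if not replicates:
        raise PreprocessingError(f"sample {sample_id!r}: no replicates to average")
    grid = replicates[0].grid
    for i, rep in enumerate(replicates[1:], start=1):
        if rep.grid != grid:
            raise PreprocessingError(
                f"sample {sample_id!r}: replicate {i} grid {rep.grid} does not "
                f"match {grid}"
            )
    mean = np.mean([rep.intensities for rep in replicates], axis=0)
    return SampleSpectrum(
        sample_id=sample_id,
        group=group,
        spectrum=ProcessedSpectrum(grid=grid, intensities=mean),
        n_replicates_used=len(replicates),
    )


def _process_one(
    raw: RawSpectrum, params: PreprocessingConfig, label: str
) -> ProcessedSpectrum:
    res = remove_baseline(
        raw, order=params.polynomial_order,
        tolerance=params.tolerance, max_iterations=params.max_iterations,
    )
    corrected = res.corrected
    if params.clip_negative:
        corrected = np.clip(corrected, 0.0, None)
    return normalize_area(corrected, raw.grid, label=label)


def preprocess_records(
    records: Iterable[CohortRecord],
    params: PreprocessingConfig | None = None,
) -> list[SampleSpectrum]:
    """Baseline-correct, normalize and average an in-memory cohort.

    Returns one :class:`SampleSpectrum` per distinct sample, in first-seen
    sample order.
    """
    params = params or PreprocessingConfig()
    by_sample: dict[str, tuple[str, list]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, (rec.group, []))[1].append(rec)

    out: list[SampleSpectrum] = []
    for sample_id, (group, recs) in by_sample.items():
        if params.normalize_before_average:
            processed = [
                _process_one(r.spectrum, params, f"{sample_id} replicate {r.replicate}")
                for r in recs
            ]
            out.append(average_replicates(processed, sample_id=sample_id, group=group))
        else:
            corrected = []
            for r in recs:
                res = remove_baseline(
                    r.spectrum, order=params.polynomial_order,
                    tolerance=params.tolerance, max_iterations=params.max_iterations,
                )
                c = np.clip(res.corrected, 0.0, None) if params.clip_negative else res.corrected
                corrected.append(c)
            grid = recs[0].spectrum.grid
            mean = np.mean(corrected, axis=0)
            spec = normalize_area(mean, grid, label=sample_id)
            out.append(SampleSpectrum(sample_id, group, spec, len(recs)))
    return out


# ---------------------------------------------------------------------------
# File I/O: two-column spectrum CSVs, manifest, processed sample matrix
# ---------------------------------------------------------------------------

def read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column wavenumber,intensity CSV (header optional)."""
    xs: list[float] = []
    ys: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or len(row) < 2:
                continue
            try:
                x, y = float(row[0]), float(row[1])
            except ValueError:
                continue  # header line
            xs.append(x)
            ys.append(y)
    if not xs:
        raise PreprocessingError(f"{path}: no numeric wavenumber,intensity rows found")
    return np.asarray(xs), np.asarray(ys)


def _grid_from_wavenumbers(x: np.ndarray, source: str) -> SpectralGrid:
    steps = np.diff(x)
    if x.size < 2 or not np.allclose(steps, steps[0]):
        raise PreprocessingError(f"{source}: wavenumber axis is not a uniform grid")
    return SpectralGrid(start=float(x[0]), stop=float(x[-1]), step=float(steps[0]))


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"file", "sample_id", "group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise PreprocessingError(
            f"{manifest_path}: manifest is missing columns {sorted(missing)}"
        )
    return df


def preprocess_cohort(
    manifest_path: str | Path,
    params: PreprocessingConfig | None = None,
) -> list[SampleSpectrum]:
    """Read a manifest of spectrum CSVs and run the full per-sample chain.

    Files are resolved relative to the manifest's directory; a missing file or
    a grid mismatch raises an error naming the offending manifest row.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent

    records: list[CohortRecord] = []
    grid: SpectralGrid | None = None
    for idx, row in df.iterrows():
        fpath = base / str(row["file"])
        if not fpath.is_file():
            raise PreprocessingError(
                f"manifest row {idx} (sample {row['sample_id']}, file {row['file']}): "
                f"file not found"
            )
        x, y = read_spectrum_csv(fpath)
        g = _grid_from_wavenumbers(x, str(fpath))
        if grid is None:
            grid = g
        elif g != grid:
            raise PreprocessingError(
                f"manifest row {idx} (file {row['file']}): grid {g} does not match "
                f"cohort grid {grid}"
            )
        records.append(
            CohortRecord(
                spectrum=RawSpectrum(grid=g, intensities=y, meta={"file": str(row["file"])}),
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                replicate=int(row["replicate"]),
            )
        )
    return preprocess_records(records, params)


def samples_to_frame(samples: Sequence[SampleSpectrum]) -> pd.DataFrame:
    """Processed sample matrix: sample_id, group, then one column per cm⁻¹."""
    if not samples:
        raise PreprocessingError("no samples to tabulate")
    grid = samples[0].spectrum.grid
    cols = [f"{w:g}" for w in grid.wavenumbers()]
    data = np.vstack([s.spectrum.intensities for s in samples])
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "group", [s.group for s in samples])
    df.insert(0, "sample_id", [s.sample_id for s in samples])
    return df


def frame_to_samples(df: pd.DataFrame) -> list[SampleSpectrum]:
    """Inverse of :func:`samples_to_frame`."""
    wavenumber_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    x = np.array([float(c) for c in wavenumber_cols])
    grid = _grid_from_wavenumbers(x, "sample matrix")
    out = []
    for _, row in df.iterrows():
        spec = ProcessedSpectrum(grid=grid, intensities=row[wavenumber_cols].to_numpy(dtype=float))
        out.append(SampleSpectrum(str(row["sample_id"]), str(row["group"]), spec, 1))
    return out
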