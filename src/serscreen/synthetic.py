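"""Seeded synthetic serum-SERS cohorts and probe spectra.

The generator emulates the acquisition design of a three-arm rat serum
study — a Sham (control) group, an ovariectomised (OVX, "disease") group and
an icariin-treated (ICA) group, 30 serum samples per group and 10 replicate
acquisitions per sample on a 400–1800 cm⁻¹ grid at 2 cm⁻¹ resolution.

Each raw acquisition is

    intensity(ν) = baseline(ν) + Σ_peaks Lorentzian(ν) + ε(ν)

where the baseline is a smooth positive polynomial standing in for serum
autofluorescence, each band is a Lorentzian at one of the 14 assigned serum
SERS positions, and ε is i.i.d. Gaussian detector noise.  Group membership
acts multiplicatively on band amplitudes through a
:class:`GroupEffectProfile`; sample- and replicate-level log-normal factors
add biological and acquisition variability.  One root seed plus per-(group,
sample, replicate) derived streams make any subset reproducible.

4-MBA probe spectra (bands at 1075 and 1583 cm⁻¹) are generated separately
for substrate-QC operations (RSD uniformity, enhancement factor,
concentration series).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .exceptions import SynthesisError

__all__ = [
    "SpectralGrid",
    "PeakTemplate",
    "GroupEffectProfile",
    "SyntheticCohortConfig",
    "RawSpectrum",
    "CohortRecord",
    "DEFAULT_PEAKS",
    "DEFAULT_EFFECTS",
    "EFFECT_BANDS_UP_IN_OVX",
    "EFFECT_BANDS_DOWN_IN_OVX",
    "default_config",
    "lorentzian",
    "generate_spectrum",
    "generate_cohort",
    "generate_latent_cohort",
    "generate_probe_series",
    "generate_probe_replicates",
    "write_cohort",
]

GROUPS = ("Sham", "OVX", "ICA")

#: Serum SERS band positions (cm⁻¹) with tentative assignments.
PEAK_ASSIGNMENTS: tuple[tuple[float, str], ...] = (
    (490.0, "Arginine: S-S stretching vibration"),
    (524.0, "Amino acid cysteine: S-S stretching mode"),
    (588.0, "Ascorbic acid, Amide VI"),
    (635.0, "Tyrosine: C-S stretching vibration"),
    (802.0, "Uracil-based ring breathing mode"),
    (883.0, "CH2, protein assignment"),
    (1004.0, "Phenylalanine: Ring breathing"),
    (1064.0, "Lipids: Skeletal C-C stretch"),
    (1127.0, "D-mannose: C-N stretching vibration"),
    (1197.0, "Tryptophan: ring vibration"),
    (1323.0, "Collagen: CH3CH2 wagging mode"),
    (1379.0, "Lipids: CH3 symmetric"),
    (1575.0, "DNA/RNA bases: Ring breathing modes"),
    (1647.0, "Collagen, Amide I: alpha-Helix"),
)

#: Band that rises in the OVX group relative to Sham (tyrosine).
EFFECT_BANDS_UP_IN_OVX: tuple[float, ...] = (635.0,)
#: Bands that fall in the OVX group relative to Sham.
EFFECT_BANDS_DOWN_IN_OVX: tuple[float, ...] = (
    490.0, 1064.0, 1197.0, 1323.0, 1379.0, 1647.0,
)


class SpectralGridError(SynthesisError):
    pass


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavenumber grid ``start + k*step``, inclusive of ``stop``."""

    start: float = 400.0
    stop: float = 1800.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if not (self.start < self.stop):
            raise SpectralGridError(f"grid start {self.start} must be < stop {self.stop}")
        if not (self.step > 0):
            raise SpectralGridError(f"grid step must be positive, got {self.step}")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def wavenumbers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points


@dataclass(frozen=True)
class PeakTemplate:
    """One Lorentzian band: apex ``amplitude`` at ``center``, HWHM ``width``."""

    center: float
    amplitude: float
    width: float = 6.0
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise SynthesisError(f"peak amplitude must be >= 0, got {self.amplitude}")
        if self.width <= 0:
            raise SynthesisError(f"peak width must be > 0, got {self.width}")


@dataclass(frozen=True)
class GroupEffectProfile:
    """Multiplicative band-amplitude effects for one study arm.

    ``multipliers`` maps peak center -> positive factor; absent centers are
    unchanged (factor 1).  The Sham profile is the all-ones reference.
    """

    group: str
    multipliers: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for center, m in self.multipliers.items():
            if m <= 0:
                raise SynthesisError(
                    f"group {self.group!r}: multiplier at {center} cm-1 must be > 0, got {m}"
                )

    def factor(self, center: float) -> float:
        return float(self.multipliers.get(center, 1.0))


# Default band heights (counts, before group/sample factors).  Chosen as a
# plausible serum-like profile: phenylalanine 1004 dominant, amide I strong.
_DEFAULT_AMPLITUDES: dict[float, float] = {
    490.0: 60.0, 524.0: 45.0, 588.0: 50.0, 635.0: 55.0, 802.0: 40.0,
    883.0: 50.0, 1004.0: 120.0, 1064.0: 70.0, 1127.0: 60.0, 1197.0: 45.0,
    1323.0: 65.0, 1379.0: 60.0, 1575.0: 70.0, 1647.0: 80.0,
}

DEFAULT_PEAKS: tuple[PeakTemplate, ...] = tuple(
    PeakTemplate(center=c, amplitude=_DEFAULT_AMPLITUDES[c], width=6.0, assignment=a)
    for c, a in PEAK_ASSIGNMENTS
)

# OVX: tyrosine up, arginine/lipids/tryptophan/collagen down; ICA strictly
# between Sham (1.0) and OVX at every affected band.
_OVX_MULT = {635.0: 1.35, 490.0: 0.70, 1064.0: 0.72, 1197.0: 0.70,
             1323.0: 0.75, 1379.0: 0.75, 1647.0: 0.70}
_ICA_MULT = {635.0: 1.15, 490.0: 0.85, 1064.0: 0.86, 1197.0: 0.85,
             1323.0: 0.88, 1379.0: 0.88, 1647.0: 0.87}

DEFAULT_EFFECTS: tuple[GroupEffectProfile, ...] = (
    GroupEffectProfile("Sham", {}),
    GroupEffectProfile("OVX", dict(_OVX_MULT)),
    GroupEffectProfile("ICA", dict(_ICA_MULT)),
)

# Degree-4 autofluorescence background, coefficients in the scaled coordinate
# xi = (nu - centre)/half_span in [-1, 1]; decreasing toward high wavenumber,
# positive everywhere, amplitude comparable to the band heights above.
DEFAULT_BASELINE_COEFFICIENTS: tuple[float, ...] = (700.0, -350.0, 120.0, -60.0, 40.0)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full description of one synthetic cohort.

    ``noise_sd`` is additive Gaussian detector noise per grid point (counts);
    ``sample_sd`` / ``replicate_sd`` are log-normal sigmas of the per-sample
    per-band and per-replicate overall intensity factors.
    """

    grid: SpectralGrid = SpectralGrid()
    peaks: tuple[PeakTemplate, ...] = DEFAULT_PEAKS
    effects: tuple[GroupEffectProfile, ...] = DEFAULT_EFFECTS
    n_samples_per_group: int = 30
    n_replicates: int = 10
    baseline_coefficients: tuple[float, ...] = DEFAULT_BASELINE_COEFFICIENTS
    noise_sd: float = 3.0
    sample_sd: float = 0.08
    replicate_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise SynthesisError("n_samples_per_group must be >= 2")
        if self.n_replicates < 1:
            raise SynthesisError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise SynthesisError("noise_sd must be >= 0")
        if self.sample_sd < 0 or self.replicate_sd < 0:
            raise SynthesisError("sample_sd and replicate_sd must be >= 0")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(e.group for e in self.effects)

    def effect_for(self, group: str) -> GroupEffectProfile:
        for e in self.effects:
            if e.group == group:
                return e
        raise SynthesisError(
            f"unknown group {group!r}; configured groups: {self.group_names}"
        )


@dataclass(frozen=True)
class RawSpectrum:
    """One acquisition: counts on a shared wavenumber grid."""

    grid: SpectralGrid
    intensities: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.shape != (self.grid.n_points,):
            raise SynthesisError(
                f"intensity vector length {arr.shape} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(arr)):
            raise SynthesisError("spectrum contains non-finite intensities")


@dataclass(frozen=True)
class CohortRecord:
    spectrum: RawSpectrum
    sample_id: str
    group: str
    replicate: int


def default_config(**overrides) -> SyntheticCohortConfig:
    """The study-condition cohort (3 × 30 × 10) with optional field overrides."""
    return replace(SyntheticCohortConfig(), **overrides) if overrides else SyntheticCohortConfig()


def lorentzian(x: np.ndarray, center: float, amplitude: float, hwhm: float) -> np.ndarray:
    """Lorentzian line with apex ``amplitude`` at ``center`` and HWHM ``hwhm``."""
    return amplitude * hwhm**2 / ((x - center) ** 2 + hwhm**2)


def evaluate_baseline(grid: SpectralGrid, coefficients: Sequence[float]) -> np.ndarray:
    """Polynomial background over ``grid``, coefficients in the scaled
    coordinate ``xi = (nu - mid)/half_span`` (low order first)."""
    x = grid.wavenumbers()
    mid = 0.5 * (grid.start + grid.stop)
    half = 0.5 * (grid.stop - grid.start)
    xi = (x - mid) / half
    return np.polynomial.polynomial.polyval(xi, np.asarray(coefficients, dtype=float))


def peak_signal(
    grid: SpectralGrid,
    peaks: Sequence[PeakTemplate],
    amplitude_factors: Sequence[float] | None = None,
) -> np.ndarray:
    """Noise- and baseline-free sum of Lorentzian bands.

    ``amplitude_factors`` multiplies each peak's amplitude in order; used by
    the preprocessing tests as the ground-truth (baseline-free) signal.
    """
    x = grid.wavenumbers()
    y = np.zeros_like(x)
    factors = np.ones(len(peaks)) if amplitude_factors is None else np.asarray(amplitude_factors, float)
    for pk, f in zip(peaks, factors):
        y += lorentzian(x, pk.center, pk.amplitude * f, pk.width)
    return y


def _sample_stream(config: SyntheticCohortConfig, group_index: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), group_index, sample_index])
    )

def _replicate_stream(
    config: SyntheticCohortConfig, group_index: int, sample_index: int, replicate_index: int
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), group_index, sample_index, replicate_index])
    )


def sample_band_factors(
    config: SyntheticCohortConfig, group: str, sample_index: int
) -> np.ndarray:
    """Per-band log-normal factors shared by all replicates of one sample."""
    gi = config.group_names.index(group)
    rng = _sample_stream(config, gi, sample_index)
    return np.exp(rng.normal(0.0, config.sample_sd, size=len(config.peaks)))


def generate_spectrum(
    config: SyntheticCohortConfig,
    group: str,
    sample_index: int,
    replicate_index: int,
) -> RawSpectrum:
    """One raw acquisition for (group, sample, replicate).

    Deterministic given ``(config.seed, group, sample_index,
    replicate_index)``; the per-sample band factors are shared across the
    sample's replicates, the overall replicate factor and the additive noise
    are drawn from the replicate's own stream.
    """
    effect = config.effect_for(group)  # raises on unknown group
    if not config.peaks:
        raise SynthesisError("peak template list is empty")
    if not (0 <= sample_index < config.n_samples_per_group):
        raise SynthesisError(
            f"sample_index {sample_index} outside configured 0..{config.n_samples_per_group - 1}"
        )
    if not (0 <= replicate_index < config.n_replicates):
        raise SynthesisError(
            f"replicate_index {replicate_index} outside configured 0..{config.n_replicates - 1}"
        )

    gi = config.group_names.index(group)
    band_factors = sample_band_factors(config, group, sample_index)
    rng = _replicate_stream(config, gi, sample_index, replicate_index)
    replicate_factor = float(np.exp(rng.normal(0.0, config.replicate_sd)))

    group_factors = np.array([effect.factor(pk.center) for pk in config.peaks])
    y = evaluate_baseline(config.grid, config.baseline_coefficients)
    y = y + peak_signal(config.grid, config.peaks, group_factors * band_factors * replicate_factor)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=config.grid.n_points)

    meta = {
        "group": group,
        "sample_index": sample_index,
        "replicate_index": replicate_index,
        "seed": config.seed,
    }
    return RawSpectrum(grid=config.grid, intensities=y, meta=meta)


def sample_id_for(group: str, sample_index: int) -> str:
    return f"{group}-{sample_index:02d}"


def generate_cohort(config: SyntheticCohortConfig) -> list[CohortRecord]:
    """All ``n_groups × n_samples_per_group × n_replicates`` acquisitions."""
    records: list[CohortRecord] = []
    for group in config.group_names:
        for s in range(config.n_samples_per_group):
            for r in range(config.n_replicates):
                records.append(
                    CohortRecord(
                        spectrum=generate_spectrum(config, group, s, r),
                        sample_id=sample_id_for(group, s),
                        group=group,
                        replicate=r,
                    )
                )
    return records


def iter_cohort(config: SyntheticCohortConfig) -> Iterator[CohortRecord]:
    yield from generate_cohort(config)


# ---------------------------------------------------------------------------
# Planted-latent-factor cohorts (component-selection fixtures)
# ---------------------------------------------------------------------------

# Regular-simplex class geometry: with 4 classes at tetrahedron vertices the
# between-class scatter is isotropic in the latent space, so every planted
# factor carries the same response variance.
_TETRAHEDRON = np.array(
    [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float
) / np.sqrt(3.0)


def generate_latent_cohort(
    seed: int,
    n_factors: int = 3,
    n_per_class: int = 15,
    n_features: int = 120,
    effect_scale: float = 3.5,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Processed-scale spectra with exactly ``n_factors`` planted group factors.

    ``n_factors + 1`` classes sit at the vertices of a regular simplex in an
    ``n_factors``-dimensional latent space, embedded into ``n_features``
    channels through a random orthonormal loading matrix; isotropic Gaussian
    noise of ``noise_sd`` is added per channel.  Because the class means span
    exactly ``n_factors`` dimensions with equal scatter per direction, a
    cross-validated prediction-error curve over latent components should show
    its elbow at ``n_factors``.  Returns (X, labels).
    """
    if n_factors < 1:
        raise SynthesisError("n_factors must be >= 1")
    if n_factors == 3:
        vertices = _TETRAHEDRON
    else:
        # regular simplex with centroid at origin: center the identity's
        # rows and keep the n_factors non-null principal directions
        E = np.eye(n_factors + 1) - 1.0 / (n_factors + 1)
        U, s, _ = np.linalg.svd(E)
        vertices = U[:, :n_factors] * s[:n_factors]
        vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7701]))
    loadings = np.linalg.qr(rng.normal(size=(n_features, n_factors)))[0]
    rows, labels = [], []
    for c in range(n_factors + 1):
        mu = effect_scale * (loadings @ vertices[c])
        rows.append(mu + noise_sd * rng.normal(size=(n_per_class, n_features)))
        labels.extend([f"G{c}"] * n_per_class)
    return np.vstack(rows), tuple(labels)


# ---------------------------------------------------------------------------
# 4-MBA probe spectra for substrate QC
# ---------------------------------------------------------------------------

#: 4-MBA characteristic aromatic-ring bands on a SERS substrate (cm⁻¹).
PROBE_BANDS: tuple[float, ...] = (1075.0, 1583.0)
_PROBE_RELATIVE_HEIGHT = {1075.0: 1.0, 1583.0: 0.85}


def probe_amplitude(concentration: float, slope: float = 30.0, floor_log10: float = -10.0) -> float:
    """Monotone response of the 1075 cm⁻¹ band to log10 concentration."""
    if concentration <= 0:
        raise SynthesisError(f"probe concentration must be > 0, got {concentration} M")
    return slope * (np.log10(concentration) - floor_log10)


def generate_probe_series(
    concentrations: Sequence[float],
    grid: SpectralGrid | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    width: float = 6.0,
    slope: float = 30.0,
) -> list[tuple[RawSpectrum, float]]:
    """4-MBA probe spectra at the given molar concentrations.

    Band amplitudes follow a monotone response to log-concentration; additive
    Gaussian noise with ``noise_sd`` emulates point-to-point acquisition
    scatter.  An empty concentration list yields an empty series.
    """
    grid = grid or SpectralGrid()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9001]))
    out: list[tuple[RawSpectrum, float]] = []
    x = grid.wavenumbers()
    for i, c in enumerate(concentrations):
        amp = probe_amplitude(c, slope=slope)  # raises on non-positive c
        y = np.zeros_like(x)
        for band in PROBE_BANDS:
            y += lorentzian(x, band, amp * _PROBE_RELATIVE_HEIGHT[band], width)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=x.size)
        meta = {"concentration_M": float(c), "series_index": i}
        out.append((RawSpectrum(grid=grid, intensities=y, meta=meta), float(c)))
    return out


def generate_probe_replicates(
    concentration: float,
    n_points: int,
    grid: SpectralGrid | None = None,
    seed: int = 0,
    noise_sd: float = 2.0,
    point_sd: float = 0.03,
) -> list[RawSpectrum]:
    """Repeated 4-MBA acquisitions at one concentration (uniformity scan).

    ``point_sd`` is the log-normal sigma of the point-to-point enhancement
    factor across the mapped substrate area; used for RSD uniformity QC.
    """
    if n_points < 1:
        raise SynthesisError("n_points must be >= 1")
    grid = grid or SpectralGrid()
    base = generate_probe_series([concentration], grid=grid, seed=seed, noise_sd=0.0)[0][0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9002]))
    out = []
    for i in range(n_points):
        factor = float(np.exp(rng.normal(0.0, point_sd)))
        y = base.intensities * factor
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.size)
        out.append(RawSpectrum(grid=grid, intensities=y, meta={"point": i}))
    return out


# ---------------------------------------------------------------------------
# File export (two-column CSV spectra + manifest)
# ---------------------------------------------------------------------------

def write_spectrum_csv(path: Path, spectrum: RawSpectrum, header: bool = True) -> None:
    x = spectrum.grid.wavenumbers()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow(["wavenumber", "intensity"])
        for xi, yi in zip(x, spectrum.intensities):
            w.writerow([f"{xi:.1f}", f"{yi:.6f}"])


def write_cohort(records: Sequence[CohortRecord], outdir: str | Path) -> Path:
    """Write one CSV per spectrum plus ``manifest.csv``; returns manifest path.

    Manifest columns: file, sample_id, group, replicate.
    """
    outdir = Path(outdir)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["file", "sample_id", "group", "replicate"])
        for rec in records:
            fname = f"spectra/{rec.sample_id}-r{rec.replicate:02d}.csv"
            write_spectrum_csv(outdir / fname, rec.spectrum)
            w.writerow([fname, rec.sample_id, rec.group, rec.replicate])
    return manifest_path
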