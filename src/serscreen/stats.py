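"""Peak-level statistics of processed SERS cohorts.

Covers band-intensity extraction against the 14-row serum assignment table,
group mean/SD and difference spectra, the three-branch group-comparison
decision tree (Shapiro–Wilk normality → Levene homogeneity → one-way ANOVA /
Welch ANOVA / Kruskal–Wallis) and the substrate-uniformity QC statistics
(relative standard deviation, enhancement factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import StatisticsError
from .preprocess import ProcessedSpectrum, SampleSpectrum
from .synthetic import PEAK_ASSIGNMENTS, SpectralGrid

__all__ = [
    "PeakAssignmentTable",
    "PeakIntensityMatrix",
    "GroupComparisonResult",
    "DifferenceSpectrum",
    "GroupMeanSpectra",
    "UniformityReport",
    "default_peak_table",
    "extract_peak_intensity",
    "build_peak_matrix",
    "mean_and_difference_spectra",
    "compare_groups",
    "compare_peak_matrix",
    "relative_standard_deviation",
    "uniformity_report",
    "enhancement_factor",
]


@dataclass(frozen=True)
class PeakAssignmentTable:
    """Band positions (cm⁻¹), assignments and extraction half-windows."""

    positions: tuple[float, ...]
    assignments: tuple[str, ...]
    window_halfwidth: float = 5.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        if len(self.positions) != len(self.assignments):
            raise StatisticsError("positions and assignments differ in length")
        if pos.size == 0:
            raise StatisticsError("peak table is empty")
        if not np.all(np.diff(pos) > 0):
            raise StatisticsError("peak positions must be unique and strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


def default_peak_table(window_halfwidth: float = 5.0) -> PeakAssignmentTable:
    """The 14 assigned serum SERS bands."""
    return PeakAssignmentTable(
        positions=tuple(p for p, _ in PEAK_ASSIGNMENTS),
        assignments=tuple(a for _, a in PEAK_ASSIGNMENTS),
        window_halfwidth=window_halfwidth,
    )


def extract_peak_intensity(
    spectrum: ProcessedSpectrum,
    position: float,
    window_halfwidth: float = 5.0,
) -> float:
    """Maximum intensity within ``position ± window_halfwidth``.

    The in-window maximum is robust to small calibration shifts; ties break
    toward the lowest wavenumber.
    """
    x = spectrum.grid.wavenumbers()
    mask = (x >= position - window_halfwidth) & (x <= position + window_halfwidth)
    if not mask.any():
        raise StatisticsError(
            f"window {position}±{window_halfwidth} cm-1 does not intersect the grid "
            f"[{spectrum.grid.start}, {spectrum.grid.stop}]"
        )
    values = spectrum.intensities[mask]
    return float(values[int(np.argmax(values))])


@dataclass(frozen=True)
class PeakIntensityMatrix:
    """Samples × peaks matrix of extracted normalized intensities."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    positions: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{p:g}" for p in self.positions])
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def column(self, position: float) -> np.ndarray:
        try:
            j = self.positions.index(position)
        except ValueError:
            raise StatisticsError(f"no peak at {position} cm-1 in the matrix") from None
        return self.values[:, j]

    def by_group(self, position: float) -> dict[str, np.ndarray]:
        col = self.column(position)
        out: dict[str, np.ndarray] = {}
        for g in dict.fromkeys(self.groups):
            out[g] = col[np.array([gi == g for gi in self.groups])]
        return out


def build_peak_matrix(
    samples: Sequence[SampleSpectrum],
    table: PeakAssignmentTable | None = None,
) -> PeakIntensityMatrix:
    """Extract every (sample, band) intensity; rows follow input order."""
    if not samples:
        raise StatisticsError("no samples supplied")
    table = table or default_peak_table()
    values = np.empty((len(samples), len(table)))
    for i, s in enumerate(samples):
        for j, pos in enumerate(table.positions):
            values[i, j] = extract_peak_intensity(s.spectrum, pos, table.window_halfwidth)
    return PeakIntensityMatrix(
        values=values,
        sample_ids=tuple(s.sample_id for s in samples),
        groups=tuple(s.group for s in samples),
        positions=tuple(table.positions),
    )


@dataclass(frozen=True)
class GroupMeanSpectra:
    """Pointwise group means and standard deviations."""

    grid: SpectralGrid
    means: Mapping[str, np.ndarray]
    sds: Mapping[str, np.ndarray]
    counts: Mapping[str, int]


@dataclass(frozen=True)
class DifferenceSpectrum:
    """mean(group_a) − mean(group_b); antisymmetric under swapping labels."""

    grid: SpectralGrid
    difference: np.ndarray
    group_a: str
    group_b: str


def mean_and_difference_spectra(
    samples: Sequence[SampleSpectrum],
    group_a: str,
    group_b: str,
) -> tuple[GroupMeanSpectra, DifferenceSpectrum]:
    """Group mean ± SD spectra and the mean(a) − mean(b) difference."""
    groups: dict[str, list[np.ndarray]] = {}
    grid = samples[0].spectrum.grid if samples else None
    for s in samples:
        groups.setdefault(s.group, []).append(s.spectrum.intensities)
    for g in (group_a, group_b):
        if g not in groups:
            raise StatisticsError(
                f"unknown group {g!r}; present: {sorted(groups)}"
            )
        if len(groups[g]) < 2:
            raise StatisticsError(f"group {g!r} has fewer than 2 samples")
    means = {g: np.mean(v, axis=0) for g, v in groups.items()}
    sds = {g: np.std(v, axis=0, ddof=1) for g, v in groups.items()}
    counts = {g: len(v) for g, v in groups.items()}
    diff = DifferenceSpectrum(
        grid=grid,
        difference=means[group_a] - means[group_b],
        group_a=group_a,
        group_b=group_b,
    )
    return GroupMeanSpectra(grid=grid, means=means, sds=sds, counts=counts), diff


@dataclass(frozen=True)
class GroupComparisonResult:
    """Routed multi-group comparison for one band."""

    position: float
    group_n: Mapping[str, int]
    group_mean: Mapping[str, float]
    group_sd: Mapping[str, float]
    normality_p: Mapping[str, float]
    variance_homogeneity_p: float | None
    test_used: str
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_groups(
    values: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    position: float = float("nan"),
    levene_center: str = "mean",
) -> GroupComparisonResult:
    """Route a multi-group comparison through the assumption decision tree.

    Shapiro–Wilk per group at ``alpha``; if all groups look normal, Levene's
    test (classic mean-centered variant by default) decides between one-way
    ANOVA (homogeneous variances) and Welch's ANOVA (heterogeneous); any
    non-normal group routes to Kruskal–Wallis.
    """
    if len(values) < 2:
        raise StatisticsError("need at least 2 groups to compare")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, arr in arrays.items():
        if arr.size < 3:
            raise StatisticsError(
                f"group {g!r} has {arr.size} values; normality testing needs >= 3"
            )

    normality_p = {g: float(sps.shapiro(arr).pvalue) for g, arr in arrays.items()}
    all_normal = all(p >= alpha for p in normality_p.values())

    groups = list(arrays.values())
    homogeneity_p: float | None = None
    if all_normal:
        homogeneity_p = float(sps.levene(*groups, center=levene_center).pvalue)
        if homogeneity_p >= alpha:
            test_used = "one-way ANOVA"
            p = float(sps.f_oneway(*groups).pvalue)
        else:
            test_used = "Welch ANOVA"
            p = float(sps.f_oneway(*groups, equal_var=False).pvalue)
    else:
        test_used = "Kruskal-Wallis"
        p = float(sps.kruskal(*groups).pvalue)

    return GroupComparisonResult(
        position=position,
        group_n={g: int(a.size) for g, a in arrays.items()},
        group_mean={g: float(a.mean()) for g, a in arrays.items()},
        group_sd={g: float(a.std(ddof=1)) for g, a in arrays.items()},
        normality_p=normality_p,
        variance_homogeneity_p=homogeneity_p,
        test_used=test_used,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def compare_peak_matrix(
    matrix: PeakIntensityMatrix,
    alpha: float = 0.05,
    adjust: str | None = None,
    levene_center: str = "mean",
) -> pd.DataFrame:
    """Run :func:`compare_groups` for every band of a peak matrix.

    ``adjust="bh"`` adds Benjamini–Hochberg adjusted p-values across bands
    (off by default); ``significant`` then refers to the adjusted values.
    """
    rows = []
    results = []
    for pos in matrix.positions:
        res = compare_groups(matrix.by_group(pos), alpha=alpha, position=pos,
                             levene_center=levene_center)
        results.append(res)
        row: dict[str, object] = {
            "position": pos,
            "test_used": res.test_used,
            "p_value": res.p_value,
            "significant": res.significant,
            "variance_homogeneity_p": res.variance_homogeneity_p,
        }
        for g in res.group_n:
            row[f"n_{g}"] = res.group_n[g]
            row[f"mean_{g}"] = res.group_mean[g]
            row[f"sd_{g}"] = res.group_sd[g]
            row[f"shapiro_p_{g}"] = res.normality_p[g]
        rows.append(row)
    df = pd.DataFrame(rows)
    if adjust is not None:
        if adjust.lower() not in ("bh", "fdr_bh"):
            raise StatisticsError(f"unknown p-value adjustment {adjust!r}")
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
        df["p_adjusted"] = p_adj
        df["significant"] = reject
    return df


@dataclass(frozen=True)
class UniformityReport:
    """Point-to-point intensity spread of one band (substrate QC)."""

    position: float
    intensities: tuple[float, ...]
    mean: float
    sd: float
    rsd_percent: float


def relative_standard_deviation(intensities: Sequence[float]) -> float:
    """100 × sample SD (n−1 denominator) / mean, in percent."""
    arr = np.asarray(intensities, dtype=float)
    if arr.size < 2:
        raise StatisticsError("RSD needs at least 2 values")
    mean = float(arr.mean())
    if mean <= 0:
        raise StatisticsError(f"RSD undefined for non-positive mean {mean:g}")
    return 100.0 * float(arr.std(ddof=1)) / mean


def uniformity_report(position: float, intensities: Sequence[float]) -> UniformityReport:
    rsd = relative_standard_deviation(intensities)
    arr = np.asarray(intensities, dtype=float)
    return UniformityReport(
        position=position,
        intensities=tuple(float(v) for v in arr),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        rsd_percent=rsd,
    )


def enhancement_factor(i_sers: float, c_sers: float, i_ref: float, c_ref: float) -> float:
    """Concentration-normalized intensity ratio (I_sers/c_sers)/(I_ref/c_ref)."""
    for name, v in (("i_sers", i_sers), ("c_sers", c_sers), ("i_ref", i_ref), ("c_ref", c_ref)):
        if v <= 0:
            raise StatisticsError(f"enhancement factor requires {name} > 0, got {v:g}")
    return (i_sers / c_sers) / (i_ref / c_ref)
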