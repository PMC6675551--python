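"""Heavy/light parallel-reaction-monitoring validation of neoepitopes.

A candidate ("light") peptide identified in the immunopeptidome is
validated by spiking in a synthetic counterpart carrying a stable-isotope
label ("heavy"), targeting both by PRM, and requiring the heavy and light
fragment-ion chromatograms to co-elute. This module does the mass
accounting for the label, computes b/y fragment m/z (monoisotopic, with the
heavy delta applied only to fragments spanning the labeled residue),
extracts ion chromatograms at a fixed m/z tolerance, and scores co-elution
by per-fragment Pearson correlation, apex alignment and spectral contrast.
A heavy-only quality-control run guards against residual light-peptide
contamination in the synthetic standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass

PROTON_MASS = 1.007276
WATER_MASS = 18.010565

#: monoisotopic residue masses (pyteomics standard amino-acid table)
RESIDUE_MASS: Mapping[str, float] = dict(_pt_mass.std_aa_mass)

# mass differences of the heavy isotopes used in SIL peptide synthesis
_D13C = 13.00335484 - 12.0
_D15N = 15.00010890 - 14.00307401


def _label_delta(n_c: int, n_n: int) -> float:
    return n_c * _D13C + n_n * _D15N


@dataclass(frozen=True)
class IsotopeLabel:
    """A stable-isotope-labeled residue and its monoisotopic mass delta."""

    residue: str
    mass_delta: float

    def __post_init__(self) -> None:
        if self.mass_delta <= 0:
            raise ValueError("label mass delta must be positive")


#: shipped full 13C/15N labels for the residues commonly used in
#: SIL peptide synthesis
STANDARD_LABELS: Mapping[str, IsotopeLabel] = {
    "K": IsotopeLabel("K", _label_delta(6, 2)),
    "R": IsotopeLabel("R", _label_delta(6, 4)),
    "L": IsotopeLabel("L", _label_delta(6, 1)),
    "P": IsotopeLabel("P", _label_delta(5, 1)),
    "V": IsotopeLabel("V", _label_delta(5, 1)),
    "F": IsotopeLabel("F", _label_delta(9, 1)),
}

DEFAULT_XIC_TOL = 0.02  # m/z window half-width for XIC extraction
DEFAULT_MIN_FRAGMENTS = 3
DEFAULT_R_MIN = 0.9
DEFAULT_MAX_APEX_DT = 0.2  # minutes
DEFAULT_CONTRAST_MIN = 0.9
DEFAULT_CONTAMINATION = 0.01  # light signal allowed, as fraction of heavy apex
DEFAULT_CHARGES = (1, 2)


class NoLabelSiteError(ValueError):
    """The labeled residue does not occur in the peptide."""


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int
    charge: int
    mz: float
    contains_label: bool = False

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError("series must be 'b' or 'y'")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")

    @property
    def name(self) -> str:
        return f"{self.series}{self.index}+{self.charge}"


@dataclass(frozen=True)
class ChromatogramTrace:
    """Intensity vs retention time for one fragment in one channel."""

    times: np.ndarray
    intensities: np.ndarray
    fragment: FragmentIon | None = None
    channel: str = "light"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        if times.shape != intens.shape:
            raise ValueError("times and intensities must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(intens < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)

    @property
    def apex_time(self) -> float:
        return float(self.times[int(np.argmax(self.intensities))])

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities.max(initial=0.0))


@dataclass(frozen=True)
class CoelutionReport:
    fragment_correlations: Mapping[str, float]
    apex_dt: float
    spectral_contrast: float
    n_qualifying: int
    verdict: str  # 'validated' | 'not_validated'
    excluded_fragments: tuple[str, ...] = ()


def heavy_mass_shift(peptide: str, label: IsotopeLabel) -> float:
    """Total heavy-label mass delta: occurrence count x per-residue delta."""
    count = peptide.count(label.residue)
    if count == 0:
        raise NoLabelSiteError(
            f"labeled residue {label.residue} absent from {peptide}"
        )
    return count * label.mass_delta


def fragment_mz(
    peptide: str,
    series: str,
    index: int,
    charge: int,
    label: IsotopeLabel | None = None,
) -> float:
    """Monoisotopic m/z of a b- or y-ion.

    b_i covers residues 1..i (residue-mass sum + charge protons); y_i covers
    the last i residues (+ H2O). The heavy delta is added only when the
    fragment's span contains the labeled residue.
    """
    n = len(peptide)
    if not 1 <= index <= n - 1:
        raise IndexError(f"fragment index {index} out of range for {n}-mer")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if series == "b":
        span = peptide[:index]
        neutral = sum(RESIDUE_MASS[a] for a in span)
    elif series == "y":
        span = peptide[n - index:]
        neutral = sum(RESIDUE_MASS[a] for a in span) + WATER_MASS
    else:
        raise ValueError("series must be 'b' or 'y'")
    if label is not None and label.residue in span:
        neutral += span.count(label.residue) * label.mass_delta
    return (neutral + charge * PROTON_MASS) / charge


def precursor_mz(
    peptide: str, charge: int, label: IsotopeLabel | None = None
) -> float:
    neutral = sum(RESIDUE_MASS[a] for a in peptide) + WATER_MASS
    if label is not None and label.residue in peptide:
        neutral += peptide.count(label.residue) * label.mass_delta
    return (neutral + charge * PROTON_MASS) / charge


def enumerate_fragments(
    peptide: str,
    label: IsotopeLabel | None = None,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> list[FragmentIon]:
    """All b/y fragments of the peptide at the requested charges."""
    n = len(peptide)
    out = []
    for series in ("b", "y"):
        for index in range(1, n):
            span = peptide[:index] if series == "b" else peptide[n - index:]
            contains = label is not None and label.residue in span
            for charge in charges:
                out.append(
                    FragmentIon(
                        series=series,
                        index=index,
                        charge=charge,
                        mz=fragment_mz(peptide, series, index, charge, label),
                        contains_label=contains,
                    )
                )
    return out


def extract_xic(
    signals: pd.DataFrame,
    target_mz: float,
    tol: float = DEFAULT_XIC_TOL,
    fragment: FragmentIon | None = None,
    channel: str = "light",
) -> ChromatogramTrace:
    """Extracted ion chromatogram from a centroided signal table.

    ``signals`` has columns mz, time, intensity; intensities of all signals
    within [target_mz - tol, target_mz + tol] are summed per time point. An
    empty window yields an empty trace.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    window = signals[(signals["mz"] - target_mz).abs() <= tol]
    grouped = window.groupby("time", sort=True)["intensity"].sum()
    return ChromatogramTrace(
        times=grouped.index.to_numpy(dtype=float),
        intensities=grouped.to_numpy(dtype=float),
        fragment=fragment,
        channel=channel,
    )


def _union_grid_correlation(
    light: ChromatogramTrace, heavy: ChromatogramTrace
) -> float | None:
    """Pearson r after linear interpolation onto the union time grid.

    Returns None when either trace is degenerate (all-zero or constant).
    """
    grid = np.union1d(light.times, heavy.times)
    if grid.size < 2:
        return None
    a = np.interp(grid, light.times, light.intensities, left=0.0, right=0.0)
    b = np.interp(grid, heavy.times, heavy.intensities, left=0.0, right=0.0)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return None
    return float(np.corrcoef(a, b)[0, 1])


def coelution_score(
    light: Mapping[str, ChromatogramTrace],
    heavy: Mapping[str, ChromatogramTrace],
    min_fragments: int = DEFAULT_MIN_FRAGMENTS,
    r_min: float = DEFAULT_R_MIN,
    max_apex_dt: float = DEFAULT_MAX_APEX_DT,
    contrast_min: float = DEFAULT_CONTRAST_MIN,
) -> CoelutionReport:
    """Score heavy/light co-elution over the shared fragments.

    validated iff >= min_fragments fragments correlate at r >= r_min, the
    summed-trace apexes align within max_apex_dt minutes, and the spectral
    contrast (normalized dot product of the fragment intensity vectors at
    the respective apexes) reaches contrast_min. Degenerate (flat) traces
    are excluded from correlation with a record in the report.
    """
    shared = sorted(set(light) & set(heavy))
    if not shared:
        raise ValueError("no shared fragments between channels")

    correlations: dict[str, float] = {}
    excluded: list[str] = []
    for key in shared:
        r = _union_grid_correlation(light[key], heavy[key])
        if r is None:
            excluded.append(key)
        else:
            correlations[key] = r

    apex_light = _summed_apex(light, shared)
    apex_heavy = _summed_apex(heavy, shared)
    if apex_light is None or apex_heavy is None:
        apex_dt = np.inf
    else:
        apex_dt = abs(apex_light - apex_heavy)

    light_vec = np.array(
        [_intensity_at(light[k], apex_light) for k in shared]
    )
    heavy_vec = np.array(
        [_intensity_at(heavy[k], apex_heavy) for k in shared]
    )
    contrast = _normalized_dot(light_vec, heavy_vec)

    n_qualifying = sum(1 for r in correlations.values() if r >= r_min)
    validated = (
        n_qualifying >= min_fragments
        and apex_dt <= max_apex_dt
        and contrast >= contrast_min
    )
    return CoelutionReport(
        fragment_correlations=correlations,
        apex_dt=float(apex_dt),
        spectral_contrast=contrast,
        n_qualifying=n_qualifying,
        verdict="validated" if validated else "not_validated",
        excluded_fragments=tuple(excluded),
    )


def _summed_apex(
    traces: Mapping[str, ChromatogramTrace], keys: Sequence[str]
) -> float | None:
    grid = np.union1d(
        np.concatenate([traces[k].times for k in keys]), np.array([])
    )
    if grid.size == 0:
        return None
    total = np.zeros_like(grid)
    for k in keys:
        t = traces[k]
        total += np.interp(grid, t.times, t.intensities, left=0.0, right=0.0)
    if total.max(initial=0.0) <= 0:
        return None
    return float(grid[int(np.argmax(total))])


def _intensity_at(trace: ChromatogramTrace, time: float | None) -> float:
    if time is None or trace.times.size == 0:
        return 0.0
    return float(
        np.interp(time, trace.times, trace.intensities, left=0.0, right=0.0)
    )


def _normalized_dot(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def check_light_contamination(
    light_traces: Mapping[str, ChromatogramTrace],
    heavy_traces: Mapping[str, ChromatogramTrace],
    threshold: float = DEFAULT_CONTAMINATION,
) -> bool:
    """QC on a heavy-only run: pass iff the strongest signal at any light
    m/z stays at or below ``threshold`` x the heavy apex intensity."""
    heavy_apex = max(
        (t.apex_intensity for t in heavy_traces.values()), default=0.0
    )
    light_max = max(
        (t.apex_intensity for t in light_traces.values()), default=0.0
    )
    if heavy_apex == 0:
        return light_max == 0
    return light_max <= threshold * heavy_apex


# ---------------------------------------------------------------------------
# Long-format trace I/O

TRACE_COLUMNS = ["fragment", "channel", "time", "intensity"]


def read_traces(
    path: str | Path,
) -> dict[str, dict[str, ChromatogramTrace]]:
    """Load long-format traces (fragment, channel, time, intensity) into
    {channel: {fragment: trace}}."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    out: dict[str, dict[str, ChromatogramTrace]] = {}
    for (channel, fragment), grp in df.groupby(["channel", "fragment"]):
        grp = grp.sort_values("time")
        out.setdefault(str(channel), {})[str(fragment)] = ChromatogramTrace(
            times=grp["time"].to_numpy(dtype=float),
            intensities=grp["intensity"].to_numpy(dtype=float),
            channel=str(channel),
        )
    return out


def write_traces(
    traces: Mapping[str, Mapping[str, ChromatogramTrace]], path: str | Path
) -> None:
    rows = []
    for channel, frags in traces.items():
        for fragment, trace in frags.items():
            for t, i in zip(trace.times, trace.intensities):
                rows.append(
                    {
                        "fragment": fragment,
                        "channel": channel,
                        "time": t,
                        "intensity": i,
                    }
                )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
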