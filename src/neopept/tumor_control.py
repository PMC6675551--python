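"""Tumor Control Index (TCI) scoring of growth curves and group statistics.

Each mouse contributes a diameter-vs-day growth curve (average of two
perpendicular measurements, mm). The TCI integrates three aspects of tumor
control, each on a 0-10 scale, for a maximum total of 30:

* rejection - 10 when the tumor is undetectable (below the detection
  floor) at the final observation and has stayed undetectable since the
  first undetectable day (a durable complete response), else 0;
* inhibition - 10 x clamp(1 - AUC(curve) / AUC(control mean), 0, 1), where
  AUC is the trapezoidal area of diameter over days;
* stability - 10 x the fraction of observation days on which the diameter
  sits within +/-20% of the diameter on the first day a measurable tumor
  appeared, or is undetectable.

The exact component formulas behind the published index are not printed in
the primary literature; this parameterization is this package's documented
convention (see docs/methods.md), constrained by the 0-30 bound and the
monotonicity of each component. Group comparisons follow the conventional
design: one-way ANOVA with Dunnett's test against the control group for
TCI totals and Tukey's all-pairs test for AUCs; two-sample comparisons use
a two-tailed t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DETECTION_FLOOR_MM = 1.0  # diameters below this count as "no palpable tumor"
STABILITY_BAND = 0.20  # +/- fraction around the first measurable diameter
COMPONENT_MAX = 10.0


class DegenerateVarianceError(ValueError):
    """All observations identical; the test statistic is undefined."""


@dataclass(frozen=True)
class GrowthCurve:
    """Diameter series for one mouse; day 0 is the tumor-challenge day."""

    mouse_id: str
    group: str
    days: np.ndarray
    diameters: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        diam = np.asarray(self.diameters, dtype=float)
        if days.shape != diam.shape:
            raise ValueError("days and diameters must have equal length")
        if days.size > 1 and not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any(diam < 0):
            raise ValueError("diameters must be non-negative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "diameters", diam)


@dataclass(frozen=True)
class TCIScore:
    rejection: float
    inhibition: float
    stability: float

    def __post_init__(self) -> None:
        for name in ("rejection", "inhibition", "stability"):
            v = getattr(self, name)
            if not 0 <= v <= COMPONENT_MAX:
                raise ValueError(f"{name} component outside [0, 10]: {v}")

    @property
    def total(self) -> float:
        return self.rejection + self.inhibition + self.stability


def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under diameter vs day (mm x day)."""
    if curve.days.size < 2:
        raise ValueError("AUC needs at least 2 time points")
    return float(np.trapezoid(curve.diameters, curve.days))


def mean_curve(curves: Sequence[GrowthCurve], group: str = "") -> GrowthCurve:
    """Pointwise mean of a group of curves on the union day grid (linear
    interpolation within each mouse's observed span)."""
    if not curves:
        raise ValueError("empty group")
    grid = np.unique(np.concatenate([c.days for c in curves]))
    stacked = np.vstack(
        [np.interp(grid, c.days, c.diameters) for c in curves]
    )
    return GrowthCurve(
        mouse_id="<mean>",
        group=group or curves[0].group,
        days=grid,
        diameters=stacked.mean(axis=0),
    )


def _interp_to(curve: GrowthCurve, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, curve.days, curve.diameters)


def tci_components(
    curve: GrowthCurve,
    control_mean: GrowthCurve,
    detection_floor: float = DETECTION_FLOOR_MM,
    stability_band: float = STABILITY_BAND,
) -> TCIScore:
    """Decompose one mouse's curve into rejection/inhibition/stability.

    The curve is linearly interpolated to the control's day grid before the
    AUC comparison. Mice observed over a truncated span contribute only
    over their observed days.
    """
    grid = control_mean.days
    diam = _interp_to(curve, grid)
    control = control_mean.diameters
    detectable = diam >= detection_floor

    # rejection: undetectable at the end, durably so
    if not detectable[-1]:
        undetectable_idx = np.flatnonzero(~detectable)
        first_clear = undetectable_idx[0]
        durable = not detectable[first_clear:].any()
        rejection = COMPONENT_MAX if durable else 0.0
    else:
        rejection = 0.0

    # inhibition: AUC ratio vs control
    control_auc = float(np.trapezoid(control, grid))
    if control_auc <= 0:
        raise ValueError("control group AUC is zero")
    curve_auc = float(np.trapezoid(diam, grid))
    inhibition = COMPONENT_MAX * float(
        np.clip(1.0 - curve_auc / control_auc, 0.0, 1.0)
    )

    # stability: fraction of days near the first measurable diameter,
    # undetectable days counting as stable
    if detectable.any():
        baseline = diam[np.flatnonzero(detectable)[0]]
        in_band = np.abs(diam - baseline) <= stability_band * baseline
        stable = in_band | ~detectable
    else:
        stable = np.ones_like(diam, dtype=bool)
    stability = COMPONENT_MAX * float(stable.mean())

    return TCIScore(
        rejection=rejection, inhibition=inhibition, stability=stability
    )


def group_tci(
    curves_by_group: Mapping[str, Sequence[GrowthCurve]],
    control_group: str,
    detection_floor: float = DETECTION_FLOOR_MM,
    stability_band: float = STABILITY_BAND,
) -> dict[str, float]:
    """Arithmetic mean of per-mouse TCI totals for each group, scored
    against the control group's mean curve."""
    control_curves = curves_by_group.get(control_group)
    if not control_curves:
        raise ValueError(f"control group {control_group!r} is empty")
    control = mean_curve(list(control_curves), group=control_group)
    return {
        group: float(
            np.mean(
                [
                    tci_components(
                        c, control, detection_floor, stability_band
                    ).total
                    for c in curves
                ]
            )
        )
        for group, curves in curves_by_group.items()
    }


def per_mouse_tci(
    curves_by_group: Mapping[str, Sequence[GrowthCurve]],
    control_group: str,
    **kwargs,
) -> dict[str, list[TCIScore]]:
    control = mean_curve(
        list(curves_by_group[control_group]), group=control_group
    )
    return {
        group: [tci_components(c, control, **kwargs) for c in curves]
        for group, curves in curves_by_group.items()
    }


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    control_group: str | None = None,
    method: str = "dunnett",
) -> pd.DataFrame:
    """One-way ANOVA followed by a multiple-comparison test.

    method='dunnett' compares each treatment against ``control_group``
    (used for TCI totals); method='tukey' runs all pairwise comparisons
    (used for AUCs). Adjusted p-values are reported.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(list(groups.values()))
    if np.allclose(pooled, pooled[0]):
        raise DegenerateVarianceError("all observations identical")

    anova = stats.f_oneway(*groups.values())
    rows = []
    if method == "dunnett":
        if control_group is None or control_group not in groups:
            raise ValueError("dunnett requires a control group")
        treatments = [g for g in groups if g != control_group]
        res = stats.dunnett(
            *(groups[g] for g in treatments), control=groups[control_group]
        )
        for g, p in zip(treatments, np.atleast_1d(res.pvalue)):
            rows.append(
                {
                    "comparison": f"{g} vs {control_group}",
                    "p_adjusted": float(p),
                }
            )
    elif method == "tukey":
        names = list(groups)
        res = stats.tukey_hsd(*(groups[g] for g in names))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "comparison": f"{names[i]} vs {names[j]}",
                        "p_adjusted": float(res.pvalue[i, j]),
                    }
                )
    else:
        raise ValueError("method must be 'dunnett' or 'tukey'")

    df = pd.DataFrame(rows, columns=["comparison", "p_adjusted"])
    df.attrs["anova_F"] = float(anova.statistic)
    df.attrs["anova_p"] = float(anova.pvalue)
    return df


def ttest_two_tailed(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Standard two-sample two-tailed t-test p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.allclose(np.concatenate([a, b]), a[0]):
        raise DegenerateVarianceError("zero pooled variance")
    return float(stats.ttest_ind(a, b).pvalue)


# ---------------------------------------------------------------------------
# Growth CSV I/O

GROWTH_COLUMNS = ["mouse_id", "group", "day", "diameter_mm"]


def read_growth_csv(path: str | Path) -> dict[str, list[GrowthCurve]]:
    """Load per-mouse growth curves grouped by treatment group."""
    df = pd.read_csv(path)
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    out: dict[str, list[GrowthCurve]] = {}
    for (group, mouse), grp in df.groupby(["group", "mouse_id"], sort=True):
        grp = grp.sort_values("day")
        out.setdefault(str(group), []).append(
            GrowthCurve(
                mouse_id=str(mouse),
                group=str(group),
                days=grp["day"].to_numpy(dtype=float),
                diameters=grp["diameter_mm"].to_numpy(dtype=float),
            )
        )
    return out


def write_growth_csv(
    curves_by_group: Mapping[str, Sequence[GrowthCurve]], path: str | Path
) -> None:
    rows = []
    for group, curves in curves_by_group.items():
        for c in curves:
            for d, v in zip(c.days, c.diameters):
                rows.append(
                    {
                        "mouse_id": c.mouse_id,
                        "group": group,
                        "day": d,
                        "diameter_mm": v,
                    }
                )
    pd.DataFrame(rows, columns=GROWTH_COLUMNS).to_csv(path, index=False)
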