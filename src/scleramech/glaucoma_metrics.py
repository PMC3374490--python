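"""Quantification metrics for experimental (microbead) glaucoma.

Sampled axon-count estimation, percent axon loss against a pooled
fellow-eye mean, positive integral IOP (cumulative pressure exposure,
mmHg*days), retinal ganglion cell body summaries, ocular morphometry
percent changes, and the displacement-tracking error budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import math

import numpy as np
import pandas as pd

__all__ = [
    "IOPSeries",
    "AxonSample",
    "MorphometryRecord",
    "estimate_axon_count",
    "percent_axon_loss",
    "positive_integral_iop",
    "percent_dimension_change",
    "rgc_body_summary",
    "error_budget",
    "round_half_away",
]


@dataclass(frozen=True)
class IOPSeries:
    """Intraocular pressure measurements for one eye over a study.

    ``arm`` is "treated" (bead injected) or "fellow" (contralateral
    control); days are counted from injection.
    """

    eye_id: str
    arm: str
    days: np.ndarray
    iop: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        iop = np.asarray(self.iop, dtype=float)
        if days.shape != iop.shape or days.ndim != 1:
            raise ValueError("days and iop must be 1-D arrays of equal length")
        if days.size and (np.any(np.diff(days) <= 0) or days[0] < 0):
            raise ValueError("days must be ascending and start at >= 0")
        if np.any(iop <= 0):
            raise ValueError("IOP values must be positive")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "iop", iop)


@dataclass(frozen=True)
class AxonSample:
    """Optic-nerve axon sampling: nerve cross-section area plus the axon
    densities measured on a few randomly placed high-power fields."""

    nerve_id: str
    nerve_area: float  # mm^2
    field_densities: np.ndarray  # axons / mm^2 per sampled image

    def __post_init__(self):
        dens = np.asarray(self.field_densities, dtype=float)
        if self.nerve_area <= 0:
            raise ValueError("nerve_area must be positive")
        if dens.size < 1:
            raise ValueError("need at least one sampled field")
        if np.any(dens < 0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "field_densities", dens)


@dataclass(frozen=True)
class MorphometryRecord:
    """Caliper morphometry of one eye."""

    eye_id: str
    strain_label: str
    age_months: float
    treatment: str  # "glaucoma" or "control"
    axial_length: float  # mm
    width_NT: float  # mm, nasal-temporal
    width_SI: float | None = None  # mm, superior-inferior
    fixed: bool = False
    inflated: bool = False

    def __post_init__(self):
        dims = [self.axial_length, self.width_NT]
        if self.width_SI is not None:
            dims.append(self.width_SI)
        if any(d <= 0 for d in dims):
            raise ValueError("eye dimensions must be positive")
        if self.age_months <= 0:
            raise ValueError("age must be positive")


# ---------------------------------------------------------------------------
# Axon counts
# ---------------------------------------------------------------------------

def estimate_axon_count(sample: AxonSample) -> int:
    """Estimate total axon number of one optic nerve.

    The mean of the sampled field densities (axons/mm^2) is multiplied by
    the individual nerve cross-section area; the result is rounded to the
    nearest axon.
    """
    return int(round(float(np.mean(sample.field_densities)) * sample.nerve_area))


def percent_axon_loss(count: float, pooled_fellow_mean: float) -> float:
    """Percent axon loss of an eye relative to the pooled fellow-eye mean.

    Negative values (apparent gain) are permitted.
    """
    if pooled_fellow_mean <= 0:
        raise ValueError("pooled fellow mean must be positive")
    return 100.0 * (1.0 - count / pooled_fellow_mean)


# ---------------------------------------------------------------------------
# Positive integral IOP
# ---------------------------------------------------------------------------

def positive_integral_iop(treated: IOPSeries, fellow: IOPSeries) -> float:
    """Cumulative IOP exposure of the treated eye (mmHg*days).

    Integrates the positive part of the pointwise treated-minus-fellow
    IOP difference over time (trapezoids on the union of measurement
    days, restricted to the overlapping range, with sign crossings
    located by linear interpolation).  Always >= 0; no extrapolation
    beyond the first/last shared measurement.
    """
    lo = max(treated.days[0], fellow.days[0])
    hi = min(treated.days[-1], fellow.days[-1])
    if hi <= lo:
        raise ValueError("IOP series have no overlapping day range")
    days = np.union1d(treated.days, fellow.days)
    days = days[(days >= lo) & (days <= hi)]
    diff = np.interp(days, treated.days, treated.iop) - np.interp(
        days, fellow.days, fellow.iop
    )
    total = 0.0
    for (d0, d1), (f0, f1) in zip(
        zip(days[:-1], days[1:]), zip(diff[:-1], diff[1:])
    ):
        if f0 >= 0 and f1 >= 0:
            total += 0.5 * (f0 + f1) * (d1 - d0)
        elif f0 <= 0 and f1 <= 0:
            continue
        else:
            dc = d0 + f0 / (f0 - f1) * (d1 - d0)
            if f0 > 0:
                total += 0.5 * f0 * (dc - d0)
            else:
                total += 0.5 * f1 * (d1 - dc)
    return total


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

def percent_dimension_change(group_mean_a: float, group_mean_b: float) -> float:
    """Percent change of dimension a relative to reference dimension b."""
    if group_mean_b <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (group_mean_a - group_mean_b) / group_mean_b


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (for comparing percent
    metrics against integers reported at coarse precision)."""
    factor = 10.0**ndigits
    y = math.floor(abs(x) * factor + 0.5) / factor
    y = math.copysign(y, x)
    return y if ndigits > 0 else float(int(y))


# ---------------------------------------------------------------------------
# RGC body counts
# ---------------------------------------------------------------------------

def rgc_body_summary(
    field_counts: pd.DataFrame,
    control_label: str = "control",
    treated_label: str = "treated",
) -> dict:
    """Summarise per-field RGC body counts into group means and the
    percent decrease of the treated group relative to the control mean.

    Parameters
    ----------
    field_counts : DataFrame with columns ``retina_id``, ``group`` and
        ``count`` (marker-positive cells per imaged field).

    Returns
    -------
    dict with per-group mean and SD of the per-retina mean counts, and
    ``percent_decrease`` of treated vs control group mean.
    """
    required = {"retina_id", "group", "count"}
    missing = required - set(field_counts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    per_retina = field_counts.groupby(["group", "retina_id"])["count"].mean()
    out: dict = {"groups": {}}
    for group, vals in per_retina.groupby(level="group"):
        arr = vals.to_numpy(dtype=float)
        out["groups"][group] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        }
    for label in (control_label, treated_label):
        if label not in out["groups"]:
            raise ValueError(f"empty group: {label!r}")
    ctrl = out["groups"][control_label]["mean"]
    trt = out["groups"][treated_label]["mean"]
    if ctrl <= 0:
        raise ValueError("control group mean must be positive")
    out["percent_decrease"] = 100.0 * (1.0 - trt / ctrl)
    return out


# ---------------------------------------------------------------------------
# Error budget
# ---------------------------------------------------------------------------

def error_budget(components: Iterable[float]) -> float:
    """Total displacement-measurement error (um) as the additive budget of
    its components (pixel-distance calibration, image-correlation error,
    ...)."""
    comps = [float(c) for c in components]
    if any(c < 0 for c in comps):
        raise ValueError("error components must be non-negative")
    return float(sum(comps))
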