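"""Per-eye inflation analysis and group aggregation.

`ScleralInflationModel` orchestrates the full chain — ellipse fitting,
meridian parameterization, polynomial displacement fitting, strain and
stress-resultant evaluation, QC exclusion — for one eye over a pressure
schedule, and `fit()` returns a `ScleralInflationResults` carrying the
region-averaged stress-resultant/strain curves.  `aggregate_groups`
assembles cohort curves into per-group, per-step summaries with
nonparametric pairwise comparisons (Bonferroni corrected across
pressure steps within each region/direction family).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import kinematics, shell_statics
from .edge_geometry import (
    DEFAULT_REGION_BOUNDARIES,
    AxisSpec,
    EdgeTrace,
    MeridianParam,
    fit_ellipse,
    mirror_trace,
    parameterize_meridian,
)

__all__ = [
    "PressureSchedule",
    "AnalysisConfig",
    "QCReport",
    "ScleralInflationModel",
    "ScleralInflationResults",
    "analyze_eye",
    "aggregate_groups",
    "GroupComparison",
]

CURVE_QUANTITIES = ("E_phi", "E_theta", "n_phi", "n_theta")


@dataclass(frozen=True)
class PressureSchedule:
    """Inflation protocol: reference pressure P0 and analyzed steps (mmHg).

    P0 is the lowest pressure at which the sclera is unwrinkled,
    typically 6-8 mmHg; the loading ramp is analyzed between 10 and
    30 mmHg.  The exact analyzed steps are configuration.
    """

    reference_pressure: float = 7.0
    steps: tuple = (10.0, 14.0, 18.0, 22.0, 26.0, 30.0)

    def __post_init__(self):
        steps = tuple(float(s) for s in self.steps)
        if len(steps) == 0 or np.any(np.diff(steps) <= 0):
            raise ValueError("steps must be ascending and non-empty")
        if steps[-1] > 30.0 + 1e-9:
            raise ValueError("steps above 30 mmHg are outside the protocol")
        if not 0 < self.reference_pressure < steps[0]:
            raise ValueError("reference pressure must be positive and below the steps")
        object.__setattr__(self, "steps", steps)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings with the defaults used throughout.

    The QC thresholds are anchored to the displacement-tracking noise
    floor: a step whose displacement-fit rms exceeds
    ``qc_rms_factor x noise_floor_um`` is invalid ("poor displacement
    fit"); above ``qc_gross_factor x`` it is treated as broken point
    correspondence.  An eye with more than ``qc_max_invalid_fraction``
    invalid steps is excluded.
    """

    region_boundaries: tuple = DEFAULT_REGION_BOUNDARIES
    n_eval_r23: int = 8
    n_eval_r4: int = 4
    poly_degree: int = 4
    noise_floor_um: float = 0.46
    qc_rms_factor: float = 3.0
    qc_gross_factor: float = 50.0
    qc_max_invalid_fraction: float = 0.5
    ratio_epsilon: float = 1e-4


@dataclass
class QCReport:
    """Quality-control outcome for one analyzed eye."""

    eye_id: str
    status: str = "analyzed"  # or "excluded"
    reasons: list = dfield(default_factory=list)
    step_flags: dict = dfield(default_factory=dict)  # pressure -> reason or "ok"

    def flag_step(self, pressure: float, reason: str) -> None:
        self.step_flags[pressure] = reason
        if reason != "ok" and reason not in self.reasons:
            self.reasons.append(reason)

    @property
    def n_valid_steps(self) -> int:
        return sum(1 for v in self.step_flags.values() if v == "ok")

    def to_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "status": self.status,
            "reasons": list(self.reasons),
            "step_flags": {f"{p:g}": v for p, v in self.step_flags.items()},
        }


def _evaluation_locations(
    param: MeridianParam, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Interior evaluation arc lengths for regions R2-3 and R4.

    R1 (peripapillary) and R5 (at the fixture) are excluded because the
    membrane assumptions fail near the ONH and the holder.
    """
    s = param.arc_length_s
    b = config.region_boundaries
    s0, total = s[0], s[-1] - s[0]

    def interior(f_lo, f_hi, n):
        pts = np.linspace(s0 + f_lo * total, s0 + f_hi * total, n + 2)
        return pts[1:-1]

    return interior(b[0], b[2], config.n_eval_r23), interior(b[2], b[3], config.n_eval_r4)


def analyze_eye(
    traces: Sequence[EdgeTrace],
    schedule: PressureSchedule,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[pd.DataFrame, QCReport, pd.DataFrame]:
    """Run the full per-eye analysis.

    Returns ``(region_curves, qc, samples)``: region-averaged curves (one
    row per region x analyzed step), the QC report, and the pointwise
    strain/resultant samples.
    """
    traces = sorted(traces, key=lambda tr: tr.pressure)
    traces = [mirror_trace(tr) if tr.side == "left" else tr for tr in traces]
    eye_id = traces[0].eye_id
    qc = QCReport(eye_id=eye_id)

    ref = [tr for tr in traces if np.isclose(tr.pressure, schedule.reference_pressure)]
    if not ref:
        raise ValueError(
            f"eye {eye_id}: missing reference trace at P0 = "
            f"{schedule.reference_pressure:g} mmHg"
        )
    reference = ref[0]
    deformed = [
        tr
        for tr in traces
        if any(np.isclose(tr.pressure, s) for s in schedule.steps)
    ]
    if not deformed:
        raise ValueError(f"eye {eye_id}: no deformed trace at any scheduled step")

    ref_fit = fit_ellipse(reference.points)
    ref_param = parameterize_meridian(ref_fit, reference)
    from .edge_geometry import assign_regions

    assign_regions(ref_param, config.region_boundaries)
    s_r23, s_r4 = _evaluation_locations(ref_param, config)
    noise_floor_mm = config.noise_floor_um * 1e-3

    sample_rows, curve_rows = [], []
    for tr in deformed:
        p = tr.pressure
        if tr.n_points != reference.n_points:
            qc.flag_step(p, "poor correspondence")
            continue
        disp = kinematics.fit_displacement(ref_param, tr, degree=config.poly_degree)
        if disp.fit_rms > config.qc_gross_factor * noise_floor_mm:
            qc.flag_step(p, "poor correspondence")
            continue
        if disp.fit_rms > config.qc_rms_factor * noise_floor_mm:
            qc.flag_step(p, "poor displacement fit")
            continue
        try:
            def_fit = fit_ellipse(tr.points)
        except ValueError:
            qc.flag_step(p, "poor correspondence")
            continue
        for region, s_eval in (("R2-3", s_r23), ("R4", s_r4)):
            t_eval = np.atleast_1d(ref_param.angle_from_s(s_eval))
            samples = kinematics.strain_samples(ref_param, disp, s_eval)
            x_def = ref_param.ellipse.point(t_eval) + disp.u(t_eval)
            curvs = shell_statics.deformed_curvatures(
                def_fit, x_def, ref_param.axis, location_s=s_eval, pressure=p
            )
            res = [
                shell_statics.stress_resultants(p, c, region=region) for c in curvs
            ]
            for sm, rs in zip(samples, res):
                sample_rows.append(
                    {
                        "eye_id": eye_id,
                        "pressure_mmHg": p,
                        "region": region,
                        "s_mm": sm.location_s,
                        "E_phi": sm.E_phi,
                        "E_theta": sm.E_theta,
                        "n_phi_N_per_m": rs.n_phi,
                        "n_theta_N_per_m": rs.n_theta,
                    }
                )
            curve_rows.append(
                {
                    "eye_id": eye_id,
                    "region": region,
                    "pressure_mmHg": p,
                    "E_phi": float(np.mean([sm.E_phi for sm in samples])),
                    "E_theta": float(np.mean([sm.E_theta for sm in samples])),
                    "n_phi": float(np.mean([r.n_phi for r in res])),
                    "n_theta": float(np.mean([r.n_theta for r in res])),
                    "n_points": len(samples),
                }
            )
        qc.flag_step(p, "ok")

    n_steps = len(qc.step_flags)
    if n_steps == 0 or qc.n_valid_steps == 0:
        qc.status = "excluded"
        if "incomplete protocol" not in qc.reasons:
            qc.reasons.append("incomplete protocol")
    elif (n_steps - qc.n_valid_steps) / n_steps > config.qc_max_invalid_fraction:
        qc.status = "excluded"

    curves = pd.DataFrame(curve_rows)
    samples_df = pd.DataFrame(sample_rows)
    if not curves.empty:
        curves = curves.sort_values(["region", "pressure_mmHg"]).reset_index(drop=True)
    return curves, qc, samples_df


class ScleralInflationModel:
    """Thin-shell inflation analysis of one eye.

    Parameters
    ----------
    traces : sequence of EdgeTrace
        Reference (at P0) and deformed edge traces of one eye.
    schedule : PressureSchedule
    config : AnalysisConfig

    Examples
    --------
    >>> model = ScleralInflationModel(eye.traces, PressureSchedule())
    >>> res = model.fit()
    >>> print(res.summary())        # doctest: +SKIP
    """

    def __init__(
        self,
        traces: Sequence[EdgeTrace],
        schedule: PressureSchedule | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.traces = list(traces)
        if not self.traces:
            raise ValueError("no traces supplied")
        self.schedule = schedule or PressureSchedule()
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        eye_id: str | None = None,
        schedule: PressureSchedule | None = None,
        config: AnalysisConfig | None = None,
    ) -> "ScleralInflationModel":
        """Build from the edge-trace CSV dialect (see :mod:`scleramech.io`)."""
        from .io import traces_from_dataframe

        traces = traces_from_dataframe(df)
        if eye_id is not None:
            traces = [tr for tr in traces if tr.eye_id == eye_id]
        return cls(traces, schedule=schedule, config=config)

    def fit(self) -> "ScleralInflationResults":
        curves, qc, samples = analyze_eye(self.traces, self.schedule, self.config)
        return ScleralInflationResults(self, curves, qc, samples)


class ScleralInflationResults:
    """Results of a per-eye inflation analysis.

    Attributes
    ----------
    region_curves : DataFrame
        Region-averaged stress-resultant/strain curve (one row per
        region x pressure step).
    qc : QCReport
    samples : DataFrame
        Pointwise strain and resultant samples.
    """

    def __init__(self, model, region_curves, qc, samples):
        self.model = model
        self.region_curves = region_curves
        self.qc = qc
        self.samples = samples

    @property
    def eye_id(self) -> str:
        return self.qc.eye_id

    def anisotropy(self) -> pd.DataFrame:
        """Per-sample anisotropy ratios E_theta/E_phi and n_theta/n_phi."""
        sr, nr = shell_statics.anisotropy_ratios(
            self.samples["E_phi"].to_numpy(),
            self.samples["E_theta"].to_numpy(),
            self.samples["n_phi_N_per_m"].to_numpy(),
            self.samples["n_theta_N_per_m"].to_numpy(),
            epsilon=self.model.config.ratio_epsilon,
        )
        out = self.samples[["eye_id", "pressure_mmHg", "region", "s_mm"]].copy()
        out["strain_ratio"] = np.atleast_1d(sr)
        out["resultant_ratio"] = np.atleast_1d(nr)
        return out

    def summary(self) -> str:
        lines = [
            "Scleral inflation analysis",
            "==========================",
            f"eye:            {self.eye_id}",
            f"status:         {self.qc.status}"
            + (f" ({'; '.join(self.qc.reasons)})" if self.qc.reasons else ""),
            f"reference P0:   {self.model.schedule.reference_pressure:g} mmHg",
            f"analyzed steps: {self.qc.n_valid_steps}/{len(self.qc.step_flags)}",
            "",
            "Region-averaged curves (strain [-], stress resultant [N/m]):",
        ]
        if self.region_curves.empty:
            lines.append("  (no valid steps)")
        else:
            tbl = self.region_curves[
                ["region", "pressure_mmHg", "E_phi", "E_theta", "n_phi", "n_theta"]
            ]
            lines.append(
                tbl.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.5f}",
                )
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Stress-resultant vs strain curves, one panel per region."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for a, region in zip(np.atleast_1d(ax), ("R2-3", "R4")):
            sub = self.region_curves[self.region_curves["region"] == region]
            a.plot(sub["E_theta"], sub["n_theta"], "o-", label=r"circumferential")
            a.plot(sub["E_phi"], sub["n_phi"], "s--", label=r"meridional")
            a.set_xlabel("Green-Lagrange strain")
            a.set_title(f"region {region}")
            a.legend()
        np.atleast_1d(ax)[0].set_ylabel("stress resultant [N/m]")
        return ax


# ---------------------------------------------------------------------------
# Group aggregation
# ---------------------------------------------------------------------------

class GroupComparison:
    """Per-group, per-step curve summaries with nonparametric tests."""

    def __init__(self, table: pd.DataFrame, alpha: float):
        self.table = table
        self.alpha = alpha

    def significant_steps(self, region: str, quantity: str) -> np.ndarray:
        sub = self.table[
            (self.table["region"] == region) & (self.table["quantity"] == quantity)
        ]
        return sub.loc[sub["significant"], "pressure_mmHg"].to_numpy()

    def summary(self) -> str:
        lines = [
            "Group comparison of inflation curves",
            "====================================",
            f"alpha = {self.alpha:g} (Bonferroni within each region/quantity family)",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.5g}"),
        ]
        return "\n".join(lines)


def aggregate_groups(
    curves: pd.DataFrame,
    group_labels: Mapping[str, str],
    alpha: float = 0.05,
) -> GroupComparison:
    """Aggregate per-eye region curves into group summaries and compare.

    Parameters
    ----------
    curves : DataFrame
        Concatenated ``region_curves`` of several eyes.
    group_labels : mapping eye_id -> group name (>= 2 eyes per group).
    alpha : familywise significance level; p-values are Bonferroni
        corrected across pressure steps within each (region, quantity)
        family.

    Two groups are compared with the Mann-Whitney U test, three or more
    with Kruskal-Wallis nonparametric ANOVA.
    """
    df = curves.copy()
    df["group"] = df["eye_id"].map(group_labels)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "eye_id"].unique())
        raise ValueError(f"eyes without group label: {missing}")
    sizes = df.groupby("group")["eye_id"].nunique()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(
            f"groups with fewer than 2 eyes: {sorted(small.index.tolist())}"
        )
    groups = sorted(sizes.index.tolist())
    rows = []
    for (region, quantity), fam in _family_iter(df):
        steps = sorted(fam["pressure_mmHg"].unique())
        n_steps = len(steps)
        for p in steps:
            at = fam[fam["pressure_mmHg"] == p]
            vals = [
                at.loc[at["group"] == g, quantity].to_numpy(dtype=float)
                for g in groups
            ]
            if len(groups) == 2:
                stat = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
            else:
                stat = stats.kruskal(*vals)
            p_raw = float(stat.pvalue)
            p_adj = min(1.0, p_raw * n_steps)
            row = {
                "region": region,
                "quantity": quantity,
                "pressure_mmHg": p,
                "p_raw": p_raw,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
            for g, v in zip(groups, vals):
                row[f"mean_{g}"] = float(np.mean(v))
                row[f"se_{g}"] = float(np.std(v, ddof=1) / np.sqrt(v.size))
                row[f"n_{g}"] = int(v.size)
            rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["region", "quantity", "pressure_mmHg"]
    ).reset_index(drop=True)
    return GroupComparison(table, alpha)


def _family_iter(df: pd.DataFrame):
    for region in sorted(df["region"].unique()):
        for quantity in CURVE_QUANTITIES:
            fam = df[df["region"] == region][
                ["eye_id", "group", "pressure_mmHg", quantity]
            ]
            yield (region, quantity), fam
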