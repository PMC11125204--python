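"""Growth-rate estimation and group statistics.

Per-embryo increase rates are slopes of ordinary least-squares lines fitted
to (day, measure) points, with measures log-transformed (natural log) where
growth is multiplicative. Groups of embryos are compared with pairwise
Mann-Whitney U-tests — one-tailed where the ablation is expected to act in a
known direction (treated < control), two-tailed otherwise — and a pooled
Student t-test for cell length-to-width ratios. Shape ratios are summarised
by the geometric mean with a multiplicative (geometric) SD factor. The
significance level defaults to α = 0.05; no multiple-testing correction is
applied (pairwise tests at fixed α).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class GrowthRateEstimate:
    embryo_id: str
    measure: str
    log_transformed: bool
    slope: float  # per day
    intercept: float
    n_points: int
    residual_sd: float


@dataclass(frozen=True)
class GroupComparison:
    test: Literal["mann_whitney", "student_t"]
    statistic: float  # U or t
    p_value: float
    alternative: Literal["two_sided", "less", "greater"]
    continuity_correction: bool
    n_a: int
    n_b: int
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def fit_increase_rate(
    day_values: Sequence[tuple[float, float]],
    log_transform: bool = True,
    *,
    embryo_id: str = "",
    measure: str = "",
) -> GrowthRateEstimate:
    """OLS slope of measure (or its natural log) against day.

    Requires at least two distinct days; under ``log_transform`` every value
    must be positive (the offending day is named otherwise).
    """
    pts = list(day_values)
    days = np.array([d for d, _ in pts], dtype=float)
    vals = np.array([v for _, v in pts], dtype=float)
    if len(np.unique(days)) < 2:
        raise ValueError("need measurements on >= 2 distinct days")
    if log_transform:
        bad = days[vals <= 0]
        if bad.size:
            raise ValueError(
                f"non-positive value under log transform at day {bad[0]:g}"
            )
        vals = np.log(vals)
    design = np.column_stack([days, np.ones_like(days)])
    (slope, intercept), *_ = np.linalg.lstsq(design, vals, rcond=None)
    resid = vals - design @ np.array([slope, intercept])
    dof = len(vals) - 2
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return GrowthRateEstimate(
        embryo_id=embryo_id,
        measure=measure,
        log_transformed=log_transform,
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(vals),
        residual_sd=residual_sd,
    )


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
    continuity: bool = True,
    alpha: float = ALPHA,
) -> GroupComparison:
    """Mann-Whitney U-test on two independent samples.

    The U statistic uses mid-ranks for ties. The p-value is exact (full
    permutation distribution) for tie-free samples with min(n_a, n_b) <= 8,
    and a normal approximation with tie-corrected variance and optional
    continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[
        alternative
    ]
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = (not has_ties) and min(a.size, b.size) <= 8
    res = sps.mannwhitneyu(
        a,
        b,
        alternative=alt,
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    return GroupComparison(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,  # type: ignore[arg-type]
        continuity_correction=continuity and not exact,
        n_a=a.size,
        n_b=b.size,
        alpha=alpha,
    )


def student_t(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = ALPHA,
) -> GroupComparison:
    """Two-sample pooled-variance Student t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Student t-test needs n >= 2 per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) != np.mean(b):
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):
        if np.allclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance")
    return GroupComparison(
        test="student_t",
        statistic=t,
        p_value=p,
        alternative="two_sided",
        continuity_correction=False,
        n_a=a.size,
        n_b=b.size,
        alpha=alpha,
    )


def geometric_summary(values: Sequence[float]) -> tuple[float, float]:
    """Geometric mean and multiplicative SD factor of positive values.

    ``gm = exp(mean(ln v))``; ``gsd = exp(sd(ln v))`` (sample SD). The pair
    reads as ``gm ×/ gsd``: one geometric SD spans gm/gsd to gm·gsd.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if (v <= 0).any():
        raise ValueError("geometric summary needs positive values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if v.size > 1 else 1.0
    return gm, gsd


#: One-tailed direction per measure for day-6 endpoint comparisons:
#: ablation is expected to reduce each of these in the treated group.
ONE_TAILED_MEASURES = {"blade_area", "n_cells", "blade_lwr", "cell_area"}


def compare_conditions(
    dataset: pd.DataFrame,
    measure: str,
    endpoint: str,
    ablated_condition: str,
    control_condition: str,
    *,
    endpoint_day: int = 6,
    start_day: int = 0,
    tail: Optional[str] = None,
    alpha: float = ALPHA,
) -> tuple[GroupComparison, pd.DataFrame]:
    """Compare one measure between an ablated and a control group.

    ``dataset`` is tidy: columns ``embryo_id, condition, day, measure,
    value``. ``endpoint='day6'`` compares per-embryo values at
    ``endpoint_day`` with a one-tailed Mann-Whitney (treated < control) for
    size-like measures; ``endpoint='rate'`` compares per-embryo OLS slopes
    (log scale for area/cell counts) two-tailed; slopes are fitted on days
    >= ``start_day`` so treated series can be aligned to their ablation day
    (the level drop at ablation is not growth). Returns the test plus a
    summary frame with box-plot statistics (median, quartiles) and geometric
    summaries for ratio measures. Embryos missing the endpoint day are
    excluded with a warning row in the summary.
    """
    sub = dataset[dataset["measure"] == measure]
    groups: dict[str, list[float]] = {}
    warnings: list[str] = []
    for cond in (ablated_condition, control_condition):
        vals = []
        for eid, df_e in sub[sub["condition"] == cond].groupby("embryo_id"):
            if endpoint == "day6":
                at_day = df_e[df_e["day"] == endpoint_day]
                if at_day.empty:
                    warnings.append(f"{eid}: no day-{endpoint_day} snapshot")
                    continue
                vals.append(float(at_day["value"].iloc[0]))
            elif endpoint == "rate":
                post = df_e[df_e["day"] >= start_day]
                pts = list(zip(post["day"], post["value"]))
                log = measure in ("blade_area", "n_cells", "cell_area")
                vals.append(fit_increase_rate(pts, log_transform=log).slope)
            else:
                raise ValueError(f"unknown endpoint {endpoint!r}")
        groups[cond] = vals
    a, b = groups[ablated_condition], groups[control_condition]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 embryos per group")
    if tail is None:
        if endpoint == "day6" and measure in ONE_TAILED_MEASURES:
            tail = "less"  # treated expected below control
        else:
            tail = "two_sided"
    comparison = mann_whitney_u(a, b, alternative=tail, alpha=alpha)
    rows = []
    for cond, vals in groups.items():
        arr = np.asarray(vals, float)
        row = {
            "condition": cond,
            "measure": measure,
            "endpoint": endpoint,
            "n": arr.size,
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
            "mean": float(arr.mean()),
        }
        if "lwr" in measure and (arr > 0).all():
            gm, gsd = geometric_summary(arr)
            row["geometric_mean"], row["geometric_sd_factor"] = gm, gsd
        rows.append(row)
    summary = pd.DataFrame(rows)
    if warnings:
        summary.attrs["warnings"] = warnings
    return comparison, summary
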