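"""Experiment-1 analysis: psychometric fits → discrimination boundary → confusion.

Per cue condition, trials are stratified into the three distance-direction
groups (approaching / intermediate / receding, by pedestal distance rate)
and one psychometric function is fit per group over size-change rate versus
the proportion of "inflating" judgments.  Each group's PSE is a point on
that group's line in the (ḋ, ṡ) stimulus plane — the satellite design
co-varies ḋ with ṡ along each group, so the PSE's distance-rate coordinate
is ``pedestal + r·PSE`` with ``r`` the satellite-pairing slope dḋ/dṡ.  A
weighted maximum-likelihood straight line through the three PSE points is
the *discrimination boundary*; its slope with respect to the distance-rate
axis, divided by the zero-image-change slope ``k_img = s₀/d₀``, is the
*confusion ratio*: 1 for judgments driven purely by image size-change, 0
for veridical physical size-change judgments.

Uncertainty comes from a nonparametric bootstrap over responses (within
group × level cells), refitting all three psychometric functions and the
boundary per resample; error bars are the MADC of the resampled confusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import (
    BALL_DIAMETER_MM,
    NORMALIZATION_DISTANCE_MM,
    CueCondition,
    DirectionGroup,
    image_boundary_slope,
)
from .observer import DEFLATING, INFLATING
from .psychometric import PsychometricFit, fit_psychometric, madc

__all__ = [
    "DiscriminationBoundary",
    "ConfusionResult",
    "group_and_fit",
    "group_pairing_slope",
    "boundary_points",
    "fit_boundary",
    "confusion_ratio",
    "analyze_condition",
    "paired_sign_test",
    "default_k_img",
]

_GROUPS = (
    DirectionGroup.APPROACHING,
    DirectionGroup.INTERMEDIATE,
    DirectionGroup.RECEDING,
)


@dataclass
class DiscriminationBoundary:
    """Straight-line separator of inflating/deflating responses in (ḋ, ṡ)."""

    slope_k: float
    intercept: float
    fit_loglik: float


@dataclass
class ConfusionResult:
    """Confusion ratio for one cue condition, with bootstrap uncertainty."""

    condition: CueCondition
    confusion: float
    ci_low: float
    ci_high: float
    madc_se: float
    boundary: DiscriminationBoundary
    per_group_fits: dict
    bootstrap_confusions: np.ndarray
    n_bootstrap_failed: int = 0


def default_k_img(
    s0: float = BALL_DIAMETER_MM, d0: float = NORMALIZATION_DISTANCE_MM
) -> float:
    """Normalization slope from the canonical start geometry (35 mm, 449 mm)."""
    return image_boundary_slope(s0, d0)


def _condition_label(condition) -> str:
    return condition.label if isinstance(condition, CueCondition) else str(condition)


def _select(records: pd.DataFrame, condition) -> pd.DataFrame:
    label = _condition_label(condition)
    out = records[records["condition"] == label]
    if out.empty:
        raise ValueError(f"no records for condition {label}")
    return out


def _counts(sub: pd.DataFrame):
    grouped = (
        sub.assign(yes=(sub["response"] == INFLATING).astype(int))
        .groupby("size_rate_mm_s")
        .agg(k=("yes", "sum"), n=("yes", "size"))
        .reset_index()
    )
    return (
        grouped["size_rate_mm_s"].to_numpy(),
        grouped["k"].to_numpy(),
        grouped["n"].to_numpy(),
    )


def group_and_fit(
    records: pd.DataFrame, condition, *, lapse_max: float = 0.06
) -> dict:
    """One psychometric fit per distance-direction group for a condition.

    Abscissa is the size-change rate, ordinate the proportion of trials
    judged "inflating".  Raises if any of the three groups is missing.
    """
    sub = _select(records, condition)
    present = set(sub["direction_group"])
    fits = {}
    for group in _GROUPS:
        if group.value not in present:
            raise ValueError(f"missing distance-direction group: {group.value}")
        data = sub[sub["direction_group"] == group.value]
        x, k, n = _counts(data)
        fits[group] = fit_psychometric(x, k, n, lapse_max=lapse_max)
    return fits


def group_pairing_slope(records: pd.DataFrame, condition, group) -> float:
    """Satellite-pairing slope r = dḋ/dṡ along one direction-group line."""
    sub = _select(records, condition)
    data = sub[sub["direction_group"] == DirectionGroup(group).value]
    s = data["size_rate_mm_s"].to_numpy()
    d = data["distance_rate_mm_s"].to_numpy()
    var = np.var(s)
    if var == 0:
        return 0.0
    return float(np.cov(s, d, bias=True)[0, 1] / var)


def boundary_points(fits: dict, records: pd.DataFrame, condition):
    """Place each group's PSE on its line in the (ḋ, ṡ) plane.

    Returns a list of ``(d_rate, pse, pse_se)`` triples, one per group, where
    ``d_rate = pedestal + r·PSE``.
    """
    sub = _select(records, condition)
    points = []
    for group, fit in fits.items():
        if not fit.converged:
            raise ValueError(
                f"psychometric fit for group {DirectionGroup(group).value} "
                f"did not converge: {fit.message}"
            )
        data = sub[sub["direction_group"] == DirectionGroup(group).value]
        pedestal = float(data["pedestal_mm_s"].iloc[0])
        r = group_pairing_slope(records, condition, group)
        se = fit.pse_se if np.isfinite(fit.pse_se) and fit.pse_se > 0 else 1.0
        points.append((pedestal + r * fit.pse, fit.pse, se))
    return points


def fit_boundary(points) -> DiscriminationBoundary:
    """Gaussian-ML straight-line fit of PSE against distance rate.

    Each point is ``(d_rate, pse, pse_se)``; with Gaussian errors on the
    PSEs, maximum likelihood is weighted least squares with weights
    ``1/pse_se²``.  The slope is taken with respect to the distance-rate
    axis (``dṡ/dḋ``).
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need at least two PSE points to fit a boundary")
    d = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    se = np.array([p[2] for p in points], dtype=float)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(y))):
        raise ValueError("boundary fit requires finite PSE points")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("boundary fit requires positive finite PSE errors")
    model = sm.WLS(y, sm.add_constant(d), weights=1.0 / se**2)
    res = model.fit()
    intercept, slope = res.params
    resid = y - (intercept + slope * d)
    loglik = float(
        np.sum(stats.norm.logpdf(resid, loc=0.0, scale=se))
    )
    return DiscriminationBoundary(
        slope_k=float(slope), intercept=float(intercept), fit_loglik=loglik
    )


def confusion_ratio(boundary: DiscriminationBoundary, k_img: float) -> float:
    """Normalize a boundary slope by the zero-image-change slope.

    1 means image-driven judgments, 0 veridical size judgments; values are
    reported unclamped (sampling noise may overshoot either endpoint).
    """
    if k_img <= 0:
        raise ValueError("k_img must be positive")
    return boundary.slope_k / k_img


def _pipeline_confusion(records, condition, k_img, lapse_max, warm=None):
    """One pass of the full pipeline; returns (confusion, boundary, fits)."""
    sub = _select(records, condition)
    fits = {}
    for group in _GROUPS:
        data = sub[sub["direction_group"] == group.value]
        x, k, n = _counts(data)
        fits[group] = fit_psychometric(
            x,
            k,
            n,
            lapse_max=lapse_max,
            warm_start=warm.get(group) if warm else None,
            extra_starts=0 if warm else 4,
        )
    points = boundary_points(fits, records, condition)
    boundary = fit_boundary(points)
    return confusion_ratio(boundary, k_img), boundary, fits


def analyze_condition(
    records: pd.DataFrame,
    condition,
    B: int = 1000,
    seed: int | None = None,
    *,
    k_img: float | None = None,
    lapse_max: float = 0.06,
    alpha: float = 0.05,
) -> ConfusionResult:
    """Full Experiment-1 pipeline for one cue condition with bootstrap CI.

    Point estimate: three psychometric fits, boundary fit, normalization by
    ``k_img`` (default: canonical 35 mm / 449 mm geometry).  Uncertainty: B
    nonparametric resamples of responses within (group, size-rate) cells,
    re-running the entire pipeline per resample; the confidence interval is
    percentile-based and ``madc_se`` is the MADC of the resampled confusions.
    """
    if k_img is None:
        k_img = default_k_img()
    condition = (
        condition
        if isinstance(condition, CueCondition)
        else CueCondition.parse(str(condition))
    )
    sub = _select(records, condition).reset_index(drop=True)

    confusion, boundary, fits = _pipeline_confusion(sub, condition, k_img, lapse_max)
    for group, fit in fits.items():
        if not fit.converged:
            raise ValueError(
                f"group {group.value} psychometric fit did not converge: "
                f"{fit.message}"
            )
    warm = {
        g: (f.pse, f.slope_sigma, f.lapse) for g, f in fits.items() if f.converged
    }

    rng = np.random.default_rng(seed)
    cells = sub.groupby(["direction_group", "size_rate_mm_s"]).indices
    yes = (sub["response"] == INFLATING).to_numpy()
    boot = []
    n_failed = 0
    resampled = sub.copy()
    for _ in range(B):
        new_yes = yes.copy()
        for idx in cells.values():
            p_cell = yes[idx].mean()
            new_yes[idx] = rng.random(len(idx)) < p_cell
        resampled["response"] = np.where(new_yes, INFLATING, DEFLATING)
        try:
            c, _, _ = _pipeline_confusion(
                resampled, condition, k_img, lapse_max, warm=warm
            )
            boot.append(c)
        except ValueError:
            n_failed += 1
    boot = np.asarray(boot)
    if len(boot) >= 2:
        ci_low, ci_high = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
        se = madc(boot)
    else:
        ci_low = ci_high = se = float("nan")
    return ConfusionResult(
        condition=condition,
        confusion=float(confusion),
        ci_low=float(min(ci_low, confusion)),
        ci_high=float(max(ci_high, confusion)),
        madc_se=float(se),
        boundary=boundary,
        per_group_fits=fits,
        bootstrap_confusions=boot,
        n_bootstrap_failed=n_failed,
    )


def paired_sign_test(confusions_a, confusions_b) -> float:
    """Exact two-sided sign test on paired differences (ties dropped).

    Returns the exact binomial two-sided p-value for the null that positive
    and negative paired differences are equally likely.
    """
    a = np.asarray(confusions_a, dtype=float)
    b = np.asarray(confusions_b, dtype=float)
    if len(a) != len(b) or len(a) < 1:
        raise ValueError("need equal-length, nonempty paired samples")
    diff = a - b
    diff = diff[diff != 0]
    if len(diff) == 0:
        raise ValueError("all pairs tied; sign test undefined")
    k = int(np.sum(diff > 0))
    return float(stats.binomtest(k, len(diff), 0.5, alternative="two-sided").pvalue)
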