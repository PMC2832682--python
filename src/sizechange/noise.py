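"""Experiment-2 analysis: 2IFC fits → JND → single-cue noise σ.

In the two-interval speed discrimination each interval's perceived speed is
the physical depth speed corrupted by the single cue's internal noise σ, so
the probability of calling the comparison faster is a cumulative Gaussian
in the signed speed difference with slope ``σ·√2`` (difference of two
equal-variance Gaussians).  The fitted JND is therefore interpreted as √2
times the standard deviation of the noise that corrupts one distance-change
cue; JNDs from the two standards (±55 mm/s) are averaged before conversion.

The binocular-vs-haptic reliability comparison is a bootstrap hypothesis
test: the attained one-sided p-value for σ_B < σ_H is the (smoothed)
fraction of cross-paired bootstrap draws with σ_B* ≥ σ_H*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CueCondition
from .psychometric import PsychometricFit, fit_psychometric, jnd, madc

__all__ = [
    "IFC_FACTOR",
    "NoiseEstimate",
    "fit_2ifc",
    "noise_sigma",
    "estimate_noise",
    "bootstrap_noise_test",
]

#: 2IFC signal-detection factor linking the fitted JND to single-cue noise:
#: the decision variable is a difference of two iid Gaussian percepts.
IFC_FACTOR = math.sqrt(2.0)


@dataclass
class NoiseEstimate:
    """Single-cue distance-change noise σ (mm/s) with bootstrap uncertainty."""

    condition: CueCondition
    sigma: float
    madc_se: float
    per_standard_jnds: tuple
    bootstrap_sigmas: np.ndarray
    per_standard_fits: dict
    n_bootstrap_failed: int = 0


def _speed_diff_counts(records: pd.DataFrame):
    """Aggregate to (signed speed difference, #comparison-faster, n)."""
    diff = (
        records["comparison_mm_s"].abs() - records["standard_mm_s"].abs()
    ).round(9)
    if "chose_comparison" in records:
        chose = records["chose_comparison"].astype(bool)
    else:
        chose = (records["response"] == "2nd") == records["standard_first"].astype(
            bool
        )
    tab = (
        pd.DataFrame({"x": diff, "yes": chose.astype(int)})
        .groupby("x")
        .agg(k=("yes", "sum"), n=("yes", "size"))
        .reset_index()
    )
    return tab["x"].to_numpy(), tab["k"].to_numpy(), tab["n"].to_numpy()


def fit_2ifc(
    records: pd.DataFrame, standard: float, *, lapse_max: float = 0.06
) -> PsychometricFit:
    """Fit the proportion "comparison faster" against signed speed difference.

    ``records`` should hold one condition; rows for the given standard are
    selected.  An unbiased observer has PSE near 0 and JND = σ·√2.
    """
    sub = records[records["standard_mm_s"] == standard]
    if sub.empty:
        raise ValueError(f"no records for standard {standard} mm/s")
    x, k, n = _speed_diff_counts(sub)
    fit = fit_psychometric(x, k, n, lapse_max=lapse_max)
    # ceiling performance: a perfect step drives sigma to its floor and the
    # JND is then design-limited, not observer-limited
    span = x[-1] - x[0]
    if fit.converged and fit.slope_sigma <= 1.001e-3 * span:
        fit.converged = False
        fit.message = "ceiling performance: JND below design resolution"
    return fit


def noise_sigma(jnd_value: float) -> float:
    """Convert a 2IFC JND into the single-cue noise σ: ``jnd / √2``."""
    if jnd_value <= 0:
        raise ValueError("jnd must be positive")
    return jnd_value / IFC_FACTOR


def estimate_noise(
    records: pd.DataFrame,
    condition,
    B: int = 1000,
    seed: int | None = None,
    *,
    lapse_max: float = 0.06,
) -> NoiseEstimate:
    """Estimate one cue's noise σ from 2IFC records, with bootstrap resamples.

    The two standards are fit separately, their JNDs averaged and divided by
    √2.  B bootstrap resamples (binomial within speed-difference cells,
    per standard) repeat the whole procedure to populate
    ``bootstrap_sigmas`` and the MADC error bar.
    """
    condition = (
        condition
        if isinstance(condition, CueCondition)
        else CueCondition.parse(str(condition))
    )
    sub = records[records["condition"] == condition.label]
    if sub.empty:
        raise ValueError(f"no records for condition {condition.label}")
    standards = sorted(sub["standard_mm_s"].unique())
    if len(standards) < 2:
        raise ValueError("both standards must be present")

    fits = {}
    counts = {}
    for std in standards:
        x, k, n = _speed_diff_counts(sub[sub["standard_mm_s"] == std])
        fits[std] = fit_psychometric(x, k, n, lapse_max=lapse_max)
        counts[std] = (x, k, n)
    jnds = tuple(jnd(fits[std]) for std in standards)
    sigma = noise_sigma(float(np.mean(jnds)))

    rng = np.random.default_rng(seed)
    boot = []
    n_failed = 0
    for _ in range(B):
        resampled_jnds = []
        ok = True
        for std in standards:
            x, k, n = counts[std]
            k_star = rng.binomial(n.astype(int), k / n)
            refit = fit_psychometric(
                x,
                k_star,
                n,
                lapse_max=lapse_max,
                warm_start=(fits[std].pse, fits[std].slope_sigma, fits[std].lapse),
                extra_starts=0,
                compute_se=False,
            )
            if not refit.converged:
                ok = False
                break
            resampled_jnds.append(refit.slope_sigma)
        if ok:
            boot.append(noise_sigma(float(np.mean(resampled_jnds))))
        else:
            n_failed += 1
    boot = np.asarray(boot)
    se = madc(boot) if len(boot) >= 2 else float("nan")
    return NoiseEstimate(
        condition=condition,
        sigma=float(sigma),
        madc_se=float(se),
        per_standard_jnds=jnds,
        bootstrap_sigmas=boot,
        per_standard_fits=fits,
        n_bootstrap_failed=n_failed,
    )


def bootstrap_noise_test(
    estimate_b: NoiseEstimate, estimate_h: NoiseEstimate
) -> float:
    """One-sided bootstrap p-value for the hypothesis σ_binocular < σ_haptic.

    The two resample sets come from independent data, so every cross pair is
    a valid draw from the joint bootstrap distribution; the p-value is the
    add-one-smoothed fraction of pairs with σ_B* ≥ σ_H*.
    """
    b = np.asarray(estimate_b.bootstrap_sigmas, dtype=float)
    h = np.asarray(estimate_h.bootstrap_sigmas, dtype=float)
    if len(b) == 0 or len(h) == 0:
        raise ValueError("both estimates need nonempty bootstrap resamples")
    exceed = int(np.sum(b[:, None] >= h[None, :]))
    return float((1 + exceed) / (len(b) * len(h) + 1))
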