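"""Maximum-likelihood psychometric functions and robust resampling utilities.

The psychometric model is the lapse-compressed cumulative Gaussian

    ψ(x) = λ + (1 − 2λ) · Φ((x − μ) / σ)

fit to binomial count data by maximum likelihood with a single symmetric
lapse parameter bounded above (``lapse_max``, default 0.06), in the spirit
of robust psychometric fitting.  The point of subjective equality (PSE) is
``μ`` — with symmetric lapse this is also the 50%-probability point — and
the just-noticeable difference (JND) is ``σ``, the level difference between
the 50% and ~84% points of the underlying Gaussian.

Optimization is multi-start bounded quasi-Newton (L-BFGS-B on
``(μ, log σ, λ)`` with analytic gradients); near-degenerate data (all
responses identical, fewer than three levels, a flat likelihood pushing σ to
its upper bound) are flagged as non-converged rather than silently returned.

Also provided: within-level nonparametric bootstrap of fits, and the
median-absolute-deviation scale estimator with finite-sample correction
(MADC) used for robust error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

__all__ = [
    "PsychometricFit",
    "BootstrapFit",
    "NotConvergedError",
    "fit_psychometric",
    "predict_prob",
    "pse",
    "jnd",
    "bootstrap_fit",
    "madc",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)
_PSI_EPS = 1e-12


class NotConvergedError(ValueError):
    """Raised when a PSE/JND is requested from a non-converged fit."""


@dataclass
class PsychometricFit:
    """A fitted cumulative-Gaussian psychometric function."""

    pse: float
    slope_sigma: float
    lapse: float
    loglik: float
    n_trials: int
    n_levels: int
    converged: bool
    message: str = ""
    pse_se: float = float("nan")
    lapse_max: float = 0.06
    levels: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    k_yes: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    n: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def predict(self, x):
        """ψ(x) at the fitted parameters."""
        return predict_prob(x, self.pse, self.slope_sigma, self.lapse)


def predict_prob(x, mu: float, sigma: float, lapse: float):
    """Lapse-compressed cumulative Gaussian ψ(x) = λ + (1−2λ)Φ((x−μ)/σ)."""
    x = np.asarray(x, dtype=float)
    out = lapse + (1.0 - 2.0 * lapse) * ndtr((x - mu) / sigma)
    return float(out) if out.ndim == 0 else out


def _negloglik_grad(theta, x, k, n, lapse_max):
    mu, log_sigma, lam = theta
    sigma = np.exp(log_sigma)
    z = (x - mu) / sigma
    phi = ndtr(z)
    pdf = np.exp(-0.5 * z * z) / _SQRT2PI
    psi = np.clip(lam + (1.0 - 2.0 * lam) * phi, _PSI_EPS, 1.0 - _PSI_EPS)
    ll = np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi))
    g_psi = k / psi - (n - k) / (1.0 - psi)
    scale = (1.0 - 2.0 * lam) * pdf
    g_mu = np.sum(g_psi * (-scale / sigma))
    g_logsigma = np.sum(g_psi * (-scale * z))
    g_lam = np.sum(g_psi * (1.0 - 2.0 * phi))
    return -ll, -np.array([g_mu, g_logsigma, g_lam])


def _probit_start(x, k, n):
    """Closed-form probit-regression initialization (no lapse)."""
    p = (k + 0.5) / (n + 1.0)
    z = ndtri(np.clip(p, 0.01, 0.99))
    w = n.astype(float)
    xm = np.average(x, weights=w)
    zm = np.average(z, weights=w)
    sxx = np.sum(w * (x - xm) ** 2)
    sxz = np.sum(w * (x - xm) * (z - zm))
    if sxx <= 0 or sxz <= 1e-12:
        return None
    a = sxz / sxx
    mu0 = xm - zm / a
    sigma0 = 1.0 / a
    return mu0, sigma0


def _aggregate(levels, k_yes, n):
    x = np.asarray(levels, dtype=float)
    k = np.asarray(k_yes, dtype=float)
    m = np.asarray(n, dtype=float)
    if not (len(x) == len(k) == len(m)):
        raise ValueError("levels, k_yes and n must have equal length")
    if np.any(m < 1):
        raise ValueError("each level needs n >= 1 trials")
    if np.any(k < 0) or np.any(k > m):
        raise ValueError("k_yes must satisfy 0 <= k_yes <= n")
    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) == len(x):
        order = np.argsort(x)
        return x[order], k[order], m[order]
    return (
        ux,
        np.bincount(inv, weights=k, minlength=len(ux)),
        np.bincount(inv, weights=m, minlength=len(ux)),
    )


def fit_psychometric(
    levels,
    k_yes,
    n,
    *,
    lapse_max: float = 0.06,
    warm_start: tuple | None = None,
    extra_starts: int = 4,
    compute_se: bool = True,
) -> PsychometricFit:
    """Fit ψ(x) = λ + (1−2λ)Φ((x−μ)/σ) to binomial response counts.

    Parameters
    ----------
    levels, k_yes, n
        Stimulus levels, number of "yes" responses and number of trials per
        level.  Duplicate levels are pooled.
    lapse_max
        Upper bound for the symmetric lapse parameter λ.
    warm_start
        Optional ``(mu, sigma, lapse)`` used as an additional start (e.g. the
        point fit when refitting bootstrap resamples).
    extra_starts
        Number of additional grid-initialized μ starts beyond the
        probit-regression start.

    Returns
    -------
    PsychometricFit
        With an honest ``converged`` flag: degenerate data (fewer than three
        distinct levels, all-identical responses, or a flat likelihood that
        drives σ to its upper bound) are flagged, never silently returned.
    """
    x, k, m = _aggregate(levels, k_yes, n)
    n_trials = int(m.sum())

    def _failed(msg):
        return PsychometricFit(
            pse=float("nan"),
            slope_sigma=float("nan"),
            lapse=float("nan"),
            loglik=float("nan"),
            n_trials=n_trials,
            n_levels=len(x),
            converged=False,
            message=msg,
            lapse_max=lapse_max,
            levels=x,
            k_yes=k,
            n=m,
        )

    if len(x) < 3:
        return _failed(f"need >= 3 distinct levels, got {len(x)}")
    if k.sum() == 0 or k.sum() == m.sum():
        return _failed("all responses identical; psychometric location unidentified")

    span = x[-1] - x[0]
    sigma_lo, sigma_hi = 1e-3 * span, 50.0 * span
    bounds = [
        (x[0] - 2.0 * span, x[-1] + 2.0 * span),
        (np.log(sigma_lo), np.log(sigma_hi)),
        (0.0, lapse_max),
    ]

    def _default_starts():
        starts = []
        probit = _probit_start(x, k, m)
        if probit is not None:
            mu0, sigma0 = probit
            mu0 = float(np.clip(mu0, *bounds[0]))
            sigma0 = float(np.clip(sigma0, sigma_lo, sigma_hi))
            starts.append((mu0, np.log(sigma0), 0.01))
        qs = np.quantile(x, np.linspace(0.15, 0.85, max(extra_starts, 1)))
        for i, mu0 in enumerate(qs[:extra_starts]):
            sigma0 = span / 4.0 if i % 2 == 0 else span / 10.0
            starts.append((float(mu0), np.log(sigma0), 0.01))
        return starts

    starts = []
    if warm_start is not None:
        mu0, sigma0, lam0 = warm_start
        starts.append(
            (
                float(np.clip(mu0, *bounds[0])),
                float(np.clip(np.log(sigma0), *bounds[1])),
                float(np.clip(lam0, 0.0, lapse_max)),
            )
        )
    if warm_start is None or extra_starts > 0:
        starts.extend(_default_starts())

    def _run(theta_list):
        best, best_ok = None, None
        for theta0 in theta_list:
            res = optimize.minimize(
                _negloglik_grad,
                np.asarray(theta0),
                args=(x, k, m, lapse_max),
                method="L-BFGS-B",
                jac=True,
                bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success and (best_ok is None or res.fun < best_ok.fun):
                best_ok = res
        # a cleanly converged start within tolerance of the overall optimum
        # beats an abnormal line-search termination at the same likelihood
        if best_ok is not None and best_ok.fun <= best.fun + 1e-6:
            return best_ok
        return best

    best = _run(starts)
    if not best.success:
        # wandered off (warm start) or line-search trouble: retry from the
        # full default start set, then polish gradient-free as a last resort
        retry = _run(_default_starts())
        if retry.success or retry.fun < best.fun:
            best = retry
    if not best.success:
        polish = optimize.minimize(
            lambda t: _negloglik_grad(t, x, k, m, lapse_max)[0],
            best.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": 400, "fatol": 1e-9, "xatol": 1e-7},
        )
        if polish.fun <= best.fun + 1e-9:
            best = polish

    mu_hat, log_sigma_hat, lam_hat = best.x
    sigma_hat = float(np.exp(log_sigma_hat))
    converged = bool(best.success)
    message = str(best.message)
    if sigma_hat >= sigma_hi * (1.0 - 1e-6):
        converged = False
        message = "slope sigma at upper bound (flat or non-monotone data)"

    pse_se = _pse_se(best.x, x, k, m, lapse_max) if compute_se else float("nan")
    return PsychometricFit(
        pse=float(mu_hat),
        slope_sigma=sigma_hat,
        lapse=float(lam_hat),
        loglik=float(-best.fun),
        n_trials=n_trials,
        n_levels=len(x),
        converged=converged,
        message=message,
        pse_se=pse_se,
        lapse_max=lapse_max,
        levels=x,
        k_yes=k,
        n=m,
    )


def _pse_se(theta, x, k, m, lapse_max):
    """Asymptotic SE of μ from a finite-difference Hessian of the negloglik."""
    h = np.array([1e-4 * max(1.0, abs(theta[0])), 1e-4, 1e-5])
    dim = len(theta)
    hess = np.empty((dim, dim))
    for j in range(dim):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _negloglik_grad(tp, x, k, m, lapse_max)
        _, gm = _negloglik_grad(tm, x, k, m, lapse_max)
        hess[:, j] = (gp - gm) / (2.0 * h[j])
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
        var = cov[0, 0]
        return float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


def pse(fit: PsychometricFit) -> float:
    """Point of subjective equality: the μ of a converged fit."""
    if not fit.converged:
        raise NotConvergedError(f"fit did not converge: {fit.message}")
    return fit.pse


def jnd(fit: PsychometricFit) -> float:
    """Just-noticeable difference: the σ of a converged fit."""
    if not fit.converged:
        raise NotConvergedError(f"fit did not converge: {fit.message}")
    return fit.slope_sigma


@dataclass
class BootstrapFit:
    """Nonparametric bootstrap of a psychometric fit."""

    samples: pd.DataFrame
    ci: dict
    n_nonconverged: int
    degenerate: bool
    warn_high_failure: bool
    pse_madc: float


def bootstrap_fit(
    levels,
    k_yes,
    n,
    B: int = 1000,
    seed: int | None = None,
    *,
    lapse_max: float = 0.06,
    alpha: float = 0.05,
) -> BootstrapFit:
    """Bootstrap a psychometric fit by binomial resampling within levels.

    The design (levels and trial counts) is fixed; responses are the random
    element, so each resample draws ``k* ~ Binomial(n, k/n)`` per level and
    refits.  Returns the resample table, percentile confidence intervals for
    (pse, sigma, lapse) over converged resamples, and the MADC of the
    resampled PSEs.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for stable percentile intervals")
    x, k, m = _aggregate(levels, k_yes, n)
    rng = np.random.default_rng(seed)
    point = fit_psychometric(x, k, m, lapse_max=lapse_max)
    warm = (
        (point.pse, point.slope_sigma, point.lapse) if point.converged else None
    )
    p_hat = k / m
    degenerate = bool(np.all((p_hat == 0) | (p_hat == 1)))

    rows = []
    for _ in range(B):
        k_star = rng.binomial(m.astype(int), p_hat)
        refit = fit_psychometric(
            x,
            k_star,
            m,
            lapse_max=lapse_max,
            warm_start=warm,
            extra_starts=0,
            compute_se=False,
        )
        rows.append(
            {
                "pse": refit.pse,
                "sigma": refit.slope_sigma,
                "lapse": refit.lapse,
                "converged": refit.converged,
            }
        )
    samples = pd.DataFrame(rows)
    ok = samples[samples["converged"]]
    n_bad = int(B - len(ok))
    ci = {}
    for name in ("pse", "sigma", "lapse"):
        if len(ok):
            lo, hi = np.nanquantile(ok[name], [alpha / 2.0, 1.0 - alpha / 2.0])
        else:
            lo = hi = float("nan")
        ci[name] = (float(lo), float(hi))
    pse_madc = madc(ok["pse"].to_numpy()) if len(ok) >= 2 else float("nan")
    return BootstrapFit(
        samples=samples,
        ci=ci,
        n_nonconverged=n_bad,
        degenerate=degenerate,
        warn_high_failure=n_bad > 0.2 * B,
        pse_madc=pse_madc,
    )


# Finite-sample correction factors b_n for the MAD scale estimator
# (robust-statistics consistency factors; n/(n - 0.8) beyond n = 9).
_MADC_FACTORS = {
    2: 1.196,
    3: 1.495,
    4: 1.363,
    5: 1.206,
    6: 1.200,
    7: 1.140,
    8: 1.129,
    9: 1.107,
}


def madc(sample) -> float:
    """Median absolute deviation with finite-sample correction (MADC).

    ``1.4826 · b_n · median(|x − median(x)|)``, a robust, Gaussian-consistent
    scale estimate.  Applied to a bootstrap resample distribution it plays
    the role of a robust standard error.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    n = len(x)
    if n < 2:
        raise ValueError("madc requires at least 2 observations")
    b_n = _MADC_FACTORS.get(n, n / (n - 0.8))
    return float(1.4826 * b_n * np.median(np.abs(x - np.median(x))))
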