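"""Linear-Gaussian explaining-away observer and oracle response rules.

The generative model mirrors the task: the desired property is the physical
size-change rate ``ṡ`` and the nuisance property is the distance-change rate
``ḋ``.  The observer receives up to three noisy cues per trial,

* an ambiguous monocular image cue ``m_I = ṡ − k·ḋ + ε_I`` (expressed in
  mm/s-equivalent units via the zero-image-change slope ``k = s₀/d₀``),
* an auxiliary binocular cue ``m_B = ḋ + ε_B`` when the binocular cue is on,
* an auxiliary haptic cue ``m_H = ḋ + ε_H`` when the haptic cue is on,

with independent zero-mean Gaussian noises.  Priors on ``(ṡ, ḋ)`` are
zero-mean Gaussians; the prior on ``ḋ`` is the slow-motion prior that, absent
auxiliary cues, attributes image growth to inflation.  *Trust* in an
auxiliary cue — the observer's belief that the cue is causally linked to the
ball's motion — inflates its effective variance, ``σ²_eff = σ²/trust``.

Because everything is linear-Gaussian the posterior over ``(ṡ, ḋ)`` is
available in closed form (2×2 conditioning), the decision rule is the sign
of the posterior mean of ``ṡ``, and the implied discrimination boundary in
the (ḋ, ṡ) stimulus plane is a straight line whose slope, normalized by the
zero-image-change slope, is the predicted confusion ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import CueCondition, DesignGrid, TrialSpec

__all__ = [
    "ObserverParams",
    "CueSample",
    "PosteriorBelief",
    "sample_cues",
    "posterior_size_rate",
    "decide",
    "predicted_confusion",
    "BayesianObserver",
    "ImageOnlyObserver",
    "VeridicalObserver",
    "image_only_observer",
    "veridical_observer",
    "simulate_exp1",
    "simulate_exp2",
]

INFLATING = "inflating"
DEFLATING = "deflating"


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the explaining-away observer.

    All noise standard deviations are in mm/s (the image cue is linearized
    into mm/s-equivalent units, so ``sigma_image`` is directly comparable to
    the size-rate grid).  Trust weights live in [0, 1]; ``lapse`` is the
    probability of a stimulus-independent random response.
    """

    sigma_image: float = 2.0
    sigma_binocular: float = 13.0
    sigma_haptic: float = 13.0
    prior_sigma_distance_rate: float = 30.0
    prior_sigma_size_rate: float = 1000.0
    trust_binocular: float = 1.0
    trust_haptic: float = 0.3
    lapse: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "sigma_image",
            "sigma_binocular",
            "sigma_haptic",
            "prior_sigma_distance_rate",
            "prior_sigma_size_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("trust_binocular", "trust_haptic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")

    def with_(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CueSample:
    """One trial's sensory measurements (absent cues are ``None``)."""

    image_rate_cue: float | None
    binocular_cue: float | None
    haptic_cue: float | None
    #: zero-image-change slope s0/d0 linking the image cue to (ṡ, ḋ)
    k_img: float


@dataclass(frozen=True)
class PosteriorBelief:
    """Gaussian posterior marginals over size- and distance-change rates."""

    mean_size_rate: float
    var_size_rate: float
    mean_distance_rate: float
    var_distance_rate: float


def _posterior_arrays(params: ObserverParams, k, m_i, m_b, m_h, has_i, has_b, has_h):
    """Vectorized 2x2 linear-Gaussian posterior over (ṡ, ḋ).

    ``k, m_*`` broadcast; ``has_*`` are boolean masks for cue presence.
    Returns (mean_s, var_s, mean_d, var_d).
    """
    p_s = 1.0 / params.prior_sigma_size_rate**2
    p_d = 1.0 / params.prior_sigma_distance_rate**2
    ii = np.where(has_i, 1.0 / params.sigma_image**2, 0.0)
    q_b = np.where(has_b, params.trust_binocular / params.sigma_binocular**2, 0.0)
    q_h = np.where(has_h, params.trust_haptic / params.sigma_haptic**2, 0.0)
    m_i = np.where(has_i, m_i, 0.0)
    m_b = np.where(has_b, m_b, 0.0)
    m_h = np.where(has_h, m_h, 0.0)

    lam11 = p_s + ii
    lam12 = -k * ii
    lam22 = p_d + k**2 * ii + q_b + q_h
    b1 = m_i * ii
    b2 = -k * m_i * ii + q_b * m_b + q_h * m_h
    det = lam11 * lam22 - lam12**2
    mean_s = (lam22 * b1 - lam12 * b2) / det
    mean_d = (lam11 * b2 - lam12 * b1) / det
    var_s = lam22 / det
    var_d = lam11 / det
    return mean_s, var_s, mean_d, var_d


def sample_cues(trial: TrialSpec, params: ObserverParams, rng) -> CueSample:
    """Draw one trial's noisy cues from the generative model."""
    rng = np.random.default_rng(rng)
    k = trial.k_img
    m_i = (
        trial.size_rate
        - k * trial.distance_rate
        + rng.normal(0.0, params.sigma_image)
    )
    m_b = (
        trial.distance_rate + rng.normal(0.0, params.sigma_binocular)
        if trial.condition.binocular
        else None
    )
    m_h = (
        trial.distance_rate + rng.normal(0.0, params.sigma_haptic)
        if trial.condition.haptic
        else None
    )
    return CueSample(image_rate_cue=m_i, binocular_cue=m_b, haptic_cue=m_h, k_img=k)


def posterior_size_rate(cues: CueSample, params: ObserverParams) -> PosteriorBelief:
    """Exact linear-Gaussian posterior over (ṡ, ḋ) given the present cues.

    Auxiliary-cue variances are inflated by 1/trust; absent cues contribute
    nothing; with no cues at all the posterior equals the (zero-mean) prior.
    """
    mean_s, var_s, mean_d, var_d = _posterior_arrays(
        params,
        np.asarray(cues.k_img, dtype=float),
        np.asarray(0.0 if cues.image_rate_cue is None else cues.image_rate_cue),
        np.asarray(0.0 if cues.binocular_cue is None else cues.binocular_cue),
        np.asarray(0.0 if cues.haptic_cue is None else cues.haptic_cue),
        cues.image_rate_cue is not None,
        cues.binocular_cue is not None,
        cues.haptic_cue is not None,
    )
    return PosteriorBelief(
        mean_size_rate=float(mean_s),
        var_size_rate=float(var_s),
        mean_distance_rate=float(mean_d),
        var_distance_rate=float(var_d),
    )


def decide(belief: PosteriorBelief, lapse: float, rng) -> str:
    """Map a posterior belief to an 'inflating'/'deflating' judgment.

    With probability ``1 − lapse`` the observer answers by the sign of the
    posterior mean size rate (ties broken uniformly); with probability
    ``lapse`` it answers uniformly at random.
    """
    if not 0.0 <= lapse < 1.0:
        raise ValueError("lapse must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    if rng.random() < lapse:
        return INFLATING if rng.random() < 0.5 else DEFLATING
    mean = belief.mean_size_rate
    if mean == 0.0:
        return INFLATING if rng.random() < 0.5 else DEFLATING
    return INFLATING if mean > 0 else DEFLATING


def predicted_confusion(
    params: ObserverParams, condition: CueCondition, k_img: float
) -> float:
    """Closed-form confusion ratio implied by the posterior-sign rule.

    The posterior mean of ``ṡ`` is linear in the cues; evaluating it at the
    noiseless cue expectations gives ``E[μ_s] = α·ṡ + β·ḋ``, whose zero set
    is the expected discrimination boundary ``ṡ = −(β/α)·ḋ``.  The returned
    value is that slope divided by ``k_img``: 1 when the observer can only
    follow the image cue, 0 in the limit of a perfectly trusted, noiseless
    auxiliary distance cue.
    """
    if k_img <= 0:
        raise ValueError("k_img must be positive")
    has_b = condition.binocular
    has_h = condition.haptic
    # unit stimulus along ṡ: noiseless cues (m_I, m_B, m_H) = (1, 0, 0)
    alpha, _, _, _ = _posterior_arrays(
        params, k_img, 1.0, 0.0, 0.0, True, has_b, has_h
    )
    # unit stimulus along ḋ: noiseless cues (−k, 1, 1)
    beta, _, _, _ = _posterior_arrays(
        params, k_img, -k_img, 1.0, 1.0, True, has_b, has_h
    )
    return float(-beta / alpha / k_img)


class BayesianObserver:
    """Explaining-away observer: sample cues → posterior → sign decision."""

    def __init__(self, params: ObserverParams | None = None):
        self.params = params or ObserverParams()

    def respond_frame(self, trials: pd.DataFrame, rng) -> np.ndarray:
        p = self.params
        rng = np.random.default_rng(rng)
        k = (
            trials["initial_diameter_mm"].to_numpy()
            / trials["initial_distance_mm"].to_numpy()
        )
        s_rate = trials["size_rate_mm_s"].to_numpy()
        d_rate = trials["distance_rate_mm_s"].to_numpy()
        cond = trials["condition"].map(lambda c: CueCondition.parse(c))
        has_b = cond.map(lambda c: c.binocular).to_numpy(dtype=bool)
        has_h = cond.map(lambda c: c.haptic).to_numpy(dtype=bool)
        n = len(trials)
        m_i = s_rate - k * d_rate + rng.normal(0.0, p.sigma_image, size=n)
        m_b = d_rate + rng.normal(0.0, p.sigma_binocular, size=n)
        m_h = d_rate + rng.normal(0.0, p.sigma_haptic, size=n)
        mean_s, _, _, _ = _posterior_arrays(
            p, k, m_i, m_b, m_h, np.ones(n, dtype=bool), has_b, has_h
        )
        return _signal_to_response(mean_s, p.lapse, rng)


class ImageOnlyObserver:
    """Oracle that answers by the sign of the end-to-start image-angle change.

    For linear kinematics the image angle grows over the trial exactly when
    ``ṡ − (s₀/d₀)·ḋ > 0``, so the decision signal is that linearized image
    rate plus a small Gaussian decision noise (mm/s) keeping psychometric
    fits well-posed.
    """

    def __init__(self, decision_noise: float = 1.0, lapse: float = 0.0):
        if decision_noise < 0:
            raise ValueError("decision_noise must be nonnegative")
        self.decision_noise = decision_noise
        self.lapse = lapse

    def respond_frame(self, trials: pd.DataFrame, rng) -> np.ndarray:
        rng = np.random.default_rng(rng)
        k = (
            trials["initial_diameter_mm"].to_numpy()
            / trials["initial_distance_mm"].to_numpy()
        )
        signal = (
            trials["size_rate_mm_s"].to_numpy()
            - k * trials["distance_rate_mm_s"].to_numpy()
            + rng.normal(0.0, self.decision_noise, size=len(trials))
        )
        return _signal_to_response(signal, self.lapse, rng)


class VeridicalObserver:
    """Oracle that answers by the sign of the physical size-change rate."""

    def __init__(self, decision_noise: float = 1.0, lapse: float = 0.0):
        if decision_noise < 0:
            raise ValueError("decision_noise must be nonnegative")
        self.decision_noise = decision_noise
        self.lapse = lapse

    def respond_frame(self, trials: pd.DataFrame, rng) -> np.ndarray:
        rng = np.random.default_rng(rng)
        signal = trials["size_rate_mm_s"].to_numpy() + rng.normal(
            0.0, self.decision_noise, size=len(trials)
        )
        return _signal_to_response(signal, self.lapse, rng)


def image_only_observer(decision_noise: float = 1.0) -> ImageOnlyObserver:
    """Oracle whose pipeline confusion ratio is 1 by construction."""
    return ImageOnlyObserver(decision_noise=decision_noise)


def veridical_observer(decision_noise: float = 1.0) -> VeridicalObserver:
    """Oracle whose pipeline confusion ratio is 0 by construction."""
    return VeridicalObserver(decision_noise=decision_noise)


def _signal_to_response(signal: np.ndarray, lapse: float, rng) -> np.ndarray:
    inflate = signal > 0
    ties = signal == 0
    if np.any(ties):
        inflate = np.where(ties, rng.random(len(signal)) < 0.5, inflate)
    if lapse > 0:
        lapsed = rng.random(len(signal)) < lapse
        inflate = np.where(lapsed, rng.random(len(signal)) < 0.5, inflate)
    return np.where(inflate, INFLATING, DEFLATING)


def _as_observer(observer):
    if isinstance(observer, ObserverParams):
        return BayesianObserver(observer)
    if hasattr(observer, "respond_frame"):
        return observer
    raise TypeError(
        "observer must be ObserverParams or expose a respond_frame method"
    )


def simulate_exp1(grid, observer, seed: int) -> pd.DataFrame:
    """Simulate binary inflating/deflating responses for an Experiment-1 grid.

    ``observer`` may be :class:`ObserverParams` (wrapped in a
    :class:`BayesianObserver`) or any object with a ``respond_frame`` method.
    The response table is fully reproducible from ``seed``.
    """
    trials = grid.trials if isinstance(grid, DesignGrid) else grid
    records = trials.copy()
    rng = np.random.default_rng(seed)
    records["response"] = _as_observer(observer).respond_frame(records, rng)
    return records


def simulate_exp2(design, params: ObserverParams, seed: int) -> pd.DataFrame:
    """Simulate 2IFC which-interval-was-faster responses.

    Each interval's perceived speed is the physical depth speed ``|ḋ|``
    corrupted by the condition's single-cue noise (``sigma_haptic`` for
    H+/B−, ``sigma_binocular`` for H−/B+); the observer reports the interval
    with the larger perceived speed, lapsing at the params' lapse rate.  The
    recorded response is the pressed button, '1st' or '2nd'.
    """
    trials = design.trials if isinstance(design, DesignGrid) else design
    records = trials.copy()
    rng = np.random.default_rng(seed)
    cond = records["condition"].map(lambda c: CueCondition.parse(c))
    sigma = cond.map(
        lambda c: params.sigma_haptic if c.haptic else params.sigma_binocular
    ).to_numpy()
    n = len(records)
    v_std = np.abs(records["standard_mm_s"].to_numpy())
    v_cmp = np.abs(records["comparison_mm_s"].to_numpy())
    percept_std = v_std + rng.normal(0.0, 1.0, size=n) * sigma
    percept_cmp = v_cmp + rng.normal(0.0, 1.0, size=n) * sigma
    cmp_faster = percept_cmp > percept_std
    ties = percept_cmp == percept_std
    if np.any(ties):
        cmp_faster = np.where(ties, rng.random(n) < 0.5, cmp_faster)
    if params.lapse > 0:
        lapsed = rng.random(n) < params.lapse
        cmp_faster = np.where(lapsed, rng.random(n) < 0.5, cmp_faster)
    std_first = records["standard_first"].to_numpy(dtype=bool)
    # comparison occupies the interval the standard does not
    records["response"] = np.where(cmp_faster == std_first, "2nd", "1st")
    records["chose_comparison"] = cmp_faster
    return records
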