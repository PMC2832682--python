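"""Generative model, posterior inference and decision rule of the observer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sizechange as sc
from sizechange.observer import DEFLATING, INFLATING


def _trial(s_rate, d_rate, condition, d0=449.0):
    return sc.TrialSpec(
        size_rate=s_rate,
        distance_rate=d_rate,
        initial_distance=d0,
        condition=condition,
    )


TINY = 1e-9


class TestSampleCues:
    def test_noiseless_limit_returns_exact_cues(self):
        params = sc.ObserverParams(
            sigma_image=TINY, sigma_binocular=TINY, sigma_haptic=TINY
        )
        trial = _trial(4.4, -65.0, sc.CueCondition(True, True))
        cues = sc.sample_cues(trial, params, rng=0)
        k = trial.k_img
        assert cues.image_rate_cue == pytest.approx(4.4 - k * (-65.0), abs=1e-6)
        assert cues.binocular_cue == pytest.approx(-65.0, abs=1e-6)
        assert cues.haptic_cue == pytest.approx(-65.0, abs=1e-6)

    def test_absent_condition_cues_are_none(self):
        params = sc.ObserverParams()
        cues = sc.sample_cues(
            _trial(2.2, 30.0, sc.CueCondition(False, False)), params, rng=0
        )
        assert cues.binocular_cue is None and cues.haptic_cue is None
        cues = sc.sample_cues(
            _trial(2.2, 30.0, sc.CueCondition(True, False)), params, rng=0
        )
        assert cues.haptic_cue is not None and cues.binocular_cue is None

    def test_monte_carlo_mean_matches_noiseless_cue(self):
        params = sc.ObserverParams(sigma_image=2.0, sigma_binocular=13.0)
        trial = _trial(-6.6, 45.5, sc.CueCondition(False, True))
        rng = np.random.default_rng(7)
        n = 10_000
        m_i = np.array(
            [sc.sample_cues(trial, params, rng).image_rate_cue for _ in range(n)]
        )
        expected = -6.6 - trial.k_img * 45.5
        assert abs(m_i.mean() - expected) < 3 * params.sigma_image / np.sqrt(n)


class TestPosterior:
    def test_no_cues_returns_prior(self):
        params = sc.ObserverParams()
        cues = sc.CueSample(None, None, None, k_img=0.078)
        belief = sc.posterior_size_rate(cues, params)
        assert belief.mean_size_rate == 0.0
        assert belief.mean_distance_rate == 0.0
        assert belief.var_size_rate == pytest.approx(
            params.prior_sigma_size_rate**2
        )
        assert belief.var_distance_rate == pytest.approx(
            params.prior_sigma_distance_rate**2
        )

    def test_negating_cues_negates_posterior_means(self):
        params = sc.ObserverParams()
        cues = sc.CueSample(3.1, -40.0, -35.0, k_img=0.078)
        neg = sc.CueSample(-3.1, 40.0, 35.0, k_img=0.078)
        b1 = sc.posterior_size_rate(cues, params)
        b2 = sc.posterior_size_rate(neg, params)
        assert b1.mean_size_rate == pytest.approx(-b2.mean_size_rate)
        assert b1.mean_distance_rate == pytest.approx(-b2.mean_distance_rate)

    def test_perfect_binocular_cue_pins_distance_rate(self):
        """σ_B → 0: posterior ḋ → m_B and (with a flat size prior) ṡ → m_I + k·m_B."""
        params = sc.ObserverParams(
            sigma_binocular=1e-8,
            trust_binocular=1.0,
            prior_sigma_size_rate=1e8,
        )
        k = 0.078
        cues = sc.CueSample(5.0, -60.0, None, k_img=k)
        belief = sc.posterior_size_rate(cues, params)
        assert belief.mean_distance_rate == pytest.approx(-60.0, abs=1e-4)
        assert belief.mean_size_rate == pytest.approx(5.0 + k * -60.0, rel=1e-4)

    def test_matches_dense_grid_numerical_posterior(self):
        """Analytic 2x2 conditioning agrees with brute-force numerical Bayes."""
        params = sc.ObserverParams(
            sigma_image=3.0,
            sigma_binocular=15.0,
            sigma_haptic=20.0,
            prior_sigma_distance_rate=40.0,
            prior_sigma_size_rate=25.0,
            trust_binocular=0.8,
            trust_haptic=0.5,
        )
        k = 0.08
        cues = sc.CueSample(4.0, -50.0, -70.0, k_img=k)
        s = np.linspace(-120, 120, 481)
        d = np.linspace(-250, 250, 501)
        S, D = np.meshgrid(s, d, indexing="ij")
        logp = (
            -0.5 * (S / params.prior_sigma_size_rate) ** 2
            - 0.5 * (D / params.prior_sigma_distance_rate) ** 2
            - 0.5 * ((cues.image_rate_cue - (S - k * D)) / params.sigma_image) ** 2
            - 0.5
            * ((cues.binocular_cue - D) ** 2)
            / (params.sigma_binocular**2 / params.trust_binocular)
            - 0.5
            * ((cues.haptic_cue - D) ** 2)
            / (params.sigma_haptic**2 / params.trust_haptic)
        )
        w = np.exp(logp - logp.max())
        w /= w.sum()
        mean_s, mean_d = (w * S).sum(), (w * D).sum()
        var_s = (w * (S - mean_s) ** 2).sum()
        var_d = (w * (D - mean_d) ** 2).sum()
        belief = sc.posterior_size_rate(cues, params)
        assert belief.mean_size_rate == pytest.approx(mean_s, abs=0.05)
        assert belief.mean_distance_rate == pytest.approx(mean_d, abs=0.1)
        assert belief.var_size_rate == pytest.approx(var_s, rel=0.02)
        assert belief.var_distance_rate == pytest.approx(var_d, rel=0.02)

    @given(
        sigma_b=st.floats(1.0, 50.0),
        sigma_h=st.floats(1.0, 50.0),
        trust_b=st.floats(0.1, 1.0),
        m_b=st.floats(-100, 100),
        m_i=st.floats(-20, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_posterior_variance_never_exceeds_prior(
        self, sigma_b, sigma_h, trust_b, m_b, m_i
    ):
        params = sc.ObserverParams(
            sigma_binocular=sigma_b, sigma_haptic=sigma_h, trust_binocular=trust_b
        )
        cues = sc.CueSample(m_i, m_b, m_b, k_img=0.078)
        belief = sc.posterior_size_rate(cues, params)
        assert belief.var_size_rate <= params.prior_sigma_size_rate**2 + 1e-9
        assert (
            belief.var_distance_rate <= params.prior_sigma_distance_rate**2 + 1e-9
        )

    def test_adding_any_cue_reduces_size_rate_variance(self):
        params = sc.ObserverParams()
        k = 0.078
        base = sc.posterior_size_rate(sc.CueSample(2.0, None, None, k), params)
        with_b = sc.posterior_size_rate(sc.CueSample(2.0, -30.0, None, k), params)
        with_bh = sc.posterior_size_rate(sc.CueSample(2.0, -30.0, -30.0, k), params)
        assert with_b.var_size_rate <= base.var_size_rate
        assert with_bh.var_size_rate <= with_b.var_size_rate


class TestDecide:
    def test_sign_rule_without_lapse(self):
        belief = sc.PosteriorBelief(5.0, 1.0, 0.0, 1.0)
        assert sc.decide(belief, 0.0, rng=0) == INFLATING
        belief = sc.PosteriorBelief(-0.4, 1.0, 0.0, 1.0)
        assert sc.decide(belief, 0.0, rng=0) == DEFLATING

    def test_half_lapse_gives_three_quarter_mixture(self):
        belief = sc.PosteriorBelief(50.0, 1.0, 0.0, 1.0)
        rng = np.random.default_rng(3)
        n = 20_000
        inflating = sum(sc.decide(belief, 0.5, rng) == INFLATING for _ in range(n))
        assert inflating / n == pytest.approx(0.75, abs=0.01)

    def test_tied_belief_splits_evenly(self):
        belief = sc.PosteriorBelief(0.0, 1.0, 0.0, 1.0)
        rng = np.random.default_rng(4)
        n = 20_000
        inflating = sum(sc.decide(belief, 0.0, rng) == INFLATING for _ in range(n))
        assert inflating / n == pytest.approx(0.5, abs=0.01)


class TestSimulateExp1:
    def test_identical_seed_identical_table(self, small_grid):
        params = sc.ObserverParams()
        a = sc.simulate_exp1(small_grid, params, seed=77)
        b = sc.simulate_exp1(small_grid, params, seed=77)
        assert a.equals(b)

    def test_strong_inflation_signal_dominates(self, hb_none):
        grid = sc.build_exp1_grid(
            repeats=50,
            conditions=[hb_none],
            seed=1,
            pedestals=(0.0,),
            satellites=(0.0,),
            size_rates=(11.0,),
        )
        params = sc.ObserverParams(sigma_image=0.5, lapse=0.0)
        rec = sc.simulate_exp1(grid, params, seed=2)
        assert (rec["response"] == INFLATING).mean() == 1.0


class TestSimulateExp2:
    def test_noiseless_observer_picks_faster_interval(self, exp2_design_haptic):
        params = sc.ObserverParams(sigma_haptic=TINY, lapse=0.0)
        rec = sc.simulate_exp2(exp2_design_haptic, params, seed=5)
        nonzero = rec[rec["offset_mm_s"] != 0]
        faster = (
            nonzero["comparison_mm_s"].abs() > nonzero["standard_mm_s"].abs()
        )
        assert (nonzero["chose_comparison"] == faster).all()

    def test_equal_speeds_split_evenly(self, haptic_only):
        design = sc.build_exp2_design(
            repeats=3000, condition=haptic_only, seed=0, offsets=(0.0,)
        )
        params = sc.ObserverParams(sigma_haptic=13.0, lapse=0.0)
        rec = sc.simulate_exp2(design, params, seed=6)
        assert rec["chose_comparison"].mean() == pytest.approx(0.5, abs=0.02)

    def test_fitted_jnd_is_sqrt2_times_sigma(self, haptic_only):
        design = sc.build_exp2_design(repeats=750, condition=haptic_only, seed=1)
        params = sc.ObserverParams(sigma_haptic=13.0, lapse=0.0)
        rec = sc.simulate_exp2(design, params, seed=9)
        fits = [sc.fit_2ifc(rec, std) for std in (-55.0, 55.0)]
        jnd_mean = np.mean([sc.jnd(f) for f in fits])
        assert jnd_mean == pytest.approx(13.0 * np.sqrt(2.0), rel=0.05)

    def test_determinism(self, exp2_design_haptic):
        params = sc.ObserverParams()
        a = sc.simulate_exp2(exp2_design_haptic, params, seed=8)
        b = sc.simulate_exp2(exp2_design_haptic, params, seed=8)
        assert a.equals(b)


class TestPredictedConfusion:
    def test_no_auxiliary_cues_gives_confusion_one(self):
        k = sc.default_k_img()
        conf = sc.predicted_confusion(
            sc.ObserverParams(), sc.CueCondition(False, False), k
        )
        assert conf == pytest.approx(1.0, abs=1e-12)

    def test_perfect_auxiliary_cue_gives_zero(self):
        k = sc.default_k_img()
        params = sc.ObserverParams(sigma_binocular=1e-6, trust_binocular=1.0)
        conf = sc.predicted_confusion(params, sc.CueCondition(False, True), k)
        assert conf == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_cues_predict_equal_confusion(self):
        k = sc.default_k_img()
        params = sc.ObserverParams(
            sigma_binocular=15.0,
            sigma_haptic=15.0,
            trust_binocular=0.7,
            trust_haptic=0.7,
        )
        c_h = sc.predicted_confusion(params, sc.CueCondition(True, False), k)
        c_b = sc.predicted_confusion(params, sc.CueCondition(False, True), k)
        assert c_h == pytest.approx(c_b)

    @given(
        sigma_b=st.floats(2.0, 60.0),
        sigma_h=st.floats(2.0, 60.0),
        trust_b=st.floats(0.05, 1.0),
        trust_h=st.floats(0.05, 1.0),
        prior_d=st.floats(5.0, 100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_precision_ratio_closed_form(
        self, sigma_b, sigma_h, trust_b, trust_h, prior_d
    ):
        """Independent derivation: confusion = p_d / (p_d + Σ trust_j/σ_j²),
        the prior ḋ precision over the total ḋ precision."""
        params = sc.ObserverParams(
            sigma_binocular=sigma_b,
            sigma_haptic=sigma_h,
            trust_binocular=trust_b,
            trust_haptic=trust_h,
            prior_sigma_distance_rate=prior_d,
        )
        k = sc.default_k_img()
        p_d = 1.0 / prior_d**2
        for cond in sc.CueCondition.all_conditions():
            q = cond.binocular * trust_b / sigma_b**2
            q += cond.haptic * trust_h / sigma_h**2
            expected = p_d / (p_d + q)
            got = sc.predicted_confusion(params, cond, k)
            assert got == pytest.approx(expected, rel=1e-9)
            assert -1e-9 <= got <= 1.0 + 1e-9

    def test_monotone_in_auxiliary_reliability_and_trust(self):
        k = sc.default_k_img()
        cond = sc.CueCondition(False, True)
        sigmas = [40.0, 20.0, 10.0, 5.0]
        confs = [
            sc.predicted_confusion(
                sc.ObserverParams(sigma_binocular=s), cond, k
            )
            for s in sigmas
        ]
        assert all(a > b for a, b in zip(confs, confs[1:]))
        trusts = [0.1, 0.4, 0.7, 1.0]
        confs = [
            sc.predicted_confusion(
                sc.ObserverParams(trust_binocular=w), cond, k
            )
            for w in trusts
        ]
        assert all(a > b for a, b in zip(confs, confs[1:]))


class TestOracleObservers:
    def test_image_only_calls_approach_inflating(self, hb_none):
        grid = sc.build_exp1_grid(
            repeats=200,
            conditions=[hb_none],
            seed=3,
            pedestals=(-71.5,),
            satellites=(0.0,),
            size_rates=(0.0,),
        )
        rec = sc.simulate_exp1(grid, sc.image_only_observer(0.5), seed=4)
        assert (rec["response"] == INFLATING).mean() > 0.99

    def test_veridical_follows_size_rate_sign(self, hb_none):
        grid = sc.build_exp1_grid(
            repeats=200,
            conditions=[hb_none],
            seed=3,
            pedestals=(-71.5, 71.5),
            satellites=(0.0,),
            size_rates=(-2.2,),
        )
        rec = sc.simulate_exp1(grid, sc.veridical_observer(0.5), seed=4)
        assert (rec["response"] == DEFLATING).mean() > 0.95

    def test_oracles_agree_when_image_and_size_share_sign(self, hb_none):
        grid = sc.build_exp1_grid(
            repeats=20,
            conditions=[hb_none],
            seed=3,
            pedestals=(71.5,),  # receding: image shrinks unless inflating fast
            satellites=(0.0,),
            size_rates=(-11.0,),
        )
        img = sc.simulate_exp1(grid, sc.image_only_observer(1e-9), seed=5)
        ver = sc.simulate_exp1(grid, sc.veridical_observer(1e-9), seed=6)
        assert (img["response"] == ver["response"]).all()
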