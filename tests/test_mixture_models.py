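"""CA/IA surface predictions, deviation algebra, joint fitting and the
likelihood-ratio ladder."""

import math

import numpy as np
import pytest
from scipy import stats

from mixtoxsys.exceptions import NumericalError, ValidationError
from mixtoxsys.mixture_models import (
    CA,
    DL,
    DR,
    IA,
    NONE,
    SA,
    SurfaceParams,
    classify_interaction,
    deviation_G,
    fit_surface,
    lr_test,
    predict_ca,
    predict_ia,
    predict_surface,
    to_decreasing,
    verdict_from_evidence,
)
from mixtoxsys.synthetic_data import gen_mixture_ray


def random_surface(rng, deviation=NONE, a=None, b=None):
    return SurfaceParams(
        theta_max=rng.uniform(50, 150),
        ec50_1=rng.uniform(0.1, 5),
        beta_1=rng.uniform(0.5, 4),
        ec50_2=rng.uniform(0.1, 5),
        beta_2=rng.uniform(0.5, 4),
        deviation=deviation,
        a=a,
        b=b,
    )


class TestDeviationG:
    def test_reference_recovery_at_zero(self):
        assert deviation_G(0.0, None, 0.3, 0.7, 1.0, SA) == 0.0
        assert deviation_G(None, None, 0.3, 0.7, 1.0, NONE) == 0.0

    def test_sa_closed_form(self):
        assert deviation_G(2.0, None, 0.5, 0.5, 1.0, SA) == pytest.approx(0.5)

    def test_dr_closed_form(self):
        assert deviation_G(1.0, 2.0, 0.25, 0.75, 1.0, DR) == pytest.approx(
            (1.0 + 2.0 * 0.25) * 0.25 * 0.75
        )

    def test_dl_sign_change_at_one_over_b(self):
        """Brute-force scan: the DL deviation flips sign exactly at TU = 1/b."""
        a, b = 2.0, 1.0
        tus = np.linspace(0.01, 3, 300)
        g = deviation_G(a, b, 0.5, 0.5, tus, DL)
        assert deviation_G(a, b, 0.5, 0.5, 1.0, DL) == pytest.approx(0.0)
        assert np.all(g[tus < 1.0] > 0) and np.all(g[tus > 1.0] < 0)

    def test_missing_b_rejected(self):
        with pytest.raises(ValidationError):
            deviation_G(1.0, None, 0.5, 0.5, 1.0, DL)


class TestPredictCA:
    def test_sham_combination_depends_only_on_total(self):
        """Two copies of the same chemical act as a dilution of itself."""
        p = SurfaceParams(theta_max=100, ec50_1=1.0, beta_1=2.0, ec50_2=1.0, beta_2=2.0)
        assert predict_ca(p, 0.5, 0.5) == pytest.approx(50.0, abs=1e-8)
        splits = [(0.1, 0.9), (0.3, 0.7), (0.25, 0.75)]
        vals = [predict_ca(p, c1, c2) for c1, c2 in splits]
        assert np.allclose(vals, vals[0], atol=1e-8)

    def test_axis_reduction_to_single_chemical(self, lms_like_surface, rng):
        from mixtoxsys.doseresponse import DoseResponseModel

        m1 = DoseResponseModel(theta_max=100.0, ec50=0.77, beta=2.0)
        for c in rng.uniform(0.01, 5, size=10):
            assert predict_ca(lms_like_surface, c, 0.0) == pytest.approx(
                m1.predict(c), abs=1e-8
            )

    def test_control_returns_plateau(self, lms_like_surface):
        assert predict_ca(lms_like_surface, 0.0, 0.0) == 100.0

    def test_antagonistic_deviation_raises_surface(self, lms_like_surface, rng):
        dev = SurfaceParams(
            theta_max=100.0, ec50_1=0.77, beta_1=2.0, ec50_2=4.5, beta_2=1.5,
            deviation=SA, a=3.0,
        )
        c1 = rng.uniform(0.05, 2.0, 100)
        c2 = rng.uniform(0.2, 9.0, 100)
        assert np.all(predict_ca(dev, c1, c2) > predict_ca(lms_like_surface, c1, c2))

    def test_reference_equals_sa_with_a_zero(self, rng):
        for _ in range(10):
            ref = random_surface(rng)
            sa = SurfaceParams(**{**vars(ref), "deviation": SA, "a": 0.0})
            c1 = rng.uniform(0, 5, 20)
            c2 = rng.uniform(0, 5, 20)
            assert np.allclose(predict_ca(ref, c1, c2), predict_ca(sa, c1, c2), atol=1e-10)


class TestPredictIA:
    def test_plateau_and_independence_product(self):
        p = SurfaceParams(theta_max=100, ec50_1=1.0, beta_1=2.0, ec50_2=1.0, beta_2=2.0)
        assert predict_ia(p, 0, 0) == pytest.approx(100.0)
        # q1 = q2 = 0.5 at the EC50s
        assert predict_ia(p, 1.0, 1.0) == pytest.approx(25.0)

    def test_antagonism_power_transform_closed_form(self):
        # G = ln 2 turns q1*q2 = 0.25 into 0.25^(1/2) = 0.5
        a = math.log(2.0) / 0.25  # z1 = z2 = 0.5 -> G = a/4
        p = SurfaceParams(theta_max=100, ec50_1=1.0, beta_1=2.0, ec50_2=1.0, beta_2=2.0,
                          deviation=SA, a=a)
        assert predict_ia(p, 1.0, 1.0) == pytest.approx(50.0)

    def test_axis_reduction(self, rng):
        p = random_surface(rng, deviation=SA, a=rng.normal())
        from mixtoxsys.doseresponse import DoseResponseModel

        m2 = DoseResponseModel(theta_max=p.theta_max, ec50=p.ec50_2, beta=p.beta_2)
        for c in rng.uniform(0.01, 5, size=10):
            assert predict_ia(p, 0.0, c) == pytest.approx(m2.predict(c), abs=1e-8)

    def test_bounded_between_zero_and_plateau(self, rng):
        for _ in range(10):
            p = random_surface(rng, deviation=SA, a=rng.normal(scale=4))
            y = predict_ia(p, rng.uniform(0, 10, 50), rng.uniform(0, 10, 50))
            assert np.all((y >= 0) & (y <= p.theta_max + 1e-12))

    def test_sign_convention_both_frameworks(self, rng):
        """a > 0 lifts the interior surface above the reference for CA and IA."""
        for _ in range(10):
            ref = random_surface(rng)
            dev = SurfaceParams(**{**vars(ref), "deviation": SA, "a": rng.uniform(0.5, 5)})
            c1 = rng.uniform(0.2, 4, 30) * ref.ec50_1
            c2 = rng.uniform(0.2, 4, 30) * ref.ec50_2
            assert np.all(predict_ca(dev, c1, c2) >= predict_ca(ref, c1, c2) - 1e-9)
            assert np.all(predict_ia(dev, c1, c2) >= predict_ia(ref, c1, c2) - 1e-9)


class TestFitSurface:
    def test_noise_free_reference_self_consistency(self, lms_like_surface):
        df, _ = gen_mixture_ray(lms_like_surface, CA, noise_sd=0.0, seed=0)
        fit = fit_surface(df, CA)
        assert fit.ss_res < 1e-10
        assert fit.params.ec50_1 == pytest.approx(0.77, abs=1e-4)
        assert fit.params.beta_1 == pytest.approx(2.0, abs=1e-4)
        assert fit.params.ec50_2 == pytest.approx(4.5, abs=1e-3)
        assert fit.params.theta_max == pytest.approx(100.0, abs=1e-4)

    def test_noise_free_ia_self_consistency(self, lms_like_surface):
        df, _ = gen_mixture_ray(lms_like_surface, IA, noise_sd=0.0, seed=0)
        fit = fit_surface(df, IA)
        assert fit.ss_res < 1e-10

    def test_too_few_points_rejected(self, lms_like_surface):
        df, _ = gen_mixture_ray(lms_like_surface, CA, noise_sd=0.0, seed=0)
        with pytest.raises(ValidationError):
            fit_surface(df.head(5), CA)

    def test_deviation_fit_requires_interior_points(self, lms_like_surface):
        df, _ = gen_mixture_ray(lms_like_surface, CA, noise_sd=0.0, seed=0)
        axes_only = df[(df.c1 == 0) | (df.c2 == 0)]
        with pytest.raises(ValidationError):
            fit_surface(axes_only, CA, SA)

    def test_nesting_of_residuals(self, lms_like_surface):
        df, _ = gen_mixture_ray(lms_like_surface, CA, noise_sd=5.0, seed=11)
        ref = fit_surface(df, CA)
        sa = fit_surface(df, CA, SA, warm_start=ref)
        dl_seed = SurfaceParams(**{**vars(sa.params), "deviation": DL, "b": 0.0})
        from mixtoxsys.mixture_models import fit_sa_as_dl

        dl = fit_surface(df, CA, DL, warm_start=fit_sa_as_dl(sa, dl_seed))
        assert ref.ss_res >= sa.ss_res - 1e-9
        assert sa.ss_res >= dl.ss_res - 1e-9

    def test_loglik_matches_profiled_gaussian_formula(self, lms_like_surface):
        df, _ = gen_mixture_ray(lms_like_surface, CA, noise_sd=5.0, seed=3)
        fit = fit_surface(df, CA)
        expected = -(fit.n / 2) * (math.log(2 * math.pi * fit.ss_res / fit.n) + 1)
        assert fit.log_lik == pytest.approx(expected)


class TestLRTest:
    def _fake_fit(self, ss, n, k):
        p = SurfaceParams(theta_max=100, ec50_1=1, beta_1=1, ec50_2=1, beta_2=1)
        from mixtoxsys.mixture_models import SurfaceFit

        return SurfaceFit(model_type=CA, params=p, ss_res=ss, ss_tot=ss * 2, n=n,
                          k_params=k, log_lik=0.0, r2=0.5)

    def test_equal_ss_gives_p_one(self):
        res = lr_test(self._fake_fit(10.0, 50, 5), self._fake_fit(10.0, 50, 6))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_chi2_against_normal_tail_identity(self):
        """For df = 1, the chi-square tail equals 2*(1 - Phi(sqrt(chi2)))."""
        res = lr_test(self._fake_fit(1.5, 100, 5), self._fake_fit(1.0, 100, 6))
        assert res.chi2 == pytest.approx(100 * math.log(1.5), rel=1e-12)
        expected_p = 2 * stats.norm.sf(math.sqrt(res.chi2))
        assert res.p == pytest.approx(expected_p, rel=1e-9)
        assert res.p == pytest.approx(1.9e-10, rel=0.05)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValidationError):
            lr_test(self._fake_fit(2.0, 50, 5), self._fake_fit(1.0, 60, 6))

    def test_wrong_nesting_order_rejected(self):
        with pytest.raises(ValidationError):
            lr_test(self._fake_fit(1.0, 50, 6), self._fake_fit(2.0, 50, 5))


class TestClassification:
    def test_published_evidence_replay(self):
        """The printed LMS ladder outcome: significant antagonistic deviation,
        no dose-level dependence."""
        from mixtoxsys.datasets import surface_test_evidence

        ev = surface_test_evidence()
        verdict = verdict_from_evidence(
            ev["p_ref_vs_A"], ev["p_A_vs_DL"], ev["a_hat_sign"], framework=ev["framework"]
        )
        assert verdict.pattern == "antagonism"
        assert verdict.dose_level_dependent is False

    def test_synergism_rule(self):
        v = verdict_from_evidence(1e-4, 0.01, -2.0)
        assert v.pattern == "synergism" and v.dose_level_dependent

    def test_no_interaction_rule(self):
        v = verdict_from_evidence(0.4, None, 1.0)
        assert v.pattern == "no_interaction" and not v.dose_level_dependent

    def test_full_ladder_on_antagonistic_data(self, rng):
        truth = SurfaceParams(theta_max=100.0, ec50_1=0.77, beta_1=2.0,
                              ec50_2=4.5, beta_2=1.5, deviation=SA, a=4.0)
        df, _ = gen_mixture_ray(truth, CA, noise_sd=3.0, seed=99)
        analysis = classify_interaction(df, CA)
        assert analysis.verdict.pattern == "antagonism"
        assert analysis.fit_sa.params.a > 0
        report = analysis.to_report()
        assert set(report) >= {"framework", "fit_ref", "ref_vs_A", "A_vs_DL", "verdict"}

    def test_increasing_endpoint_conversion(self):
        y = np.array([1.0, 2.0, 5.0])
        flipped, ceiling = to_decreasing(y)
        assert ceiling == 5.0
        assert np.allclose(flipped, [4.0, 3.0, 0.0])


class TestBruteForceOracle:
    def test_ca_root_agrees_with_grid_refinement(self, rng):
        """Independent oracle: 3-stage grid refinement of the monotone
        toxic-unit-sum equation, no bisection logic shared."""
        for _ in range(20):
            p = random_surface(rng, deviation=SA, a=rng.normal(scale=2))
            c1 = rng.uniform(0.1, 3) * p.ec50_1
            c2 = rng.uniform(0.1, 3) * p.ec50_2
            t1, t2 = c1 / p.ec50_1, c2 / p.ec50_2
            tu = t1 + t2
            g = p.a * (t1 / tu) * (t2 / tu)
            target = math.exp(g)

            def tu_sum(y):
                ratio = (p.theta_max - y) / y
                return (c1 / (p.ec50_1 * ratio ** (1 / p.beta_1))
                        + c2 / (p.ec50_2 * ratio ** (1 / p.beta_2)))

            lo, hi = 1e-9 * p.theta_max, p.theta_max * (1 - 1e-9)
            for _stage in range(4):
                ys = np.linspace(lo, hi, 1000)
                vals = np.array([tu_sum(y) for y in ys]) - target
                idx = int(np.searchsorted(vals > 0, True))
                lo, hi = ys[max(idx - 1, 0)], ys[min(idx, 999)]
            oracle = 0.5 * (lo + hi)
            assert predict_ca(p, c1, c2) == pytest.approx(oracle, abs=1e-6 * p.theta_max)
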