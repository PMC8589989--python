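"""FRAP normalization, half-recovery, model fitting, and diagnostics."""

import math

import numpy as np
import pytest

from dsbkinetics.frap import (
    DegenerateDenominatorError,
    FrapRecord,
    HalfRecoveryNotReached,
    NormalizedFrapCurve,
    assess_single_population_adequacy,
    fit_frap,
    half_recovery_time,
    koff_area_independence,
    normalize_frap,
)
from dsbkinetics.models import (
    DiffusionFrapParams,
    ReactionFrapParams,
    reaction_frap,
    soumpasis_frap,
)


def make_record(time, roi, reference, background, bleach_index, **kw):
    return FrapRecord(
        time=np.asarray(time, float),
        roi_trace=np.asarray(roi, float),
        reference_trace=np.asarray(reference, float),
        background_trace=np.asarray(background, float)
        if np.ndim(background)
        else np.full(len(time), float(background)),
        bleach_index=bleach_index,
        **kw,
    )


class TestNormalizeFrap:
    def test_constant_traces_give_unit_curve(self):
        n = 50
        rec = make_record(np.arange(n), [200.0] * n, [400.0] * n, 0.0, 10)
        curve = normalize_frap(rec)
        np.testing.assert_allclose(curve.value, 1.0, atol=1e-12)
        assert curve.time_post_bleach[0] == 0.0

    def test_half_drop_gives_half_plateau(self):
        n = 40
        roi = np.r_[np.full(10, 200.0), np.full(30, 100.0)]
        rec = make_record(np.arange(n), roi, np.full(n, 400.0), 0.0, 10)
        curve = normalize_frap(rec)
        np.testing.assert_allclose(curve.value, 0.5, atol=1e-12)

    def test_acquisition_bleaching_cancels_exactly(self):
        # reference decays as g(t); roi = 0.5 * g(t) * prebleach level after bleach
        n, b = 60, 12
        t = np.arange(n, dtype=float)
        g = np.exp(-0.01 * t)
        roi = 300.0 * g.copy()
        roi[b:] = 0.5 * 300.0 * g[b:]
        rec = make_record(t, roi, 600.0 * g, 0.0, b)
        curve = normalize_frap(rec)
        np.testing.assert_allclose(curve.value, 0.5, atol=1e-12)

    def test_invariant_under_common_rescaling_and_offset(self):
        rng = np.random.default_rng(0)
        n, b = 80, 15
        t = np.arange(n, dtype=float)
        roi = 100 + rng.uniform(0, 20, n)
        ref = 250 + rng.uniform(0, 20, n)
        bg = np.full(n, 12.0)
        base = normalize_frap(make_record(t, roi, ref, bg, b)).value
        gain = 3.7
        scaled = normalize_frap(make_record(t, gain * roi, gain * ref, gain * bg, b)).value
        np.testing.assert_allclose(scaled, base, rtol=1e-12)
        # time-varying factor common to roi and reference also cancels
        f = 1.0 + 0.3 * np.sin(t / 9.0)
        warped = normalize_frap(make_record(t, roi * f, ref * f, 0.0, b)).value
        clean = normalize_frap(make_record(t, roi, ref, 0.0, b)).value
        np.testing.assert_allclose(warped, clean, rtol=1e-12)

    def test_degenerate_reference_names_frame(self):
        n = 30
        ref = np.full(n, 100.0)
        ref[17] = 5.0
        rec = make_record(np.arange(n), np.full(n, 50.0), ref, 10.0, 5)
        with pytest.raises(DegenerateDenominatorError, match="frame 17"):
            normalize_frap(rec)

    def test_requires_prebleach_frames(self):
        with pytest.raises(ValueError):
            make_record(np.arange(10), np.ones(10), np.ones(10), 0.0, 0)

    def test_prebleach_frame_count_selects_window(self):
        n, b = 20, 10
        roi = np.r_[np.linspace(100, 200, b), np.full(n - b, 90.0)]
        rec = make_record(np.arange(n), roi, np.full(n, 400.0), 0.0, b)
        all_mean = normalize_frap(rec, "all").prebleach_mean
        last3 = normalize_frap(rec, 3).prebleach_mean
        assert last3 > all_mean  # ramp rising into the bleach


class TestHalfRecoveryTime:
    def test_reaction_curve_half_time_is_ln2_over_koff(self):
        for k_on in (0.05, 0.3, 1.0):
            for k_off in (0.05, 0.1, 0.5):
                t = np.linspace(0, 120, 4000)
                v = reaction_frap(t, ReactionFrapParams(k_on, k_off))
                curve = NormalizedFrapCurve(time_post_bleach=t, value=v)
                expected = math.log(2) / k_off
                assert half_recovery_time(curve) == pytest.approx(expected, rel=5e-3)

    def test_linear_recovery_crosses_at_midpoint(self):
        t = np.linspace(0, 8, 9)
        v = 0.2 + 0.1 * t  # 0.2 -> 1.0 over 8 s, half level 0.6 at t = 4
        curve = NormalizedFrapCurve(time_post_bleach=t, value=v)
        assert half_recovery_time(curve) == pytest.approx(4.0, abs=1e-12)

    def test_flat_curve_is_not_reached(self):
        curve = NormalizedFrapCurve(
            time_post_bleach=np.linspace(0, 10, 20), value=np.full(20, 0.2)
        )
        with pytest.raises(HalfRecoveryNotReached):
            half_recovery_time(curve)


def synthetic_curve(model_id, n=200, t_max=60.0, noise=0.0, seed=0, **params):
    t = np.linspace(0, t_max, n)
    if model_id == "reaction":
        v = reaction_frap(t, ReactionFrapParams(**params))
    else:
        v = soumpasis_frap(np.maximum(t, 1e-12), DiffusionFrapParams(**params))
        v[0] = 0.0
    if noise:
        v = v + np.random.default_rng(seed).normal(0, noise, n)
    return NormalizedFrapCurve(time_post_bleach=t, value=v)


class TestFitFrap:
    def test_reaction_noiseless_self_consistency(self):
        curve = synthetic_curve("reaction", k_on_prime=0.3, k_off=0.1)
        fit = fit_frap(curve, "reaction", fit_window_start=0.0)
        assert fit.params.k_on_prime == pytest.approx(0.3, rel=1e-6)
        assert fit.params.k_off == pytest.approx(0.1, rel=1e-6)

    def test_diffusion_noiseless_self_consistency(self):
        curve = synthetic_curve("diffusion", tau_D=2.5)
        fit = fit_frap(curve, "diffusion")
        assert fit.params.tau_D == pytest.approx(2.5, rel=1e-6)
        assert fit.bleach_depth_scale == pytest.approx(1.0, rel=1e-6)

    def test_reaction_with_noise_recovers_within_ten_percent(self):
        curve = synthetic_curve(
            "reaction", k_on_prime=0.3, k_off=0.1, noise=0.02, seed=7
        )
        fit = fit_frap(curve, "reaction", fit_window_start=3.0)
        assert fit.params.k_off == pytest.approx(0.1, rel=0.10)
        assert fit.params.k_on_prime == pytest.approx(0.3, rel=0.25)

    def test_default_window_is_three_seconds_for_reaction(self):
        curve = synthetic_curve("reaction", k_on_prime=0.3, k_off=0.1)
        fit = fit_frap(curve, "reaction")
        assert fit.fit_window[0] >= 3.0

    def test_deterministic(self):
        curve = synthetic_curve("reaction", k_on_prime=0.2, k_off=0.15, noise=0.05, seed=3)
        f1 = fit_frap(curve, "reaction")
        f2 = fit_frap(curve, "reaction")
        assert f1.params == f2.params

    def test_window_excluding_all_data_rejected(self):
        curve = synthetic_curve("reaction", k_on_prime=0.3, k_off=0.1, t_max=10.0)
        with pytest.raises(ValueError):
            fit_frap(curve, "reaction", fit_window_start=100.0)

    def test_too_few_points_rejected(self):
        curve = synthetic_curve("reaction", n=30, t_max=60.0, k_on_prime=0.3, k_off=0.1)
        with pytest.raises(ValueError, match=">= 10 points"):
            fit_frap(curve, "reaction", fit_window_start=45.0)


class TestAdequacy:
    def test_correct_model_is_adequate(self):
        curve = synthetic_curve("reaction", k_on_prime=0.3, k_off=0.1, noise=0.01, seed=1)
        fit = fit_frap(curve, "reaction", fit_window_start=0.0)
        (rep,) = assess_single_population_adequacy(curve, [fit], noise_scale=0.01)
        assert rep.adequate
        assert rep.runs_test_p >= 0.01

    def test_two_component_mixture_rejects_single_models(self):
        # mixture of two reaction components with very different rates
        t = np.linspace(0, 60, 240)
        slow = reaction_frap(t, ReactionFrapParams(0.6, 0.05))
        fast = reaction_frap(t, ReactionFrapParams(0.6, 1.5))
        v = 0.5 * slow + 0.5 * fast + np.random.default_rng(5).normal(0, 0.005, t.size)
        curve = NormalizedFrapCurve(time_post_bleach=t, value=v)
        reports = assess_single_population_adequacy(
            curve,
            [
                fit_frap(curve, "reaction", fit_window_start=0.0),
                fit_frap(curve, "diffusion", fit_window_start=0.0),
            ],
            noise_scale=0.005,
        )
        assert all(not r.adequate for r in reports)
        assert any("structured-residuals" in r.flags or "chi-square-excess" in r.flags
                   for r in reports)

    def test_pure_noise_flagged_by_recovery_sanity_check(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 60, 240)
        v = 0.5 + rng.normal(0, 0.01, t.size)
        curve = NormalizedFrapCurve(time_post_bleach=t, value=v)
        fit = fit_frap(curve, "reaction", fit_window_start=0.0)
        (rep,) = assess_single_population_adequacy(curve, [fit], noise_scale=0.01)
        assert not rep.adequate
        assert "no-recovery-signal" in rep.flags


def _fit_with_area(k_off, area, seed=0, noise=0.01):
    curve = synthetic_curve(
        "reaction", k_on_prime=0.3, k_off=k_off, noise=noise, seed=seed
    )
    curve.bleach_area = area
    return fit_frap(curve, "reaction")


class TestKoffAreaIndependence:
    def test_identical_rates_across_areas_pass(self):
        fits = [
            _fit_with_area(0.1, a, seed=int(10 * a) + i)
            for a in (1.0, 2.0, 4.0)
            for i in range(3)
        ]
        rep = koff_area_independence(fits)
        assert rep.passed
        assert rep.slope_ci[0] <= 0.0 <= rep.slope_ci[1]

    def test_doubled_koff_in_large_area_fails(self):
        fits = [_fit_with_area(0.1, 1.0, seed=i) for i in range(4)]
        fits += [_fit_with_area(0.2, 4.0, seed=100 + i) for i in range(4)]
        rep = koff_area_independence(fits)
        assert not rep.passed

    def test_single_area_group_rejected(self):
        fits = [_fit_with_area(0.1, 1.0, seed=i) for i in range(6)]
        with pytest.raises(ValueError, match="distinct bleach areas"):
            koff_area_independence(fits)

    def test_small_groups_rejected(self):
        fits = [_fit_with_area(0.1, 1.0, seed=1), _fit_with_area(0.1, 4.0, seed=2)]
        with pytest.raises(ValueError, match=">= 3 fits"):
            koff_area_independence(fits)
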