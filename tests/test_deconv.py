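"""Numerical deconvolution and its convolution adjoint."""

import numpy as np
import pytest

from ivivc.deconv import (
    AbsorptionProfile,
    convolve,
    deconvolve,
    mean_absorption_profile,
)
from ivivc.errors import DeconvolutionError, ProfileError
from ivivc.simulate import PLASMA_TIMES, generate_study, paper_like_spec
from ivivc.uir import UIRModel

from .conftest import make_profile

T_OBS = np.array(PLASMA_TIMES)


def _mono_uir(alpha=0.1, coeff=1.0, subject="S01"):
    return UIRModel(subject, [coeff], [alpha], ka=3.0, t_lag=0.0,
                    aic=0.0, sse=0.0, r2=1.0, dose_ref=1.0)


def test_step_input_round_trip_exact():
    """A step Fa is exactly representable by the piecewise-constant input:
    forward-convolve a known step, deconvolve, recover within 1e-3."""
    uir = _mono_uir()
    dose = 30.0
    # step: all absorbed at constant rate over (0, 2], then flat at 0.8
    fa_true = np.where(T_OBS >= 2.0, 0.8, 0.8 * T_OBS / 2.0)
    fa_prof = AbsorptionProfile("S01", "X", T_OBS, fa_true, dose)
    c = convolve(fa_prof, uir, dose, T_OBS)
    rec = deconvolve(make_profile(T_OBS, c, regimen="X", dose=dose), uir)
    np.testing.assert_allclose(rec.fa, fa_true, atol=1e-3)


def test_convolve_then_deconvolve_identity_smooth_input():
    uir = _mono_uir()
    dose = 30.0
    fa = 1 - np.exp(-0.25 * T_OBS)
    fa_prof = AbsorptionProfile("S01", "X", T_OBS, fa, dose)
    c = convolve(fa_prof, uir, dose, T_OBS)
    rec = deconvolve(make_profile(T_OBS, c, regimen="X", dose=dose), uir)
    c_back = convolve(rec, uir, dose, T_OBS)
    np.testing.assert_allclose(c_back[1:], c[1:], rtol=1e-6)


def test_impulse_input_identity():
    """Deconvolving the (dose-scaled) UIR curve itself returns an
    absorption profile jumping to ~1 at the first node."""
    uir = _mono_uir()
    dose = 30.0
    c = dose * uir.uir(T_OBS)
    rec = deconvolve(make_profile(T_OBS, c, regimen="X", dose=dose), uir)
    assert rec.fa[1] == pytest.approx(1.0, abs=0.02)
    assert rec.fa[-1] == pytest.approx(1.0, abs=0.02)


def test_bolus_convolution_scales_uir():
    """A unit step at t=0 reproduces the dose-scaled impulse response."""
    grid = np.arange(0.0, 72.5, 0.5)
    fa = AbsorptionProfile(None, "X", grid, np.ones_like(grid), 30.0)
    uir = _mono_uir()
    times = np.array([0.25, 1.0, 4.0, 24.0, 72.0])
    c = convolve(fa, uir, 30.0, times)
    np.testing.assert_allclose(c, 30.0 * np.exp(-0.1 * times), rtol=1e-12)


def test_zero_absorption_gives_zero_profile():
    grid = np.arange(0.0, 10.5, 0.5)
    fa = AbsorptionProfile(None, "X", grid, np.zeros_like(grid), 30.0)
    c = convolve(fa, _mono_uir(), 30.0, np.array([1.0, 5.0, 20.0]))
    np.testing.assert_array_equal(c, 0.0)


def test_fa_monotone_by_construction_and_dose_equivariant():
    rng = np.random.default_rng(8)
    uir = _mono_uir()
    fa = 1 - np.exp(-0.3 * T_OBS)
    c = convolve(AbsorptionProfile("S01", "X", T_OBS, fa, 30.0), uir, 30.0, T_OBS)
    noisy = np.maximum(c + rng.normal(0, 0.5, c.size), 0.0)
    noisy[0] = 0.0
    rec = deconvolve(make_profile(T_OBS, noisy, regimen="X", dose=30.0), uir)
    assert np.all(np.diff(rec.fa) >= -1e-12)
    # doubling concentrations and dose leaves fa unchanged
    rec2 = deconvolve(make_profile(T_OBS, 2 * noisy, regimen="X", dose=60.0), uir)
    np.testing.assert_allclose(rec2.fa, rec.fa, rtol=1e-8)


def test_subject_mismatch_rejected():
    uir = _mono_uir(subject="S02")
    prof = make_profile(T_OBS, np.ones_like(T_OBS), regimen="X", subject="S01")
    with pytest.raises(ProfileError, match="subject"):
        deconvolve(prof, uir)


def test_underdetermined_grid_rejected_unless_smoothed():
    # a grid finer than the observations has more input intervals than
    # equations: singular without regularization
    uir = _mono_uir()
    t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    fa = 1 - np.exp(-0.5 * t)
    c = convolve(AbsorptionProfile("S01", "X", t, fa, 30.0), uir, 30.0, t)
    prof = make_profile(t, c, regimen="X", dose=30.0)
    fine = np.arange(0.0, 4.1, 0.25)
    with pytest.raises(DeconvolutionError, match="ill-conditioned"):
        deconvolve(prof, uir, grid=fine)
    rec = deconvolve(prof, uir, grid=fine, smoothing=1e-4)
    assert np.all(np.diff(rec.fa) >= -1e-12)
    assert rec.fa[-1] == pytest.approx(fa[-1], abs=0.05)


def test_mean_absorption_profile_arithmetic():
    a = AbsorptionProfile("S01", "X", [0, 1, 2], [0, 0.5, 1.0], 30.0)
    b = AbsorptionProfile("S02", "X", [0, 1, 2], [0, 0.3, 0.9], 30.0)
    m = mean_absorption_profile([a, b])
    np.testing.assert_allclose(m.fa, [0, 0.4, 0.95])
    same = mean_absorption_profile([a, a])
    np.testing.assert_allclose(same.fa, a.fa)
    with pytest.raises(ProfileError, match="mixed"):
        mean_absorption_profile(
            [a, AbsorptionProfile("S03", "Y", [0, 1, 2], [0, 0.1, 0.2], 30.0)]
        )


def test_two_stage_absorption_recovered_as_biphasic():
    """Two-stage generator truth: fast absorption before the change-point,
    slower after; the mean deconvolved profile shows the same break."""
    spec = paper_like_spec(seed=3, absorption_mode="two_stage", residual_cv=0.05)
    dataset, truth = generate_study(spec)
    from ivivc.datatypes import AnalysisConfig
    from ivivc.pipeline import fit_stage_uir, stage_deconvolve

    uirs = fit_stage_uir(dataset, AnalysisConfig(seed=3))
    _, fa_mean = stage_deconvolve(dataset, uirs, AnalysisConfig(seed=3))
    prof = fa_mean["A"]
    t, fa = prof.times, prof.fa
    tc = spec.two_stage_params[-1]
    early = (t > 0) & (t <= tc)
    late = t > 2 * tc
    rate_early = np.diff(fa[np.nonzero(early)[0]]).mean() / np.diff(t[early]).mean()
    rate_late = np.diff(fa[np.nonzero(late)[0]]).mean() / np.diff(t[late]).mean()
    assert rate_early > 5 * rate_late
    # and the generator's own truth is biphasic in the same way
    fa_truth = truth.fa_true("A", t)
    assert fa_truth[np.argmin(np.abs(t - tc))] > 0.5 * fa_truth[-1]
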