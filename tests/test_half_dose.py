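"""Total-intensity decay, half-dose solving, normalized half-dose."""

import numpy as np
import pytest

from rtdecay import (
    direct_summation_ratio,
    intensity_ratio,
    normalized_half_dose,
    solve_half_dose,
)
from rtdecay.decay_fit import DecayParameters
from rtdecay.exceptions import InvalidInputError, NoDecayError
from rtdecay.half_dose import ResolutionWindow
from rtdecay.radial_curve import flat_curve
from rtdecay.wilson_scaling import scale_series


FULL = ResolutionWindow(d_low=None, d_min=None)  # s from 0, to convergence


def flat_ratio_oracle(b0, beta, gamma, D):
    """Closed form for a flat curve over s in [0, inf):
    exp(-gamma^2 D^2) * (B0 / (B0 + beta D))^(3/2)."""
    return np.exp(-(gamma**2) * D * D) * (b0 / (b0 + beta * D)) ** 1.5


def test_ratio_is_one_at_zero_dose(calibrated_curve):
    params = DecayParameters(B0=20, beta=30, C=1, gamma=2)
    assert intensity_ratio(params, calibrated_curve, 0.0) == 1.0


def test_pure_scale_limit_is_curve_independent(calibrated_curve, sim_curve):
    """beta = 0: ratio = exp(-gamma^2 D^2) exactly, whatever the curve."""
    params = DecayParameters(B0=20, beta=0, C=1, gamma=1)
    D = 0.8326  # gamma^2 D^2 = ln 2
    for curve in (flat_curve(), calibrated_curve, sim_curve):
        assert intensity_ratio(params, curve, D) == pytest.approx(
            np.exp(-(D**2)), rel=1e-9
        )
        assert intensity_ratio(params, curve, D) == pytest.approx(0.5, abs=1e-3)


def test_flat_curve_matches_closed_form_at_example_point():
    params = DecayParameters(B0=20, beta=15, C=1, gamma=1)
    assert intensity_ratio(params, flat_curve(), 0.5, FULL) == pytest.approx(
        flat_ratio_oracle(20, 15, 1, 0.5), rel=1e-6
    )


def test_flat_curve_matches_closed_form_on_grid():
    curve = flat_curve()
    for beta in np.linspace(5, 50, 10):
        for gamma in np.linspace(0.5, 5, 10):
            params = DecayParameters(B0=20, beta=beta, C=1, gamma=gamma)
            D = 0.3
            assert intensity_ratio(params, curve, D, FULL) == pytest.approx(
                flat_ratio_oracle(20, beta, gamma, D), rel=1e-6
            )


def test_half_dose_closed_forms():
    curve = flat_curve()
    # beta = 0: D1/2 = sqrt(ln 2) / gamma
    res = solve_half_dose(DecayParameters(B0=20, beta=0, C=1, gamma=1), curve, FULL)
    assert res.d_half == pytest.approx(np.sqrt(np.log(2)), rel=1e-6)
    # gamma = 0: (B0/(B0+beta D))^(3/2) = 1/2  =>  D = B0 (2^(2/3)-1) / beta
    res = solve_half_dose(DecayParameters(B0=20, beta=15, C=1, gamma=0), curve, FULL)
    assert res.d_half == pytest.approx(20 * (2 ** (2 / 3) - 1) / 15, rel=1e-6)


def test_no_decay_raises():
    with pytest.raises(NoDecayError):
        solve_half_dose(DecayParameters(B0=20, beta=0, C=1, gamma=0), flat_curve(), FULL)


def test_negative_dose_rejected(calibrated_curve):
    params = DecayParameters(B0=20, beta=15, C=1, gamma=1)
    with pytest.raises(InvalidInputError):
        intensity_ratio(params, calibrated_curve, -0.1)


def test_ratio_strictly_decreasing(calibrated_curve):
    params = DecayParameters(B0=20, beta=15, C=1, gamma=1)
    doses = np.linspace(0, 1.2, 25)
    ratios = [intensity_ratio(params, calibrated_curve, D) for D in doses]
    assert np.all(np.diff(ratios) < 0)


def test_monotone_in_beta_and_gamma(calibrated_curve):
    assert normalized_half_dose(30, 1.0, calibrated_curve) < normalized_half_dose(
        15, 1.0, calibrated_curve
    )
    assert normalized_half_dose(15, 2.0, calibrated_curve) < normalized_half_dose(
        15, 1.0, calibrated_curve
    )


def test_truncation_bias_direction(reference_table, sim_curve):
    """Truncating at the experimental d_min inflates the half-dose."""
    for _, row in reference_table.iterrows():
        params = DecayParameters(
            B0=20.0, beta=row.beta_ave_A2_MGy, C=1.0, gamma=row.gamma_ave_MGy
        )
        d_conv = solve_half_dose(params, sim_curve, ResolutionWindow()).d_half
        d_trunc = solve_half_dose(
            params, sim_curve, ResolutionWindow(d_min=row.d_min_A)
        ).d_half
        assert d_trunc >= d_conv * (1 - 1e-9)


def test_half_dose_grows_with_b0(sim_curve):
    prev = 0.0
    for b0 in (10.0, 20.0, 30.0, 40.0):
        params = DecayParameters(B0=b0, beta=20.0, C=1.0, gamma=1.3)
        d = solve_half_dose(params, sim_curve, ResolutionWindow()).d_half
        assert d > prev
        prev = d


def test_normalized_flag_and_modes(calibrated_curve):
    params = DecayParameters(B0=20.0, beta=15.0, C=1.0, gamma=1.0)
    res = solve_half_dose(params, calibrated_curve, ResolutionWindow())
    assert res.mode == "converged" and res.normalized
    res = solve_half_dose(params, calibrated_curve, ResolutionWindow(d_min=2.0))
    assert res.mode == "truncated" and not res.normalized


def test_direct_summation_identical_wedges(make_series):
    series = make_series(seed=9, n_wedges=2, n_reflections=300)
    w0 = series.wedges[0]
    series.wedges[1].intensity = w0.intensity
    series.wedges[1].hkl, series.wedges[1].s = w0.hkl, w0.s
    result = direct_summation_ratio(series)
    np.testing.assert_allclose(result.ratios, 1.0)
    assert not result.crossed and result.d_half is None


def test_direct_summation_matches_model_noise_free(cubic_cell, sim_curve):
    """Expectation-valued intensities reproduce the truncated-window ratio.

    All wedges share one reflection set, so the only deviation from the
    continuous-integral model is the Monte-Carlo discretization of the
    resolution window; the delta-method error of each ratio bounds it.
    """
    from rtdecay.radial_curve import evaluate
    from rtdecay.synthetic_data import SimulationConfig, generate_series

    truth = DecayParameters(B0=20.0, beta=32.0, C=1.0, gamma=3.6)
    config = SimulationConfig(
        cell=cubic_cell, curve=sim_curve, truth=truth, d_min=2.0, seed=17
    )
    series = generate_series(config)
    s0, hkl0 = series.wedges[0].s, series.wedges[0].hkl
    g0 = np.asarray(evaluate(sim_curve, s0))
    for w in series.wedges:  # same reflections, expectation-valued intensities
        w.s, w.hkl = s0, hkl0
        w.intensity = g0 * np.exp(-2.0 * truth.B(w.dose) * s0**2) * truth.scale(w.dose)
    result = direct_summation_ratio(series)

    window = ResolutionWindow(d_low=12.0, d_min=2.0)
    d0 = series.wedges[0].dose
    w0 = series.wedges[0].intensity
    n = len(s0)
    for dose, ratio, w in zip(result.doses, result.ratios, series.wedges):
        model = intensity_ratio(truth, sim_curve, dose, window) / intensity_ratio(
            truth, sim_curve, d0, window
        )
        # delta-method MC error of the (correlated) ratio of sample means
        rel_dev = w.intensity / w.intensity.mean() - w0 / w0.mean()
        mc_se = np.std(rel_dev) / np.sqrt(n)
        assert abs(ratio / model - 1.0) < max(4.0 * mc_se, 1e-6)


def test_direct_summation_half_dose_stochastic(make_series, sim_curve, rng):
    """Interpolated crossing agrees with the model within bootstrap error."""
    truth = DecayParameters(B0=20.0, beta=32.0, C=1.0, gamma=3.6)
    series = make_series(beta=32.0, gamma=3.6, seed=23)
    result = direct_summation_ratio(series)
    assert result.crossed

    # bootstrap over reflections within each wedge
    boots = []
    sums = [w.intensity for w in series.wedges]
    for _ in range(200):
        totals = np.array(
            [np.sum(rng.choice(v, size=len(v), replace=True)) for v in sums]
        )
        ratios = totals / totals[0]
        d_half = None
        for i in range(1, len(ratios)):
            if ratios[i] < 0.5 <= ratios[i - 1]:
                f = (ratios[i - 1] - 0.5) / (ratios[i - 1] - ratios[i])
                d_half = result.doses[i - 1] + f * (result.doses[i] - result.doses[i - 1])
                break
        if d_half is not None:
            boots.append(d_half)
    se = np.std(boots)

    window = ResolutionWindow(d_low=12.0, d_min=2.0)
    # model ratio is relative to D=0; the measured one to the first wedge dose
    d0 = series.wedges[0].dose
    r0 = intensity_ratio(truth, sim_curve, d0, window)
    from scipy.optimize import brentq

    model_d = brentq(
        lambda D: intensity_ratio(truth, sim_curve, D, window) - 0.5 * r0, d0, 2.0
    )
    assert abs(result.d_half - model_d) < 3.0 * max(se, 1e-4)
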