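"""Synthetic-series generator: determinism, distribution, dose schedules."""

import numpy as np
import pytest

from rtdecay import UnitCell, generate_series, generate_survey, plan_burn_protocol
from rtdecay.decay_fit import DecayParameters
from rtdecay.exceptions import InvalidInputError
from rtdecay.radial_curve import evaluate, generic_protein_curve
from rtdecay.synthetic_data import SimulationConfig, design_total_dose


def test_burn_protocol_per_cycle_dose():
    schedule = plan_burn_protocol(assumed_beta=20.0, dose_rate=100.0)
    assert schedule.per_cycle_dose == pytest.approx(0.05)
    assert len(schedule.doses) == 11
    assert schedule.exposure_s == pytest.approx(0.5)  # 50 kGy at 100 kGy/s
    assert schedule.burn_per_cycle == 0.0
    assert np.all(np.diff(schedule.doses) > 0)
    spacings = np.diff(schedule.doses)
    np.testing.assert_allclose(spacings, spacings[0])  # equally spaced


def test_burn_protocol_with_total_dose_budget():
    schedule = plan_burn_protocol(assumed_beta=20.0, dose_rate=100.0, total_dose=1.1)
    assert schedule.per_cycle_dose == pytest.approx(0.05)  # data dose still capped
    assert schedule.burn_per_cycle == pytest.approx(0.05)  # rest delivered as burns
    assert schedule.doses[-1] == pytest.approx(10.5 * 0.1)


def test_burn_protocol_invalid_inputs():
    with pytest.raises(InvalidInputError):
        plan_burn_protocol(assumed_beta=0.0, dose_rate=100.0)
    with pytest.raises(InvalidInputError):
        plan_burn_protocol(assumed_beta=20.0, dose_rate=-1.0)


def test_design_total_dose_budgets_both_channels():
    # scale-limited truth: gamma budget dominates
    d = design_total_dose(DecayParameters(B0=20, beta=15, C=1, gamma=3.0))
    assert d * 3.0 <= 1.05 + 1e-12
    # B-limited truth: total B increase lands in the targeted band
    d = design_total_dose(DecayParameters(B0=20, beta=142, C=1, gamma=5.7))
    assert 20.0 <= d * 142 <= 45.0


def test_same_seed_bit_identical(make_series):
    s1 = make_series(seed=99)
    s2 = make_series(seed=99)
    for w1, w2 in zip(s1.wedges, s2.wedges):
        np.testing.assert_array_equal(w1.intensity, w2.intensity)
        np.testing.assert_array_equal(w1.hkl, w2.hkl)


def test_different_seed_differs(make_series):
    s1 = make_series(seed=1)
    s2 = make_series(seed=2)
    assert not np.array_equal(s1.wedges[0].intensity, s2.wedges[0].intensity)


def test_exponential_draw_mean(rng):
    """10^5 exponential draws at fixed J: sample mean within 3/sqrt(n)."""
    J = 7.3
    draws = rng.exponential(J, 100_000)
    assert abs(draws.mean() / J - 1.0) < 3.0 / np.sqrt(100_000)


def test_wedge_count_and_annulus(make_series):
    series = make_series(seed=4, n_wedges=11)
    assert len(series.wedges) == 11
    for w in series.wedges:
        d = 1.0 / (2.0 * w.s)
        assert np.all(d >= 2.0 - 1e-9)
        assert np.all(d <= 12.0 + 1e-9)
        assert w.n_reflections == 2000


def test_shell_means_converge_to_model(make_series, sim_curve):
    """Per-shell empirical mean intensity matches J within 3/sqrt(n_shell)."""
    truth = DecayParameters(B0=20.0, beta=15.0, C=1.0, gamma=1.0)
    series = make_series(beta=15.0, gamma=1.0, seed=77, n_reflections=8000)
    w = series.wedges[0]
    g = np.asarray(evaluate(sim_curve, w.s))
    J = 1e4 * truth.scale(w.dose) * g * np.exp(-2.0 * truth.B(w.dose) * w.s**2)
    edges = np.quantile(w.s, np.linspace(0, 1, 9))
    for lo, hi in zip(edges[:-1], edges[1:]):
        shell = (w.s >= lo) & (w.s < hi)
        n = shell.sum()
        if n < 50:
            continue
        assert abs(w.intensity[shell].mean() / J[shell].mean() - 1.0) < 3.0 / np.sqrt(n)


def test_dose_rate_metadata_does_not_touch_intensities(cubic_cell, sim_curve):
    truth = DecayParameters(B0=20, beta=15, C=1, gamma=1)
    kw = dict(cell=cubic_cell, curve=sim_curve, truth=truth, d_min=2.0, seed=12)
    slow = generate_series(SimulationConfig(dose_rate=0.4, **kw))
    fast = generate_series(SimulationConfig(dose_rate=300.0, **kw))
    for w1, w2 in zip(slow.wedges, fast.wedges):
        np.testing.assert_array_equal(w1.intensity, w2.intensity)
    assert slow.wedges[0].dose_rate != fast.wedges[0].dose_rate


def test_gaussian_noise_option(make_series):
    clean = make_series(seed=8)
    noisy = make_series(seed=8, noise="wilson_plus_gaussian")
    assert np.all(clean.wedges[0].sigma == 0)
    assert np.all(noisy.wedges[0].sigma > 0)
    assert not np.array_equal(clean.wedges[0].intensity, noisy.wedges[0].intensity)


def test_survey_generation(reference_table, sim_curve):
    small = reference_table.iloc[:3]
    series = generate_survey(small, seed=5, n_series_per_row=2,
                             curve=sim_curve, n_reflections_per_wedge=200)
    assert len(series) == 6
    acronyms = {s.acronym for s in series}
    assert acronyms == set(small["acronym"])
    for s in series:
        assert 0 < s.solvent_fraction < 1
    # base-seed shift changes intensities, not metadata
    shifted = generate_survey(small, seed=6, n_series_per_row=2,
                              curve=sim_curve, n_reflections_per_wedge=200)
    assert not np.array_equal(
        series[0].wedges[0].intensity, shifted[0].wedges[0].intensity
    )
    assert [s.acronym for s in series] == [s.acronym for s in shifted]
    assert [s.wedges[0].dose for s in series] == [s.wedges[0].dose for s in shifted]


def test_non_cubic_cells_populate_annulus(sim_curve):
    cell = UnitCell(28, 63, 60, beta=90.2)  # monoclinic lysozyme geometry
    truth = DecayParameters(B0=20, beta=15, C=1, gamma=1)
    config = SimulationConfig(cell=cell, curve=sim_curve, truth=truth,
                              d_min=1.9, seed=3, n_reflections_per_wedge=500)
    series = generate_series(config)
    assert series.wedges[0].n_reflections == 500
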