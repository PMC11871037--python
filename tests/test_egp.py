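"""EGP reconstruction: simulator ground truth, consistency, equivariance."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tracegtt.cohort import sample_cohort, simulate_test
from tracegtt.egp import bolus_response, reconstruct_egp, smooth_unlabeled, unlabeled_glucose
from tracegtt.errors import DomainError, SchemaError
from tracegtt.tracer import TracerCurve, TracerFit, dose_to_concentration, fit_tracer
from tests.conftest import enrichment_series

GRID_TIMES = np.array([0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0])


def exact_fit(mouse) -> TracerFit:
    """TracerFit carrying the simulator's true parameters."""
    return TracerFit(ka=mouse.ka, k2=mouse.k2_true, amplitude=np.nan,
                     F=mouse.F, k1=mouse.k1, kL=mouse.kL, residual_sse=0.0,
                     param_se={}, converged=True)


def chain(mouse, record, na_matrix):
    """Measurement record -> (fit, unlabelled series, unlabelled dose conc)."""
    enr = enrichment_series(record, na_matrix)
    fit = fit_tracer(
        TracerCurve(record.glucose_times, record.glucose * enr,
                    0.05 * record.dose_total_mg, mouse.body_weight),
        mouse.pool_volume,
    )
    qu = unlabeled_glucose(record.glucose, enr)
    du = dose_to_concentration(0.95 * record.dose_total_mg, mouse.pool_volume)
    return fit, qu, du


def test_unlabeled_glucose_arithmetic():
    out = unlabeled_glucose(np.array([10.0, 8.0]), np.array([0.05, 0.0]))
    np.testing.assert_allclose(out, [9.5, 8.0])


def test_unlabeled_glucose_schema_checks():
    with pytest.raises(SchemaError):
        unlabeled_glucose(np.ones(3), np.zeros(4))
    with pytest.raises(SchemaError):
        unlabeled_glucose(np.ones(2), np.zeros(2),
                          times=np.array([0, 5.0]),
                          enrichment_times=np.array([0, 10.0]))
    with pytest.raises(DomainError):
        unlabeled_glucose(np.ones(2), np.array([0.0, 0.2]))


def test_unlabeled_matches_simulator_state(noiseless_mouse, noiseless_record,
                                           na_matrix):
    """total x (1 - enrichment) reproduces the simulator's internal Q_u."""
    from tracegtt.cohort import simulate_unlabeled

    m, rec = noiseless_mouse, noiseless_record
    enr = enrichment_series(rec, na_matrix)
    qu = unlabeled_glucose(rec.glucose, enr)
    du = dose_to_concentration(0.95 * rec.dose_total_mg, m.pool_volume)
    truth = simulate_unlabeled(m, du, rec.glucose_times)
    np.testing.assert_allclose(qu, truth, atol=2e-4)  # limited by MID window truncation


def test_smooth_constant_has_zero_derivative():
    sp = smooth_unlabeled(GRID_TIMES, np.full(9, 9.0))
    grid = np.arange(0, 121.0)
    np.testing.assert_allclose(sp.derivative()(grid), 0.0, atol=1e-12)


def test_interpolant_passes_through_points():
    rng = np.random.default_rng(5)
    vals = 9 + rng.normal(0, 0.5, GRID_TIMES.size)
    for mode in ("cubic", "pchip"):
        sp = smooth_unlabeled(GRID_TIMES, vals, mode=mode)
        np.testing.assert_allclose(sp(GRID_TIMES), vals, atol=1e-12)


def test_derivative_of_sin_like_curve():
    """Spline derivative tracks an analytic derivative within 10% sup-norm."""
    f = lambda t: 9 + np.sin(2 * np.pi * t / 240)
    df = lambda t: (2 * np.pi / 240) * np.cos(2 * np.pi * t / 240)
    sp = smooth_unlabeled(GRID_TIMES, f(GRID_TIMES))
    grid = np.arange(5, 121.0)
    err = np.abs(sp.derivative()(grid) - df(grid))
    assert err.max() <= 0.10 * np.abs(df(grid)).max()


def test_duplicate_times_rejected():
    with pytest.raises(SchemaError):
        smooth_unlabeled(np.array([0, 5, 5, 10, 20.0]), np.zeros(5))


def test_fasting_steady_state_balance():
    """No bolus, constant Q_u = 9 mM, k2 = 0.02 -> EGP = 0.18 mM/min."""
    fit = TracerFit(ka=0.05, k2=0.02, amplitude=0.0, F=0.8, k1=0.04, kL=0.01,
                    residual_sse=0.0, param_se={}, converged=True)
    prof = reconstruct_egp(GRID_TIMES, np.full(9, 9.0), fit,
                           dose_unlabeled_conc=0.0)
    np.testing.assert_allclose(prof.egp, 0.18, atol=1e-10)
    assert prof.egp_steady == pytest.approx(0.18, abs=1e-10)
    assert prof.egp_overall == pytest.approx(0.18, abs=1e-10)
    assert prof.negative_fraction == 0.0


def test_dip_recovery_within_5_percent(noiseless_mouse, noiseless_record,
                                       na_matrix):
    """Noiseless OGTT with the suppression dip: pointwise error < 5% on [5,120]."""
    m, rec = noiseless_mouse, noiseless_record
    fit, qu, du = chain(m, rec, na_matrix)
    prof = reconstruct_egp(rec.glucose_times, qu, fit, du)
    truth = m.egp_true(prof.grid)
    mask = prof.grid >= 5
    rel = np.abs(prof.egp[mask] - truth[mask]) / truth[mask]
    assert rel.max() < 0.05


def test_constant_egp_steady_state_recovery(noiseless_design, na_matrix):
    """Simulation without suppression recovers egp_basal within 2%."""
    m = sample_cohort(noiseless_design)[0]
    m.egp_suppression_depth = 0.0
    rec = simulate_test(m, noiseless_design)
    fit, qu, du = chain(m, rec, na_matrix)
    prof = reconstruct_egp(rec.glucose_times, qu, fit, du)
    assert prof.egp_steady == pytest.approx(m.egp_basal, rel=0.02)


def test_summaries_are_exact_window_means(noiseless_mouse, noiseless_record,
                                          na_matrix):
    m, rec = noiseless_mouse, noiseless_record
    fit, qu, du = chain(m, rec, na_matrix)
    prof = reconstruct_egp(rec.glucose_times, qu, fit, du)
    g = prof.grid
    assert prof.egp_steady == pytest.approx(
        prof.egp[(g >= 90) & (g <= 120)].mean(), abs=1e-12)
    assert prof.egp_overall == pytest.approx(
        prof.egp[(g >= 5) & (g <= 120)].mean(), abs=1e-12)


def test_forward_consistency_identity(noiseless_mouse, noiseless_record,
                                      na_matrix):
    """Integrating the reconstructed EGP through the plasma balance
    reproduces the smoothed unlabelled curve (deconvolution is self-inverse)."""
    m, rec = noiseless_mouse, noiseless_record
    fit, qu, du = chain(m, rec, na_matrix)
    prof = reconstruct_egp(rec.glucose_times, qu, fit, du)

    from scipy.interpolate import CubicSpline
    egp_interp = CubicSpline(prof.grid, prof.egp)

    def rhs(t, y):
        absorption = fit.F * fit.ka * du * np.exp(-fit.ka * t)
        return [absorption + egp_interp(t) - fit.k2 * y[0]]

    sol = solve_ivp(rhs, (0, 120), [qu[0]], t_eval=prof.grid,
                    rtol=1e-10, atol=1e-12)
    # the smoothed curve as reconstruct_egp sees it: bolus response + residual spline
    residual = qu - np.asarray(bolus_response(rec.glucose_times, fit, du))
    sp = smooth_unlabeled(rec.glucose_times, residual)
    smoothed = np.asarray(bolus_response(prof.grid, fit, du)) + sp(prof.grid)
    np.testing.assert_allclose(sol.y[0], smoothed, atol=5e-4)


def test_unit_equivariance(noiseless_mouse, noiseless_record, na_matrix):
    """Scaling all concentrations by c scales reconstructed EGP by c."""
    m, rec = noiseless_mouse, noiseless_record
    fit, qu, du = chain(m, rec, na_matrix)
    base = reconstruct_egp(rec.glucose_times, qu, fit, du)
    c = 3.7
    scaled = reconstruct_egp(rec.glucose_times, c * qu, fit, c * du)
    np.testing.assert_allclose(scaled.egp, c * base.egp, rtol=1e-10)


def test_requires_converged_fit(noiseless_record):
    bad = TracerFit(ka=0.05, k2=0.02, amplitude=1.0, F=0.8, k1=0.04, kL=0.01,
                    residual_sse=1.0, param_se={}, converged=False)
    with pytest.raises(DomainError):
        reconstruct_egp(GRID_TIMES, np.full(9, 9.0), bad, 1.0)
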