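"""TI/FEP estimators, block averaging, convergence and hysteresis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ionsite import (
    DataError,
    FEPWindowSeries,
    FreeEnergyEstimate,
    HarmonicAlchemySpec,
    InsufficientDataError,
    LambdaSchedule,
    OrientationError,
    ScheduleError,
    TIWindowSeries,
    block_error,
    combine_forward_backward,
    fep_estimate,
    gen_harmonic_fep,
    gen_harmonic_ti,
    oriented_forward,
    running_average,
    ti_integrate,
)
from ionsite.alchemical import read_fep_tsv, read_ti_tsv, write_fep_tsv, write_ti_tsv
from ionsite.constants import kbt

GAUSS7 = LambdaSchedule.gauss7()


def series_from_node_values(values, schedule=GAUSS7, direction="forward"):
    """Constant two-sample series per node — encodes exact node means."""
    return TIWindowSeries(
        nodes=schedule.nodes,
        samples=[np.full(2, v) for v in values],
        sample_interval_ps=1.0,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# schedule


def test_gauss7_nodes_and_weights():
    nodes, w = np.array(GAUSS7.nodes), np.array(GAUSS7.weights)
    assert len(nodes) == 7
    assert np.all((nodes > 0) & (nodes < 1))
    assert np.all(np.diff(nodes) > 0)
    assert abs(w.sum() - 1.0) < 1e-12


@given(st.integers(min_value=0, max_value=13))
def test_gauss7_exact_for_polynomials_up_to_degree_13(deg):
    rng = np.random.default_rng(deg)
    coeffs = rng.uniform(-2, 2, deg + 1)
    p = np.polynomial.Polynomial(coeffs)
    quadrature = sum(w * p(x) for x, w in zip(GAUSS7.nodes, GAUSS7.weights))
    exact = p.integ()(1.0) - p.integ()(0.0)
    assert quadrature == pytest.approx(exact, rel=1e-12, abs=1e-12)


def test_invalid_schedules_rejected():
    with pytest.raises(ScheduleError):
        LambdaSchedule(nodes=(0.0, 0.5), weights=(0.5, 0.5))  # node at endpoint
    with pytest.raises(ScheduleError):
        LambdaSchedule(nodes=(0.2, 0.8), weights=(0.6, 0.6))  # weights ≠ 1


# ---------------------------------------------------------------------------
# TI


def test_ti_constant_samples():
    est = ti_integrate(series_from_node_values([2.0] * 7), GAUSS7)
    assert est.value == pytest.approx(2.0, abs=1e-12)
    assert est.error == 0.0
    assert est.per_node_means == (2.0,) * 7


def test_ti_linear_integrand_is_exact():
    est = ti_integrate(series_from_node_values(GAUSS7.nodes), GAUSS7)
    assert est.value == pytest.approx(0.5, abs=1e-14)  # ∫₀¹ λ dλ


def test_ti_harmonic_noiseless_node_means():
    """TI on the analytic harmonic integrand equals the quadrature exactly and
    the closed form (k_BT/2)·ln(k1/k0) up to the rule's intrinsic error."""
    spec = HarmonicAlchemySpec()
    integrand = [
        (spec.k1 - spec.k0) * kbt() / (2.0 * spec.k_at(lam)) for lam in GAUSS7.nodes
    ]
    est = ti_integrate(series_from_node_values(integrand), GAUSS7)
    quadrature = sum(w * f for w, f in zip(GAUSS7.weights, integrand))
    assert est.value == pytest.approx(quadrature, abs=1e-9)
    # dense-grid oracle for ∫₀¹ (k1−k0)·k_BT/(2k(λ)) dλ
    lam = np.linspace(0.0, 1.0, 200_001)
    dense = np.trapezoid((spec.k1 - spec.k0) * kbt() / (2 * spec.k_at(lam)), lam)
    assert dense == pytest.approx(spec.true_dg, abs=1e-9)
    assert est.value == pytest.approx(spec.true_dg, abs=5e-5)


def test_ti_node_mismatch_errors():
    with pytest.raises(ScheduleError):
        ti_integrate(
            TIWindowSeries(
                nodes=(0.2, 0.8),
                samples=[np.ones(2), np.ones(2)],
                sample_interval_ps=1.0,
            ),
            GAUSS7,
        )


def test_ti_harmonic_recovery_within_three_se():
    spec = HarmonicAlchemySpec(samples_per_node=10_000, ar1_phi=0.5, seed=42)
    fwd, bwd, true_dg = gen_harmonic_ti(spec, GAUSS7)
    comb = combine_forward_backward(ti_integrate(fwd, GAUSS7), ti_integrate(bwd, GAUSS7))
    assert abs(comb.value - true_dg) < 3 * comb.error
    assert not comb.flagged


def test_ti_antisymmetry_on_noiseless_input():
    values = np.array([(np.e**2 - 1) * kbt() / (2 * (1 + (np.e**2 - 1) * l)) for l in GAUSS7.nodes])
    plus = ti_integrate(series_from_node_values(values), GAUSS7)
    minus = ti_integrate(series_from_node_values(-values), GAUSS7)
    assert minus.value == pytest.approx(-plus.value, abs=1e-12)


# ---------------------------------------------------------------------------
# FEP


def test_fep_constant_and_zero_windows():
    one = FEPWindowSeries(
        windows=((0.0, 1.0),), samples=[np.full(4, 3.7)], sample_interval_ps=1.0
    )
    assert fep_estimate(one).value == pytest.approx(3.7, abs=1e-12)
    zero = FEPWindowSeries(
        windows=((0.0, 0.5), (0.5, 1.0)),
        samples=[np.zeros(4), np.zeros(4)],
        sample_interval_ps=1.0,
    )
    assert fep_estimate(zero).value == pytest.approx(0.0, abs=1e-12)


def test_fep_gaussian_closed_form(rng):
    """⟨e^{−ΔU/kBT}⟩ for ΔU ~ N(μ, σ²) gives ΔG = μ − σ²/(2 k_BT)."""
    mu, var, n = 1.0, 0.5, 100_000
    du = mu + np.sqrt(var) * rng.standard_normal(n)
    series = FEPWindowSeries(
        windows=((0.0, 1.0),), samples=[du], sample_interval_ps=1.0
    )
    est = fep_estimate(series, block_length_ps=100.0)
    expected = mu - var / (2.0 * kbt())
    assert expected == pytest.approx(0.5806, abs=1e-3)
    assert abs(est.value - expected) < 3 * est.error


def test_fep_windows_must_tile_unit_interval():
    with pytest.raises(ScheduleError):
        FEPWindowSeries(
            windows=((0.0, 0.4), (0.5, 1.0)),
            samples=[np.ones(2), np.ones(2)],
            sample_interval_ps=1.0,
        )


def test_fep_ti_agreement_on_harmonic_fixture():
    spec = HarmonicAlchemySpec(samples_per_node=4_000, ar1_phi=0.3, seed=5)
    fwd, bwd, true_dg = gen_harmonic_fep(spec, n_windows=20)
    ef = oriented_forward(fep_estimate(fwd))
    eb = oriented_forward(fep_estimate(bwd))
    fep_comb = combine_forward_backward(ef, eb)
    tf, tb, _ = gen_harmonic_ti(spec, GAUSS7)
    ti_comb = combine_forward_backward(ti_integrate(tf, GAUSS7), ti_integrate(tb, GAUSS7))
    combined_se = np.hypot(fep_comb.error, ti_comb.error)
    assert abs(fep_comb.value - ti_comb.value) < 3 * combined_se
    assert abs(fep_comb.value - true_dg) < 3 * fep_comb.error


def test_oriented_forward_negates_backward_fep_only():
    fep_b = FreeEnergyEstimate(value=1.5, error=0.1, direction="backward", method="FEP")
    assert oriented_forward(fep_b).value == -1.5
    ti_b = FreeEnergyEstimate(value=1.5, error=0.1, direction="backward", method="TI")
    assert oriented_forward(ti_b).value == 1.5


# ---------------------------------------------------------------------------
# block averaging


def test_block_error_constant_series():
    assert block_error(np.full(1000, 2.0), 1.0, 50.0) == 0.0


def test_block_error_iid_normal(rng):
    x = rng.standard_normal(10_000)
    sem = block_error(x, 1.0, 100.0)  # blocks of 100 samples
    assert sem == pytest.approx(0.01, rel=0.30)  # analytic SEM of iid means


def test_block_error_ar1_approaches_analytic_sem(rng):
    phi, n = 0.9, 100_000
    from ionsite.synthetic import _ar1_unit

    x = _ar1_unit(rng, n, phi)
    sem = block_error(x, 1.0, 2000.0)  # blocks ≫ correlation time τ≈19
    analytic = np.sqrt((1 + phi) / (1 - phi)) / np.sqrt(n)
    assert sem == pytest.approx(analytic, rel=0.35)


def test_block_error_preconditions():
    with pytest.raises(DataError, match="multiple"):
        block_error(np.ones(100), 3.0, 50.0)
    with pytest.raises(InsufficientDataError):
        block_error(np.ones(40), 1.0, 50.0)


# ---------------------------------------------------------------------------
# running averages


def test_running_average_constant_converges():
    ra = running_average(np.full(100, 1.3))
    assert ra.converged
    np.testing.assert_allclose(ra.curve, 1.3)


def test_running_average_drifting_series_not_converged():
    # cumulative mean of a 0→10 ramp climbs ~2.5 kcal/mol over the final 20%
    ramp = np.linspace(0.0, 10.0, 10_000)
    assert not running_average(ramp, tolerance=0.5).converged


def test_running_average_small_noise_converges(rng):
    x = 0.1 * rng.standard_normal(5_000)
    assert running_average(x, tolerance=0.5).converged


def test_running_average_needs_ten_samples():
    with pytest.raises(DataError):
        running_average(np.ones(5))


# ---------------------------------------------------------------------------
# forward/backward combination


def test_combine_published_endpoints():
    f = FreeEnergyEstimate(value=-22.3, error=1.2, direction="forward", method="TI")
    b = FreeEnergyEstimate(value=-24.2, error=1.2, direction="backward", method="TI")
    comb = combine_forward_backward(f, b)
    assert comb.value == pytest.approx(-23.25)
    assert comb.hysteresis == pytest.approx(1.9)
    assert not comb.flagged  # 1.9 < 2·√(1.2²+1.2²)


def test_combine_identical_estimates():
    f = FreeEnergyEstimate(value=-5.0, error=0.2, direction="forward", method="TI")
    b = FreeEnergyEstimate(value=-5.0, error=0.2, direction="backward", method="TI")
    comb = combine_forward_backward(f, b)
    assert comb.value == -5.0
    assert comb.hysteresis == 0.0
    assert not comb.flagged


def test_combine_flags_large_hysteresis():
    f = FreeEnergyEstimate(value=0.0, error=0.1, direction="forward", method="TI")
    b = FreeEnergyEstimate(value=10.0, error=0.1, direction="backward", method="TI")
    assert combine_forward_backward(f, b).flagged


def test_combine_rejects_same_direction():
    f = FreeEnergyEstimate(value=0.0, error=0.1, direction="forward", method="TI")
    with pytest.raises(OrientationError):
        combine_forward_backward(f, f)


# ---------------------------------------------------------------------------
# TSV round trips


def test_ti_tsv_round_trip(tmp_path):
    spec = HarmonicAlchemySpec(samples_per_node=200, seed=2)
    fwd, _, _ = gen_harmonic_ti(spec, GAUSS7)
    p = write_ti_tsv(fwd, tmp_path / "fwd.tsv")
    back = read_ti_tsv(p, direction="forward")
    np.testing.assert_allclose(back.nodes, fwd.nodes)
    for a, b in zip(back.samples, fwd.samples):
        np.testing.assert_allclose(a, b)
    assert back.sample_interval_ps == pytest.approx(fwd.sample_interval_ps)


def test_fep_tsv_round_trip(tmp_path):
    spec = HarmonicAlchemySpec(samples_per_node=100, seed=2)
    fwd, _, _ = gen_harmonic_fep(spec, n_windows=5)
    p = write_fep_tsv(fwd, tmp_path / "fwd.tsv")
    back = read_fep_tsv(p, direction="forward")
    assert back.windows == fwd.windows
    for a, b in zip(back.samples, fwd.samples):
        np.testing.assert_allclose(a, b)
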