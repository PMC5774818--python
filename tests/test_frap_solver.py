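"""Unit and property tests for the analytic recovery-curve solver."""

from __future__ import annotations

import numpy as np
import pytest

from h1frap import (
    FrapGeometry,
    RateSet,
    RecoveryCurve,
    band_factor,
    frap_curve,
    get_model,
    invert_leading_order,
    leading_order_map,
    mode_polynomial,
    reaction_matrix,
    reduced_model_curve,
    solve_mode,
    two_population_curve,
)
from h1frap.frap_solver import mode_term_real_form

#: A parameter regime whose per-mode cubic has a genuine complex-conjugate
#: root pair (strong directed cycle u -> w -> v -> u).
COMPLEX_ROOT_RATES = RateSet(kappa_u=1.0, gamma_b=1.0, gamma_u=0.02, eta_b=1.0, D=0.5)


def _random_model9_rates(rng):
    return get_model(9).rates(rng.lognormal(-2.0, 1.2, size=4))


# ---------------------------------------------------------------------------
# Geometry and curve containers
# ---------------------------------------------------------------------------


def test_geometry_validation():
    with pytest.raises(ValueError):
        FrapGeometry(L=16.0, h=9.0)  # band wider than the interval
    with pytest.raises(ValueError):
        FrapGeometry(L=16.0, h=0.75, c=0.1)  # band sticks out of the interval
    g = FrapGeometry()
    assert g.prefactor == pytest.approx(16.0**2 / ((16.0 - 1.5) * 0.75))


def test_recovery_curve_validation():
    with pytest.raises(ValueError):
        RecoveryCurve(np.array([1.0, 1.0]), np.array([0.1, 0.2]))
    with pytest.raises(ValueError):
        RecoveryCurve(np.array([1.0, 2.0]), np.array([0.1, np.inf]))
    with pytest.raises(ValueError):
        RecoveryCurve(np.array([-1.0, 2.0]), np.array([0.1, 0.2]))


# ---------------------------------------------------------------------------
# Mode polynomial and roots
# ---------------------------------------------------------------------------


def test_mode_polynomial_is_characteristic_polynomial_of_shifted_reaction_matrix():
    """Oracle: r_n(s) = det(sI - (M - diag(xi_n, 0, 0))) via numpy.poly."""
    rng = np.random.default_rng(3)
    geo = FrapGeometry()
    for _ in range(300):
        rates = RateSet(*rng.lognormal(-1.5, 1.2, size=6), D=rng.uniform(1, 50))
        n = int(rng.integers(1, 200))
        xi = rates.D * (n * np.pi / geo.L) ** 2
        A = reaction_matrix(rates) - np.diag([xi, 0.0, 0.0])
        expected = np.poly(A)  # monic char poly of A has roots = eigenvalues
        got = np.array(mode_polynomial(rates, geo, n))
        assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)


def test_solve_mode_roots_satisfy_polynomial_and_residues_sum_to_one():
    rng = np.random.default_rng(5)
    geo = FrapGeometry()
    for _ in range(300):
        rates = _random_model9_rates(rng)
        n = int(rng.integers(1, 500))
        mode = solve_mode(rates, geo, n)
        _, b, c, d = mode_polynomial(rates, geo, n)
        z = mode.roots
        res = z**3 + b * z**2 + c * z + d
        scale = max(abs(b) ** 1.5, abs(c) ** 0.75, abs(d) ** 0.5, 1.0)
        assert np.max(np.abs(res)) < 1e-6 * scale**2
        assert np.sum(mode.residues) == pytest.approx(1.0, abs=1e-8)
        assert np.all(z.real <= 1e-12)  # dissipative system: stable roots


def test_solve_mode_complex_pair_detection_and_ordering():
    geo = FrapGeometry()
    mode = solve_mode(COMPLEX_ROOT_RATES, geo, 2)
    assert mode.complex_pair
    z = mode.roots
    assert z[0] == pytest.approx(np.conj(z[1]))
    assert z[0].imag > 0
    assert abs(z[2].imag) < 1e-10
    # physiological-scale rates give three real roots
    mode2 = solve_mode(
        RateSet(kappa_u=0.008, gamma_b=0.4, gamma_u=0.05, eta_b=0.005), geo, 3
    )
    assert not mode2.complex_pair


def test_mode_term_real_form_matches_complex_evaluation():
    """The explicit real-trigonometric branch equals the complex sum."""
    geo = FrapGeometry()
    t = np.linspace(0.0, 300.0, 40)
    for rates, n in (
        (COMPLEX_ROOT_RATES, 2),
        (RateSet(kappa_u=0.008, gamma_b=0.4, gamma_u=0.05, eta_b=0.005), 5),
    ):
        mode = solve_mode(rates, geo, n)
        a0, a1, a2 = mode_term_real_form(mode, t)
        for k, a_real in enumerate((a0, a1, a2)):
            a_cplx = sum(
                mode.residues[i] * mode.roots[i] ** k * np.exp(mode.roots[i] * t)
                for i in range(3)
            ).real
            assert np.allclose(a_real, a_cplx, atol=1e-12)


def test_band_factor_parseval():
    """prefactor * sum S_n^2 -> 1 (completeness of the cosine basis)."""
    geo = FrapGeometry()
    n = np.arange(1, 200_001)
    s = band_factor(geo, n)
    # the partial sums approach 1 from below like 1/N
    partial_100k = geo.prefactor * np.sum(s[:100_000] ** 2)
    partial_200k = geo.prefactor * np.sum(s**2)
    assert partial_200k == pytest.approx(1.0, abs=5e-5)
    assert abs(1.0 - partial_200k) < abs(1.0 - partial_100k) / 1.8


# ---------------------------------------------------------------------------
# Full curves
# ---------------------------------------------------------------------------


def test_frap_curve_basic_shape(geometry, h12_model9_rates):
    t = np.array([0.0, 1.0, 10.0, 100.0, 1000.0, 1e5])
    curve = frap_curve(9, h12_model9_rates, geometry, t, adaptive=True)
    v = curve.values
    # fully bleached band at t=0; the truncated series converges only like
    # 1/N at t=0, so the adaptive evaluation lands within ~1e-2 of zero
    assert v[0] == pytest.approx(0.0, abs=1e-2)
    assert np.all(np.diff(v) > 0)  # recovery increases at these spacings
    assert v[-1] == pytest.approx(1.0, abs=1e-6)  # full recovery
    # bounded up to the series truncation error at t=0
    assert np.all((v >= -1e-2) & (v <= 1 + 1e-9))


def test_frap_curve_deterministic(geometry, h12_model9_rates):
    t = np.linspace(1.0, 400.0, 25)
    a = frap_curve(9, h12_model9_rates, geometry, t, adaptive=True).values
    b = frap_curve(9, h12_model9_rates, geometry, t, adaptive=True).values
    assert np.array_equal(a, b)


def test_adaptive_matches_large_fixed_truncation(geometry, h12_model9_rates):
    t = np.linspace(1.0, 500.0, 30)
    a = frap_curve(9, h12_model9_rates, geometry, t, adaptive=True).values
    b = frap_curve(9, h12_model9_rates, geometry, t, n_modes=6000).values
    assert np.allclose(a, b, atol=1e-8)


def test_complex_root_curve_is_finite_and_real(geometry):
    t = np.geomspace(0.05, 50.0, 30)
    curve = frap_curve(9, COMPLEX_ROOT_RATES, geometry, t, adaptive=True)
    assert np.all(np.isfinite(curve.values))
    assert np.all((curve.values >= -1e-9) & (curve.values <= 1 + 1e-9))


def test_frap_curve_rejects_nonconforming_rates(geometry, h12_model9_rates):
    with pytest.raises(ValueError, match="mask"):
        frap_curve(6, h12_model9_rates, geometry, np.array([1.0]))


def test_frap_curve_rejects_structurally_invalid_rates(geometry):
    # no route out of the strong state: recovery can never complete
    bad = get_model(9).rates([0.0, 0.4, 0.05, 0.005])  # kappa_u = 0
    with pytest.raises(ValueError, match="validity"):
        frap_curve(9, bad, geometry, np.array([1.0]))


def test_strict_mode_enforces_labelling_condition(geometry):
    with pytest.raises(ValueError, match="kappa_u<gamma_u"):
        frap_curve(9, COMPLEX_ROOT_RATES, geometry, np.array([1.0]), strict=True)
    # non-strict evaluation accepts the same rates
    frap_curve(9, COMPLEX_ROOT_RATES, geometry, np.array([1.0]))


def test_two_population_curve_validation(geometry):
    with pytest.raises(ValueError):
        two_population_curve(0.0, 0.1, 0.1, geometry, np.array([1.0]))
    with pytest.raises(ValueError):
        two_population_curve(25.0, 0.0, 0.0, geometry, np.array([1.0]))


def test_model0_dispatch_equals_two_population(geometry):
    rates = RateSet(kappa_b=0.05, kappa_u=0.01, D=25.0)
    t = np.linspace(1.0, 300.0, 20)
    a = frap_curve(0, rates, geometry, t, adaptive=True).values
    b = two_population_curve(25.0, 0.05, 0.01, geometry, t, adaptive=True).values
    assert np.array_equal(a, b)


def test_pure_diffusion_limit(geometry):
    """k_b = 0: the bound pool is empty and recovery is pure diffusion."""
    t = np.array([1e4])
    v = two_population_curve(25.0, 0.0, 0.5, geometry, t, adaptive=True).values
    assert v[0] == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# Leading-order reduction
# ---------------------------------------------------------------------------


def test_leading_order_map_worked_example(h15_model9_rates):
    pmap = leading_order_map(h15_model9_rates, model=9)
    assert pmap.gamma == pytest.approx(0.099881 / 0.014805, rel=1e-12)
    assert pmap.D_eff == pytest.approx(3.227462443, rel=1e-4)
    assert pmap.k_star == pytest.approx(0.001173848, rel=1e-3)
    assert pmap.k_off == pytest.approx(0.002045, rel=1e-12)


def test_leading_order_map_generic_vs_model9(h12_model9_rates):
    pmap = leading_order_map(h12_model9_rates, model=9)
    g = h12_model9_rates.gamma_b / h12_model9_rates.gamma_u
    assert pmap.k_star == pytest.approx(h12_model9_rates.eta_b * g / (1 + g))
    assert pmap.k_off == pytest.approx(h12_model9_rates.kappa_u)


def test_invert_leading_order_roundtrip():
    assert invert_leading_order(25.0 / (1 + 3.5), 25.0) == pytest.approx(3.5)
    with pytest.raises(ValueError):
        invert_leading_order(30.0, 25.0)


def test_reduction_converges_in_the_fast_exchange_limit(geometry, h15_model9_rates):
    """Scaling (gamma_b, gamma_u) by s at fixed ratio drives the full curve
    to the reduced one — and the limit is not yet reached at s = 10."""
    t = np.geomspace(1.0, 600.0, 25)
    pmap = leading_order_map(h15_model9_rates, model=9)
    reduced = reduced_model_curve(pmap, geometry, t, adaptive=True).values
    seps = []
    for s in (10.0, 1000.0, 1e5):
        scaled = h15_model9_rates.with_rates(
            gamma_b=h15_model9_rates.gamma_b * s,
            gamma_u=h15_model9_rates.gamma_u * s,
        )
        full = frap_curve(9, scaled, geometry, t, adaptive=True).values
        seps.append(np.max(np.abs(full - reduced)))
    # roughly first-order convergence in 1/s
    assert seps[1] < seps[0] / 50
    assert seps[2] < seps[1] / 50
    assert seps[2] < 1e-3


def test_reduction_fails_at_physiological_scale(geometry, h15_model9_rates):
    """At published-scale rates the reduced curve misses the early recovery."""
    t = np.geomspace(1.0, 600.0, 25)
    full = frap_curve(9, h15_model9_rates, geometry, t, adaptive=True).values
    pmap = leading_order_map(h15_model9_rates, model=9)
    reduced = reduced_model_curve(pmap, geometry, t, adaptive=True).values
    assert np.max(np.abs(full - reduced)) > 0.05
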