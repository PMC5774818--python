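"""Shared fixtures: geometries, schedules, reference rate sets and curves."""

from __future__ import annotations

import pytest

from h1frap import FrapGeometry, NoiseModel, RateSet, frap_schedule, simulate_curve


@pytest.fixture(scope="session")
def geometry() -> FrapGeometry:
    return FrapGeometry()


@pytest.fixture(scope="session")
def schedule():
    return frap_schedule(800.0)


@pytest.fixture(scope="session")
def h12_model9_rates() -> RateSet:
    """Published-scale model-9 estimates for an H1.2-like dataset."""
    return RateSet(
        kappa_u=0.00794, gamma_b=0.40596, gamma_u=0.04912, eta_b=0.00453, D=25.0
    )


@pytest.fixture(scope="session")
def h12_model6_rates() -> RateSet:
    """Published-scale model-6 estimates for the same dataset."""
    return RateSet(
        gamma_b=0.40596, gamma_u=0.04912, eta_b=0.00380, eta_u=0.00867, D=25.0
    )


@pytest.fixture(scope="session")
def h12_model7_rates() -> RateSet:
    """Published-scale model-7 estimates for the same dataset."""
    return RateSet(
        kappa_b=0.04024, kappa_u=0.00794, gamma_b=0.36572, gamma_u=0.05365, D=25.0
    )


@pytest.fixture(scope="session")
def h15_model9_rates() -> RateSet:
    """Published-scale model-9 estimates for an H1.5-like dataset."""
    return RateSet(
        kappa_u=0.002045, gamma_b=0.099881, gamma_u=0.014805, eta_b=0.001347, D=25.0
    )


@pytest.fixture(scope="session")
def noiseless_curve(geometry, schedule, h12_model9_rates):
    return simulate_curve(
        9, h12_model9_rates, geometry, schedule, NoiseModel(sigma=0.0)
    )


@pytest.fixture(scope="session")
def noisy_curve(geometry, schedule, h12_model9_rates):
    return simulate_curve(
        9, h12_model9_rates, geometry, schedule, NoiseModel(sigma=0.005, seed=7)
    )
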