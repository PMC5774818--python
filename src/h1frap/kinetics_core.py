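"""Kinetic model family for histone H1–chromatin exchange.

Ten compartment topologies describe how a nuclear protein partitions between a
freely diffusing pool ``u``, a weakly chromatin-bound pool ``w`` (seconds-scale
residence) and a strongly bound pool ``v`` (minutes-scale residence):

* model 0 — the classical two-population scheme (free ↔ bound, no ``w``);
* model 1 — all six exchange rates active;
* models 2–5 — five active rates (one κ or η removed);
* models 6–9 — four active rates, the topologies that survive model selection.

Rates (all s⁻¹): ``gamma_b``/``gamma_u`` free↔weak, ``eta_b``/``eta_u``
weak↔strong, ``kappa_b``/``kappa_u`` free↔strong; ``_b`` is toward the more
bound state, ``_u`` toward the less bound one. Every three-population topology
keeps the rapid pair (γ_b, γ_u) active, reflecting the well-established fast
exchange of linker histones with chromatin.

This module owns the rate containers, the active-rate masks (shipped as
editable YAML so a mask can be corrected without touching code), the validity
conditions a topology must satisfy to yield a well-posed recovery curve, the
steady-state population proportions, and the reciprocal-rate transition times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "RATE_NAMES",
    "RateSet",
    "PathwayModel",
    "SteadyState",
    "TransitionTimes",
    "ValidationReport",
    "model_registry",
    "get_model",
    "validate_model",
    "steady_state",
    "transition_times",
    "reaction_matrix",
]

#: Canonical parameter order used everywhere (fit vectors, reports, masks).
RATE_NAMES: tuple[str, ...] = (
    "kappa_b",
    "kappa_u",
    "gamma_b",
    "gamma_u",
    "eta_b",
    "eta_u",
)

#: Transition-time labels keyed by the rate whose reciprocal they are.
TRANSITION_OF_RATE: dict[str, str] = {
    "kappa_b": "tau_uv",
    "kappa_u": "tau_vu",
    "gamma_b": "tau_uw",
    "gamma_u": "tau_wu",
    "eta_b": "tau_wv",
    "eta_u": "tau_vw",
}


@dataclass(frozen=True)
class RateSet:
    """Exchange rates (s⁻¹) and diffusion coefficient (μm²/s).

    Rates of transitions that a given topology does not include are stored as
    exact zeros, so the steady-state rate products and sums apply uniformly to
    every model.
    """

    kappa_b: float = 0.0
    kappa_u: float = 0.0
    gamma_b: float = 0.0
    gamma_u: float = 0.0
    eta_b: float = 0.0
    eta_u: float = 0.0
    D: float = 25.0

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.D <= 0:
            raise ValueError("diffusion coefficient D must be > 0")

    def as_array(self) -> np.ndarray:
        """Rates in canonical order (excludes D)."""
        return np.array([getattr(self, name) for name in RATE_NAMES])

    def with_rates(self, **kwargs: float) -> "RateSet":
        return replace(self, **kwargs)

    @classmethod
    def from_values(
        cls, values: Iterable[float], names: Iterable[str], D: float = 25.0
    ) -> "RateSet":
        return cls(D=D, **dict(zip(names, values, strict=True)))


@dataclass(frozen=True)
class PathwayModel:
    """A model identity with its set of active exchange rates."""

    model_id: int
    active_rates: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.active_rates - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rates in mask: {sorted(unknown)}")

    @property
    def is_two_population(self) -> bool:
        return self.model_id == 0

    def n_free_params(self, d_free: bool = False) -> int:
        return len(self.active_rates) + (1 if d_free else 0)

    @property
    def active_names(self) -> tuple[str, ...]:
        """Active rates in canonical order."""
        return tuple(n for n in RATE_NAMES if n in self.active_rates)

    def conforms(self, rates: RateSet, atol: float = 0.0) -> bool:
        """True when every inactive rate is (numerically) zero."""
        return all(
            abs(getattr(rates, n)) <= atol
            for n in RATE_NAMES
            if n not in self.active_rates
        )

    def rates(self, values: Iterable[float], D: float = 25.0) -> RateSet:
        """Build a RateSet from active-rate values in canonical order."""
        return RateSet.from_values(values, self.active_names, D=D)


def _load_masks() -> dict[int, frozenset[str]]:
    text = resources.files("h1frap").joinpath("model_masks.yaml").read_text()
    raw = yaml.safe_load(text)
    return {int(k): frozenset(v) for k, v in raw.items()}


_MASKS = _load_masks()


def model_registry() -> list[PathwayModel]:
    """The ten pathway topologies, ordered by model id."""
    return [PathwayModel(i, _MASKS[i]) for i in sorted(_MASKS)]


def get_model(model_id: int) -> PathwayModel:
    if model_id not in _MASKS:
        raise KeyError(f"no pathway model with id {model_id}")
    return PathwayModel(model_id, _MASKS[model_id])


@dataclass(frozen=True)
class ValidationReport:
    """Pass/fail record for each well-posedness condition of a topology."""

    model_id: int
    checks: dict[str, bool]
    reasons: dict[str, str]

    @property
    def valid(self) -> bool:
        return all(self.checks.values())

    def failures(self) -> list[str]:
        return [k for k, ok in self.checks.items() if not ok]


_CONDITIONS_3POP = (
    # (label, lambda, human-readable meaning)
    ("kappa_u+eta_u>0", lambda r: r.kappa_u + r.eta_u > 0,
     "the strongly bound state must have an outgoing rate"),
    ("kappa_b+eta_b>0", lambda r: r.kappa_b + r.eta_b > 0,
     "the strongly bound state must have an incoming rate"),
    ("kappa_b+gamma_b>0", lambda r: r.kappa_b + r.gamma_b > 0,
     "the free state must have an outgoing rate"),
    ("kappa_u+gamma_u>0", lambda r: r.kappa_u + r.gamma_u > 0,
     "the free state must have an incoming rate"),
    ("gamma_b+eta_u>0", lambda r: r.gamma_b + r.eta_u > 0,
     "the weakly bound state must have an incoming rate"),
    ("gamma_u+eta_b>0", lambda r: r.gamma_u + r.eta_b > 0,
     "the weakly bound state must have an outgoing rate"),
    ("kappa_u<gamma_u", lambda r: r.kappa_u < r.gamma_u,
     "the rapid exchange must be carried by the gamma pair"),
)

_CONDITIONS_2POP = (
    ("kappa_b>0", lambda r: r.kappa_b > 0, "binding rate must be positive"),
    ("kappa_u>0", lambda r: r.kappa_u > 0, "unbinding rate must be positive"),
)


def validate_model(model: PathwayModel, rates: RateSet) -> ValidationReport:
    """Check the conditions under which the recovery curve is well defined.

    For the three-population topologies these are the seven conditions that
    rule out a population with no incoming or no outgoing transition and keep
    the γ pair as the rapid exchange. Model 0 only needs both of its rates
    positive. Failures are reported, not raised; the curve solvers refuse
    invalid inputs at their own boundary.
    """
    conds = _CONDITIONS_2POP if model.is_two_population else _CONDITIONS_3POP
    checks = {label: bool(fn(rates)) for label, fn, _ in conds}
    reasons = {label: why for label, _, why in conds}
    return ValidationReport(model.model_id, checks, reasons)


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium proportions and the rate products/sums behind them."""

    P_u: float
    P_w: float
    P_v: float
    Pi_u: float
    Pi_w: float
    Pi_v: float
    Pi_total: float
    Sigma_u: float
    Sigma_total: float

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.P_u, self.P_w, self.P_v])


def _pi_sigma(rates: RateSet) -> tuple[float, float, float, float, float]:
    """Rate products Π and sums Σ of the three-population system."""
    r = rates
    pi_u = r.kappa_u * r.eta_b + r.kappa_u * r.gamma_u + r.eta_u * r.gamma_u
    pi_w = r.gamma_b * r.kappa_u + r.gamma_b * r.eta_u + r.kappa_b * r.eta_u
    pi_v = r.eta_b * r.gamma_b + r.eta_b * r.kappa_b + r.gamma_u * r.kappa_b
    sigma_u = r.kappa_u + r.gamma_u + r.eta_b + r.eta_u
    sigma_total = r.kappa_b + r.gamma_b + sigma_u
    return pi_u, pi_w, pi_v, sigma_u, sigma_total


def steady_state(model: PathwayModel, rates: RateSet) -> SteadyState:
    """Equilibrium fractions P_u, P_w, P_v of the three populations.

    P_i = Π_i / Π_total with Π_u = κ_u η_b + κ_u γ_u + η_u γ_u and cyclic
    analogues; for model 0 the familiar two-state fractions
    k_u/(k_b+k_u), k_b/(k_b+k_u) are returned with P_w = 0.
    """
    if model.is_two_population:
        total = rates.kappa_b + rates.kappa_u
        if total <= 0:
            raise ValueError("degenerate topology: both exchange rates are zero")
        return SteadyState(
            P_u=rates.kappa_u / total,
            P_w=0.0,
            P_v=rates.kappa_b / total,
            Pi_u=rates.kappa_u,
            Pi_w=0.0,
            Pi_v=rates.kappa_b,
            Pi_total=total,
            Sigma_u=rates.kappa_u,
            Sigma_total=total,
        )
    pi_u, pi_w, pi_v, sigma_u, sigma_total = _pi_sigma(rates)
    pi_total = pi_u + pi_w + pi_v
    if pi_total <= 0:
        raise ValueError("degenerate topology: all steady-state rate products vanish")
    return SteadyState(
        P_u=pi_u / pi_total,
        P_w=pi_w / pi_total,
        P_v=pi_v / pi_total,
        Pi_u=pi_u,
        Pi_w=pi_w,
        Pi_v=pi_v,
        Pi_total=pi_total,
        Sigma_u=sigma_u,
        Sigma_total=sigma_total,
    )


@dataclass(frozen=True)
class TransitionTimes:
    """Mean transition times (s) between states; reciprocal active rates.

    Entries for inactive transitions are ``None`` (absent), never zero.
    Naming: ``tau_uv`` is the mean wandering time before binding strongly
    (1/κ_b), ``tau_wu`` the mean weak-state residence time (1/γ_u), etc.
    """

    tau_uv: float | None = None
    tau_vu: float | None = None
    tau_uw: float | None = None
    tau_wu: float | None = None
    tau_wv: float | None = None
    tau_vw: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            k: getattr(self, k)
            for k in ("tau_uv", "tau_vu", "tau_uw", "tau_wu", "tau_wv", "tau_vw")
        }


def transition_times(model: PathwayModel, rates: RateSet) -> TransitionTimes:
    """Reciprocals of the active rates, labelled by the transition they time."""
    out: dict[str, float] = {}
    for rate_name in model.active_names:
        value = getattr(rates, rate_name)
        if value > 0:
            out[TRANSITION_OF_RATE[rate_name]] = 1.0 / value
    return TransitionTimes(**out)


def reaction_matrix(rates: RateSet) -> np.ndarray:
    """The 3×3 linear reaction matrix M with d/dt (u,w,v) = M (u,w,v).

    The spatial operator is excluded; this is the well-mixed part whose kernel
    gives the steady-state proportions and whose per-mode shift by the
    diffusive decay ξ_n yields the mode polynomials of the recovery curve.
    """
    r = rates
    return np.array(
        [
            [-(r.gamma_b + r.kappa_b), r.gamma_u, r.kappa_u],
            [r.gamma_b, -(r.gamma_u + r.eta_b), r.eta_u],
            [r.kappa_b, r.eta_b, -(r.kappa_u + r.eta_u)],
        ]
    )
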