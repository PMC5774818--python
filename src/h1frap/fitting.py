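"""Constrained multistart nonlinear least squares for recovery curves.

Protocol: each active rate is searched within a window spanning two orders of
magnitude on either side of 10⁻² s⁻¹ — concretely (1e-4, 1e2) s⁻¹, i.e. all
transition times longer than ten milliseconds — starting the bounded
trust-region-reflective optimizer from ``n_starts`` random initial points
whose rates are drawn from an exponential distribution with rate parameter
λ = 0.8 (mean initial rate 1.25 s⁻¹), clipped into the bounds. The optimizer
works on the logarithms of the parameters: rates span several orders of
magnitude, and the log transform equalizes their scales and roughly halves
the iteration count compared with the linear parameterization. Converged
solutions are clustered by relative parameter distance; the fit reported is
the lowest-RSS cluster representative, and the convergence count is the
number of starts landing in that cluster.

Per-fit statistics: residual sum of squares, linearized standard errors
√diag(s²(JᵀJ)⁻¹) with s² = RSS/(n−p) and J the finite-difference residual
Jacobian at the optimum, and the small-sample corrected Akaike criterion in
its Gaussian-RSS form AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with
k = p + 1 (the error variance counts as a parameter). The absolute AICc then
carries an arbitrary additive constant — comparisons on a common dataset are
what is meaningful. Overfit detection flags estimates that are numerically
zero or pinned at a search bound, the signature of a topology with more
transitions than the data support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .frap_solver import FrapGeometry, RecoveryCurve, frap_curve
from .kinetics_core import PathwayModel, RateSet, get_model, validate_model

__all__ = [
    "FitConfig",
    "FitResult",
    "residuals",
    "multistart_fit",
    "standard_errors",
    "aicc",
    "detect_overfit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Settings of the multistart least-squares protocol."""

    d_fixed: float | None = 25.0  # μm²/s; None lets D float as a parameter
    n_starts: int = 1000
    init_rate_lambda: float = 0.8  # s: exponential rate parameter of the draws
    rate_lower_bound: float = 1e-4  # s⁻¹
    rate_upper_bound: float = 1e2  # s⁻¹ (transition times > 10 ms)
    d_bounds: tuple[float, float] = (1e-4, 1e3)  # μm²/s, free-D search window
    cluster_tol: float = 1e-3  # relative parameter distance
    seed: int = 0
    max_nfev: int | None = 200  # per-start evaluation cap (log-space iterations)
    n_modes_adaptive: bool = True

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not (0 < self.rate_lower_bound < self.rate_upper_bound):
            raise ValueError("need 0 < rate_lower_bound < rate_upper_bound")
        if self.init_rate_lambda <= 0:
            raise ValueError("init_rate_lambda must be > 0")


@dataclass
class FitResult:
    """One model fitted to one curve."""

    model_id: int
    estimates: RateSet
    param_names: tuple[str, ...]  # fitted parameters, canonical order (+ "D" if free)
    rss: float
    aicc: float
    conv_count: int
    n_points: int
    n_params: int
    std_errors: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    n_starts_succeeded: int = 0
    config: FitConfig | None = None
    #: every converged start as (parameter vector, rss), best first
    solutions: list[tuple[np.ndarray, float]] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        vals = [
            getattr(self.estimates, n) if n != "D" else self.estimates.D
            for n in self.param_names
        ]
        return np.array(vals)

    @property
    def overfit(self) -> bool:
        return any(k != "validity" for k in self.flags)


def residuals(
    model: PathwayModel | int,
    rates: RateSet,
    geometry: FrapGeometry,
    curve: RecoveryCurve,
) -> np.ndarray:
    """Observed minus theoretical intensity at each observation time."""
    if isinstance(model, int):
        model = get_model(model)
    theo = frap_curve(model, rates, geometry, curve.times, adaptive=True)
    return curve.values - theo.values


def _make_objective(model, curve, geometry, config):
    names = list(model.active_names)
    d_free = config.d_fixed is None
    if d_free:
        names = names + ["D"]

    def build_rates(x: np.ndarray) -> RateSet:
        if d_free:
            return model.rates(x[:-1], D=x[-1])
        return model.rates(x, D=config.d_fixed)

    def obj(x: np.ndarray) -> np.ndarray:
        return residuals(model, build_rates(x), geometry, curve)

    return obj, build_rates, tuple(names), d_free


def _draw_starts(
    config: FitConfig, n_rates: int, d_free: bool, rng: np.random.Generator
) -> np.ndarray:
    rates0 = rng.exponential(1.0 / config.init_rate_lambda,
                             size=(config.n_starts, n_rates))
    rates0 = np.clip(rates0, config.rate_lower_bound, config.rate_upper_bound)
    if not d_free:
        return rates0
    lo, hi = config.d_bounds
    d0 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(config.n_starts, 1)))
    return np.hstack([rates0, d0])


def _cluster_best(
    solutions: list[tuple[np.ndarray, float]], cluster_tol: float
) -> tuple[np.ndarray, float, int]:
    """Lowest-RSS representative and the count of starts converging to it."""
    solutions = sorted(solutions, key=lambda s: s[1])
    x_best, rss_best = solutions[0]
    scale = np.maximum(np.abs(x_best), 1e-12)
    count = sum(
        1
        for x, _ in solutions
        if np.max(np.abs(x - x_best) / scale) <= cluster_tol
    )
    return x_best, rss_best, count


def multistart_fit(
    model: PathwayModel | int,
    curve: RecoveryCurve,
    geometry: FrapGeometry,
    config: FitConfig | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Fit one model to one curve with the multistart protocol.

    ``x0`` (parameter vector in the model's canonical order, D last if free)
    replaces the first random start when given — handy for warm restarts.
    All randomness comes from ``config.seed``.
    """
    if isinstance(model, int):
        model = get_model(model)
    config = config or FitConfig()
    if curve.times.size and curve.times[0] <= 0:
        raise ValueError(
            "fit curves must start after the bleach (first time > 0); "
            "drop the t=0 point"
        )
    obj, build_rates, names, d_free = _make_objective(model, curve, geometry, config)
    n_rates = len(model.active_names)
    lower = np.full(n_rates, config.rate_lower_bound)
    upper = np.full(n_rates, config.rate_upper_bound)
    if d_free:
        lower = np.append(lower, config.d_bounds[0])
        upper = np.append(upper, config.d_bounds[1])

    rng = np.random.default_rng(config.seed)
    starts = _draw_starts(config, n_rates, d_free, rng)
    if x0 is not None:
        starts[0] = np.clip(np.asarray(x0, dtype=float), lower, upper)

    def obj_log(u: np.ndarray) -> np.ndarray:
        return obj(np.exp(u))

    log_lower, log_upper = np.log(lower), np.log(upper)
    solutions: list[tuple[np.ndarray, float]] = []
    errors: list[str] = []
    for start in starts:
        try:
            sol = least_squares(
                obj_log,
                np.log(start),
                bounds=(log_lower, log_upper),
                method="trf",
                max_nfev=config.max_nfev,
            )
            solutions.append((np.exp(sol.x), 2.0 * sol.cost))
        except Exception as exc:  # noqa: BLE001 - per-start diagnostics
            errors.append(f"start {start}: {exc}")
    if not solutions:
        raise RuntimeError(
            "all starts failed; per-start diagnostics:\n" + "\n".join(errors)
        )

    x_best, rss, conv_count = _cluster_best(solutions, config.cluster_tol)
    estimates = build_rates(x_best)
    n, p = curve.times.size, len(names)
    result = FitResult(
        model_id=model.model_id,
        estimates=estimates,
        param_names=names,
        rss=rss,
        aicc=aicc(rss, n, p),
        conv_count=conv_count,
        n_points=n,
        n_params=p,
        n_starts_succeeded=len(solutions),
        config=config,
        solutions=sorted(solutions, key=lambda s: s[1]),
    )
    result.std_errors = standard_errors(result, curve, geometry)
    result.flags.update(detect_overfit(result))
    report = validate_model(model, estimates)
    if not report.valid:
        result.flags["validity"] = ",".join(report.failures())
    return result


def _fd_jacobian(obj, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the residual vector."""
    r0 = obj(x)
    J = np.empty((r0.size, x.size))
    for j in range(x.size):
        h = rel_step * max(abs(x[j]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0) if x[j] - h < 0 else xm[j] - h
        J[:, j] = (obj(xp) - obj(xm)) / (xp[j] - xm[j])
    return J


def standard_errors(
    fit: FitResult, curve: RecoveryCurve, geometry: FrapGeometry
) -> dict[str, float]:
    """Linearized asymptotic standard errors √diag(s²(JᵀJ)⁻¹).

    A (numerically) singular JᵀJ marks the fit non-identifiable — the
    expected outcome in the wide-bound fast-exchange regime where only the
    ratio of the weak-exchange rates is determined — and yields inf entries.
    """
    model = get_model(fit.model_id)
    config = fit.config or FitConfig()
    obj, _, names, _ = _make_objective(model, curve, geometry, config)
    n, p = fit.n_points, fit.n_params
    if n <= p:
        raise ValueError("need more observations than parameters")
    J = _fd_jacobian(obj, fit.params)
    jtj = J.T @ J
    s2 = fit.rss / (n - p)
    cond = np.linalg.cond(jtj)
    if not np.isfinite(cond) or cond > 1e12:
        fit.flags["non_identifiable"] = f"cond(JtJ)={cond:.3g}"
        cov = s2 * np.linalg.pinv(jtj)
    else:
        cov = s2 * np.linalg.inv(jtj)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return dict(zip(names, se))


def aicc(rss: float, n_points: int, n_params: int) -> float:
    """Corrected Akaike criterion, Gaussian-RSS form, k = n_params + 1."""
    n, k = n_points, n_params + 1
    if n <= k + 1:
        raise ValueError("AICc needs n_points > n_params + 2")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def detect_overfit(
    fit: FitResult, zero_tol: float = 1e-6, bound_rtol: float = 1e-2
) -> dict[str, str]:
    """Flag estimates that are numerically zero or pinned at a search bound.

    A transition rate the data cannot support is driven to (effectively) zero
    or onto the lower bound of the search region; either disqualifies the
    topology as overparameterized for that curve.
    """
    config = fit.config or FitConfig()
    flags: dict[str, str] = {}
    for name in fit.param_names:
        if name == "D":
            continue
        val = getattr(fit.estimates, name)
        if val < zero_tol:
            flags[name] = "numerically zero"
        elif val <= config.rate_lower_bound * (1 + bound_rtol):
            flags[name] = "pinned at lower bound"
        elif val >= config.rate_upper_bound * (1 - bound_rtol):
            flags[name] = "pinned at upper bound"
    return flags
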