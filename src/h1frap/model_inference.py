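"""Model comparison, biological summaries, reduction adequacy and group tests.

This stage turns per-curve fits into scientific statements:

* ``compare_models`` fits every candidate pathway topology to one curve,
  disqualifies overparameterized topologies (rates driven to zero or pinned at
  a search bound), ranks the survivors by AICc and reports tie groups. On data
  that several topologies can represent exactly, the survivors tie: they reach
  the same residual sum of squares with the same parameter count, so AICc
  cannot separate them and the data alone cannot identify the assembly
  pathway.
* ``biological_summary`` converts rate estimates into steady-state population
  percentages and mean transition times — the quantities with a direct
  biological reading.
* ``leading_order_adequacy`` and ``fit_leading_order`` examine the
  fast-exchange reduction: when weak-binding exchange is not truly fast, the
  reduced (effective-diffusion) model visibly misses the early recovery; when
  it is fast, only the ratio γ = γ_b/γ_u is identifiable and the individual
  rates are not.
* ``rss_surface`` maps the residual surface over (γ_b, γ_u) to show that
  degeneracy directly: a ray of equal-RSS minima at fixed γ under wide
  bounds, a unique basin under the default bounds.
* ``ks_group_compare`` compares per-cell parameter estimates between two
  treatment groups with the two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .frap_solver import (
    FrapGeometry,
    PerturbationMap,
    RecoveryCurve,
    frap_curve,
    invert_leading_order,
    leading_order_map,
    reduced_model_curve,
    two_population_curve,
)
from .fitting import FitConfig, FitResult, aicc, multistart_fit, residuals
from .kinetics_core import (
    RateSet,
    get_model,
    model_registry,
    steady_state,
    transition_times,
)

__all__ = [
    "ComparisonRow",
    "ComparisonTable",
    "GroupComparison",
    "AdequacyReport",
    "ReducedFit",
    "SurfaceTable",
    "compare_models",
    "biological_summary",
    "summary_row",
    "leading_order_adequacy",
    "fit_leading_order",
    "rss_surface",
    "ks_group_compare",
]

logger = logging.getLogger(__name__)

#: Two fits whose AICc differ by less than this are reported as tied. Fits of
#: equally expressive topologies agree to numerical precision; the tolerance
#: absorbs optimizer round-off.
DEFAULT_TIE_TOL = 1e-4

DASH = "—"


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonRow:
    """One candidate topology in a comparison table."""

    model_id: int
    fit: FitResult | None = None
    error: str | None = None
    rank: int | None = None  # 1-based among qualified fits; None if not ranked
    tie_group: int | None = None  # shared by rows tied with each other

    @property
    def rss(self) -> float:
        return self.fit.rss if self.fit else float("nan")

    @property
    def aicc(self) -> float:
        return self.fit.aicc if self.fit else float("nan")

    @property
    def disqualified(self) -> bool:
        return self.error is not None or (self.fit is not None and self.fit.overfit)


@dataclass
class ComparisonTable:
    """All candidate topologies fitted to one curve, ranked by AICc."""

    rows: list[ComparisonRow]
    tie_tol: float = DEFAULT_TIE_TOL

    def row(self, model_id: int) -> ComparisonRow:
        for r in self.rows:
            if r.model_id == model_id:
                return r
        raise KeyError(f"no row for model {model_id}")

    @property
    def qualified(self) -> list[ComparisonRow]:
        return [r for r in self.rows if not r.disqualified]

    @property
    def best(self) -> ComparisonRow:
        ranked = [r for r in self.rows if r.rank is not None]
        if not ranked:
            raise ValueError("no qualified fits in the table")
        return min(ranked, key=lambda r: r.rank)

    def tie_groups(self) -> dict[int, list[int]]:
        """Tie-group label -> model ids, for groups of two or more."""
        groups: dict[int, list[int]] = {}
        for r in self.rows:
            if r.tie_group is not None:
                groups.setdefault(r.tie_group, []).append(r.model_id)
        return {g: ms for g, ms in groups.items() if len(ms) > 1}

    def to_text(self) -> str:
        lines = ["model\trss\taicc\tconv\trank\ttie_group\tflags"]
        for r in self.rows:
            if r.fit is None:
                lines.append(f"{r.model_id}\t-\t-\t-\t-\t-\terror: {r.error}")
                continue
            flagtxt = (
                ";".join(f"{k}={v}" for k, v in r.fit.flags.items()) or "-"
            )
            lines.append(
                f"{r.model_id}\t{r.rss:.6e}\t{r.aicc:.4f}\t{r.fit.conv_count}"
                f"\t{r.rank if r.rank is not None else '-'}"
                f"\t{r.tie_group if r.tie_group is not None else '-'}"
                f"\t{flagtxt}"
            )
        return "\n".join(lines)


def compare_models(
    curve: RecoveryCurve,
    geometry: FrapGeometry,
    config: FitConfig | None = None,
    model_ids: Sequence[int] | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> ComparisonTable:
    """Fit each candidate topology to the curve and rank survivors by AICc.

    Overparameterized topologies — those whose extra rates the optimizer
    drives to zero or pins at a bound — are disqualified rather than ranked.
    Per-model fit failures are recorded in the row and do not abort the
    table. Ranked rows whose AICc chain together within ``tie_tol`` share a
    tie group.
    """
    if model_ids is None:
        model_ids = [m.model_id for m in model_registry()]
    model_ids = list(model_ids)
    if len(model_ids) < 1:
        raise ValueError("compare_models needs at least one model id")
    config = config or FitConfig()

    rows = []
    for mid in model_ids:
        row = ComparisonRow(model_id=mid)
        try:
            row.fit = multistart_fit(get_model(mid), curve, geometry, config)
        except Exception as exc:  # noqa: BLE001 - tabulated per model
            row.error = str(exc)
            logger.warning("model %d fit failed: %s", mid, exc)
        rows.append(row)

    ranked = sorted(
        (r for r in rows if not r.disqualified), key=lambda r: r.aicc
    )
    group = 0
    for i, r in enumerate(ranked):
        r.rank = i + 1
        if i > 0 and abs(r.aicc - ranked[i - 1].aicc) < tie_tol:
            r.tie_group = ranked[i - 1].tie_group
        else:
            group += 1
            r.tie_group = group
    return ComparisonTable(rows=rows, tie_tol=tie_tol)


# ---------------------------------------------------------------------------
# Biological summary
# ---------------------------------------------------------------------------


def _fmt(x: float, decimals: int) -> str:
    if not np.isfinite(x):
        return DASH
    return f"{x:.{decimals}f}"


def summary_row(model_id: int, rates: RateSet) -> dict[str, str]:
    """Population percentages (1 decimal) and transition times (2 decimals).

    Transitions absent from the topology (rate zero, infinite mean time) are
    dashed.
    """
    model = get_model(model_id)
    ss = steady_state(model, rates)
    tt = transition_times(model, rates)
    row = {
        "P_u_pct": _fmt(100 * ss.P_u, 1),
        "P_w_pct": _fmt(100 * ss.P_w, 1),
        "P_v_pct": _fmt(100 * ss.P_v, 1),
    }
    for name in ("uv", "vu", "uw", "wu", "wv", "vw"):
        val = getattr(tt, f"tau_{name}")
        row[f"tau_{name}_s"] = DASH if val is None else _fmt(val, 2)
    return row


def biological_summary(
    fits: Mapping[str, FitResult] | Mapping[str, tuple[int, RateSet]],
) -> str:
    """Tab-delimited summary of population splits and transition times.

    ``fits`` maps a dataset label to either a ``FitResult`` or a
    ``(model_id, RateSet)`` pair. The output is a pure function of the
    estimates.
    """
    header = [
        "dataset",
        "model",
        "P_u_pct",
        "P_w_pct",
        "P_v_pct",
        "tau_uv_s",
        "tau_vu_s",
        "tau_uw_s",
        "tau_wu_s",
        "tau_wv_s",
        "tau_vw_s",
    ]
    lines = ["\t".join(header)]
    for label, entry in fits.items():
        if isinstance(entry, FitResult):
            mid, rates = entry.model_id, entry.estimates
        else:
            mid, rates = entry
        row = summary_row(mid, rates)
        lines.append("\t".join([label, str(mid)] + [row[k] for k in header[2:]]))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Leading-order reduction: adequacy and direct fitting
# ---------------------------------------------------------------------------


@dataclass
class AdequacyReport:
    """Full three-population fit vs its fast-exchange reduction on one curve."""

    pmap: PerturbationMap
    rss_full: float
    rss_reduced: float
    sup_separation: float  # sup-norm distance between the two theoretical curves
    threshold: float
    adequate: bool

    def verdict(self) -> str:
        return "reduction adequate" if self.adequate else "reduction inadequate"


def leading_order_adequacy(
    fit3: FitResult,
    curve: RecoveryCurve,
    geometry: FrapGeometry,
    threshold: float = 0.01,
) -> AdequacyReport:
    """Does the fast-exchange reduction reproduce the full model's recovery?

    Maps the fitted rates to effective parameters (D_eff, k*, k_off),
    evaluates the reduced two-population curve on the observation grid, and
    compares it against both the data (RSS) and the full-model curve
    (sup-norm). The reduction is adequate only when weak-state exchange is
    genuinely fast relative to diffusion across the bleached band; at
    physiological rate scales it typically is not, and the reduced curve
    misses the early recovery.
    """
    rates = fit3.estimates
    if rates.gamma_u <= 0:
        raise ValueError("leading-order reduction needs gamma_u > 0")
    pmap = leading_order_map(rates, model=fit3.model_id)
    full = frap_curve(fit3.model_id, rates, geometry, curve.times, adaptive=True)
    reduced = reduced_model_curve(pmap, geometry, curve.times, adaptive=True)
    rss_full = float(np.sum((curve.values - full.values) ** 2))
    rss_reduced = float(np.sum((curve.values - reduced.values) ** 2))
    sep = float(np.max(np.abs(full.values - reduced.values)))
    return AdequacyReport(
        pmap=pmap,
        rss_full=rss_full,
        rss_reduced=rss_reduced,
        sup_separation=sep,
        threshold=threshold,
        adequate=sep < threshold,
    )


@dataclass
class ReducedFit:
    """Direct fit of the reduced (effective-diffusion) two-population model.

    Fitting (D_eff, k_star, k_off) determines the weak-exchange ratio
    γ = D/D_eff − 1 for a given free diffusion coefficient D, but not γ_b and
    γ_u individually — they are reported as non-identifiable.
    """

    d_eff: float
    k_star: float
    k_off: float
    rss: float
    aicc: float
    conv_count: int
    n_points: int
    gamma: float
    d_free: float  # the assumed free diffusion coefficient used for gamma
    std_errors: dict[str, float] = field(default_factory=dict)
    non_identifiable: tuple[str, ...] = ("gamma_b", "gamma_u")

    def summary(self) -> str:
        lines = [
            f"D_eff_um2_per_s\t{self.d_eff:.6g}",
            f"k_star_per_s\t{self.k_star:.6g}",
            f"k_off_per_s\t{self.k_off:.6g}",
            f"gamma\t{self.gamma:.6g}",
        ]
        for name in self.non_identifiable:
            lines.append(f"{name}_per_s\t{DASH} (not uniquely determined)")
        return "\n".join(lines)


def fit_leading_order(
    curve: RecoveryCurve,
    geometry: FrapGeometry,
    config: FitConfig | None = None,
) -> ReducedFit:
    """Fit the reduced model's (D_eff, k_star, k_off) to one curve.

    The reduced system is the two-population exchange model with diffusion
    coefficient D_eff; the multistart protocol (log-space bounded
    trust-region) is applied to its three parameters. The weak-exchange
    ratio γ is back-computed from D_eff and the configured free diffusion
    coefficient; the underlying exchange rates γ_b and γ_u are flagged
    non-identifiable.
    """
    config = config or FitConfig()
    if curve.times.size and curve.times[0] <= 0:
        raise ValueError("fit curves must start after the bleach; drop the t=0 point")
    d_free = config.d_fixed if config.d_fixed is not None else 25.0

    lower = np.log(
        [config.d_bounds[0], config.rate_lower_bound, config.rate_lower_bound]
    )
    upper = np.log(
        [config.d_bounds[1], config.rate_upper_bound, config.rate_upper_bound]
    )

    def obj(u: np.ndarray) -> np.ndarray:
        d_eff, k_star, k_off = np.exp(u)
        theo = two_population_curve(
            d_eff, k_star, k_off, geometry, curve.times, adaptive=True
        )
        return curve.values - theo.values

    rng = np.random.default_rng(config.seed)
    d0 = np.exp(
        rng.uniform(
            np.log(config.d_bounds[0]),
            np.log(config.d_bounds[1]),
            size=config.n_starts,
        )
    )
    r0 = np.clip(
        rng.exponential(1.0 / config.init_rate_lambda, size=(config.n_starts, 2)),
        config.rate_lower_bound,
        config.rate_upper_bound,
    )
    starts = np.log(np.column_stack([d0, r0]))

    solutions: list[tuple[np.ndarray, float]] = []
    for start in starts:
        try:
            sol = least_squares(
                obj,
                start,
                bounds=(lower, upper),
                method="trf",
                max_nfev=config.max_nfev,
            )
            solutions.append((np.exp(sol.x), 2.0 * sol.cost))
        except Exception as exc:  # noqa: BLE001 - per-start diagnostics
            logger.debug("reduced-fit start failed: %s", exc)
    if not solutions:
        raise RuntimeError("all reduced-model starts failed")
    solutions.sort(key=lambda s: s[1])
    x_best, rss = solutions[0]
    scale = np.maximum(np.abs(x_best), 1e-12)
    conv = sum(
        1
        for x, _ in solutions
        if np.max(np.abs(x - x_best) / scale) <= config.cluster_tol
    )

    # linearized standard errors in the natural parameters
    def obj_nat(x: np.ndarray) -> np.ndarray:
        return obj(np.log(x))

    n, p = curve.times.size, 3
    J = np.empty((n, p))
    r0_vec = obj_nat(x_best)
    for j in range(p):
        h = 1e-6 * x_best[j]
        xp, xm = x_best.copy(), x_best.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (obj_nat(xp) - obj_nat(xm)) / (2 * h)
    del r0_vec
    jtj = J.T @ J
    s2 = rss / (n - p)
    cov = s2 * np.linalg.pinv(jtj)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    d_eff, k_star, k_off = x_best
    try:
        gamma = invert_leading_order(float(d_eff), d_free)
    except ValueError:
        logger.warning(
            "fitted D_eff=%.4g not below the free D=%.4g; gamma undefined",
            d_eff, d_free,
        )
        gamma = float("nan")
    return ReducedFit(
        d_eff=float(d_eff),
        k_star=float(k_star),
        k_off=float(k_off),
        rss=float(rss),
        aicc=aicc(rss, n, p),
        conv_count=conv,
        n_points=n,
        gamma=gamma,
        d_free=float(d_free),
        std_errors=dict(zip(("D_eff", "k_star", "k_off"), se)),
    )


# ---------------------------------------------------------------------------
# RSS surface over (gamma_b, gamma_u)
# ---------------------------------------------------------------------------


@dataclass
class SurfaceTable:
    """RSS evaluated on a (γ_b, γ_u) grid, other rates fixed or re-optimized."""

    gamma_b: np.ndarray  # grid values, length nb
    gamma_u: np.ndarray  # grid values, length nu
    rss: np.ndarray  # shape (nb, nu)
    mode: str  # "fixed" or "profile"
    model_id: int
    base_rates: RateSet

    def minima(self, rtol: float = 1e-3) -> list[tuple[int, int]]:
        """Grid indices whose RSS is within ``rtol`` (relative) of the minimum."""
        m = float(np.min(self.rss))
        hits = np.argwhere(self.rss <= m * (1 + rtol) + 1e-300)
        return [tuple(ij) for ij in hits]

    def to_text(self) -> str:
        lines = ["gamma_b_per_s\tgamma_u_per_s\trss"]
        for i, gb in enumerate(self.gamma_b):
            for j, gu in enumerate(self.gamma_u):
                lines.append(f"{gb:.8g}\t{gu:.8g}\t{self.rss[i, j]:.10e}")
        return "\n".join(lines)


def rss_surface(
    model_id: int,
    curve: RecoveryCurve,
    geometry: FrapGeometry,
    gamma_b_grid: np.ndarray,
    gamma_u_grid: np.ndarray,
    base_rates: RateSet,
    mode: str = "fixed",
    config: FitConfig | None = None,
) -> SurfaceTable:
    """RSS over a (γ_b, γ_u) grid with the remaining rates fixed or profiled.

    ``mode="fixed"`` holds the non-grid rates at ``base_rates``;
    ``mode="profile"`` re-optimizes the model's other active rates at each
    node (warm-started from ``base_rates``). In the fast-exchange regime the
    surface exhibits a ray of equal-RSS minima along constant γ = γ_b/γ_u;
    under the default, narrower search bounds a single basin remains.
    """
    if mode not in ("fixed", "profile"):
        raise ValueError("mode must be 'fixed' or 'profile'")
    model = get_model(model_id)
    if not {"gamma_b", "gamma_u"} <= set(model.active_names):
        raise ValueError("rss_surface needs a model with gamma_b and gamma_u active")
    gb = np.asarray(gamma_b_grid, dtype=float)
    gu = np.asarray(gamma_u_grid, dtype=float)
    if np.any(gb <= 0) or np.any(gu <= 0):
        raise ValueError("grid rates must be positive")
    config = config or FitConfig()
    other = [n for n in model.active_names if n not in ("gamma_b", "gamma_u")]

    out = np.empty((gb.size, gu.size))
    for i, b in enumerate(gb):
        for j, u in enumerate(gu):
            node_rates = base_rates.with_rates(gamma_b=float(b), gamma_u=float(u))
            if mode == "fixed" or not other:
                r = residuals(model, node_rates, geometry, curve)
                out[i, j] = float(np.sum(r * r))
                continue

            def obj(logx: np.ndarray, _node=node_rates) -> np.ndarray:
                upd = dict(zip(other, np.exp(logx)))
                return residuals(model, _node.with_rates(**upd), geometry, curve)

            x0 = np.log([getattr(base_rates, n) for n in other])
            lo = np.full(len(other), np.log(config.rate_lower_bound))
            hi = np.full(len(other), np.log(config.rate_upper_bound))
            sol = least_squares(
                obj,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                method="trf",
                max_nfev=config.max_nfev,
            )
            out[i, j] = float(2.0 * sol.cost)
    return SurfaceTable(
        gamma_b=gb,
        gamma_u=gu,
        rss=out,
        mode=mode,
        model_id=model_id,
        base_rates=base_rates,
    )


# ---------------------------------------------------------------------------
# Group comparison (two-sample Kolmogorov–Smirnov)
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Two-sample KS comparison of per-curve estimates of one parameter."""

    parameter: str
    samples_a: np.ndarray
    samples_b: np.ndarray
    statistic: float
    pvalue: float
    direction: str  # "increase", "decrease" or "none" (B relative to A, by median)
    significant: bool
    alpha: float
    flags: dict[str, str] = field(default_factory=dict)


def ks_group_compare(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    alpha: float = 0.05,
    parameter: str = "",
) -> GroupComparison:
    """Two-sample Kolmogorov–Smirnov test between per-curve estimates.

    Uses the exact two-sample p-value when both samples have at most 25
    observations and the asymptotic formula otherwise. Direction is the sign
    of the median difference (B minus A). Fully tied (degenerate) samples are
    flagged.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    method = "exact" if (a.size <= 25 and b.size <= 25) else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    med_diff = float(np.median(b) - np.median(a))
    if med_diff > 0:
        direction = "increase"
    elif med_diff < 0:
        direction = "decrease"
    else:
        direction = "none"
    flags: dict[str, str] = {}
    if np.unique(np.concatenate([a, b])).size == 1:
        flags["degenerate"] = "all observations identical"
    pvalue = float(min(1.0, res.pvalue))
    return GroupComparison(
        parameter=parameter,
        samples_a=a,
        samples_b=b,
        statistic=float(res.statistic),
        pvalue=pvalue,
        direction=direction,
        significant=bool(pvalue < alpha),
        alpha=alpha,
        flags=flags,
    )
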