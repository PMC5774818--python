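# Methods

This note records the mathematical conventions and numerical choices behind
`h1frap`, in enough detail to re-derive every formula in the code.

## 1. Reaction–diffusion system

Let `u(x,t)`, `w(x,t)`, `v(x,t)` be the fluorescent (unbleached) fractions of
the free, weakly bound and strongly bound pools on `x ∈ [0, L]` with no-flux
boundaries. With the six rates named in the README,

```
u_t = D u_xx − (kappa_b + gamma_b) u + gamma_u w + kappa_u v
w_t =           gamma_b u − (gamma_u + eta_b) w + eta_u v
v_t =           kappa_b u + eta_b w − (kappa_u + eta_u) v
```

Before the bleach the system sits at its steady state `(P_u, P_w, P_v)`,
the normalized kernel of the reaction matrix `R` (the right-hand side without
diffusion). Cofactor expansion gives closed forms

```
Pi_u = kappa_u·eta_b + kappa_u·gamma_u + eta_u·gamma_u
Pi_w = gamma_b·kappa_u + gamma_b·eta_u + kappa_b·eta_u
Pi_v = eta_b·gamma_b + eta_b·kappa_b + gamma_u·kappa_b
P_i  = Pi_i / (Pi_u + Pi_w + Pi_v)
```

valid for every pathway model with all three states reachable; the
two-population model 0 uses `P_u = kappa_u/(kappa_b+kappa_u)` directly.
`steady_state` raises if the active-rate pattern makes the kernel degenerate.
Mean transition times are reciprocals of rates, e.g. `tau_uw = 1/gamma_b`.

At `t = 0` a band `|x − c| < h` is bleached to zero in all three pools and
the mean unbleached fraction over the band, `F(t)`, is observed.

## 2. Series solution

Expanding in the Neumann cosine basis `cos(nπx/L)` decouples the PDE into a
3×3 linear ODE per mode with matrix `R − diag(ξ_n, 0, 0)`,
`ξ_n = D (nπ/L)²`. Its characteristic polynomial is the cubic

```
s³ + (Σ_total + ξ_n) s² + (Π_total + Σ_u ξ_n) s + Π_u ξ_n = 0
```

where `Σ_total` is the sum of all active rates, `Σ_u` the sum of rates out of
bound states plus the unbinding-side rates (`kappa_u + gamma_u + eta_b +
eta_u`), `Π_total = Pi_u + Pi_w + Pi_v` and `Π_u = Pi_u`. All roots have
negative real part for valid rate sets (the per-mode matrix is a compartment
matrix minus a positive leak). The recovery is

```
F(t) = (1 − g(t)) − pref · Σ_{n≥1} (ℓ_n(t) − g(t)) S_n²,
pref = L² / ((L − 2h) h),   S_n = band Fourier factor,
ℓ_n(t) = Σ_i A_{i,n} exp(z_{i,n} t),   A_{i,n} = (z² + Σ_total z + Π_total)/Π_{j≠i}(z_i − z_j)
```

and `g(t) = 1ᵀ exp(M₂ t) (P_w, P_v)ᵀ` is the *immobile kernel*: the recovery
a mode with `ξ → ∞` would have (only the bound pools refill, by exchange).
Subtracting `g` from every mode term and adding it back through the Parseval
identity `pref·Σ S_n² = 1` makes the corrected terms decay like `n⁻⁴`
instead of `n⁻²`, so the adaptive summation (`tolerance 1e-10, run of 10
negligible chunks`) typically stops well below 1000 modes.

Cubic roots are obtained for all modes at once from batched companion-matrix
eigenvalues. Complex-conjugate pairs (they occur for strongly directed
cycles, e.g. `kappa_u = gamma_b = eta_b = 1, gamma_u = 0.02, D = 0.5`) are
kept in complex arithmetic and recombined to a real form; numerically
repeated roots (pair-relative gap below 1e-9) are split symmetrically before
computing residues, which keeps the partial-fraction formula finite.

Seven positivity/ordering conditions define a *valid* rate set. Six are
structural and always enforced by the solver; the seventh
(`kappa_u < gamma_u`, "strong binding is slower than weak") only labels which
bound state is which, so it is enforced only under `strict=True` and its
violation in a fit is flagged as `validity` without counting as overfitting.

## 3. Finite-difference oracle

`h1frap.reference` integrates the same PDE with a cell-centred reflecting
Laplacian and `scipy.integrate.solve_ivp` (BDF, sparse Jacobian, rtol 1e-9).
The bleach band is snapped to cell boundaries; grids with `m` a multiple of
64 place the edges exactly, giving clean second-order convergence (observed
error ratios 3.97 and 3.88 for m = 192/384/768; sup error ≈ 5e-7 at m = 640).
The oracle shares no code with the series solver beyond the rate container,
so agreement (sup-norm ≤ 1e-3 across six regimes in the acceptance suite,
actually ~1e-6) is a genuine cross-check.

## 4. Synthetic data

The default acquisition mirrors a realistic timelapse: samples every 5 s to
50 s, every 10 s to 150 s, every 15 s to 450 s, then every 20 s (57 points to
790 s). Noise is additive Gaussian (default σ = 0.0067; most studies here use
0.005). Cohorts draw per-cell rates from mean-preserving lognormals
(`draw_cell_rates`, default CV 20%) with `SeedSequence.spawn` streams so any
cell is reproducible independently.

## 5. Fitting

`multistart_fit` minimizes the residual sum of squares with
`scipy.optimize.least_squares` (TRF) **in log space**: parameters are
`ln(rate)`, bounds `[1e-4, 1e2] s⁻¹` (rates), `[1e-4, 1e3]` for a free `D`.
The log parameterization matters: rates span five decades, and in natural
space TRF needs ~5–20× more Jacobian evaluations to traverse the valley.
Starts are drawn i.i.d. Exponential(λ = 0.8 s), clipped to the box. Converged
solutions are clustered at 1e-3 relative distance; `conv_count` reports how
many starts reached the best cluster. Standard errors come from the
Gauss–Newton covariance `σ̂²(JᵀJ)⁻¹` with a central finite-difference
Jacobian in natural space; a condition number above 1e12 sets a
`non_identifiable` flag and switches to the pseudoinverse.

Overfitting diagnostics: an active rate below 1e-6 s⁻¹ is *numerically zero*;
one within 1% of a bound is *pinned*. Either flag (or `non_identifiable`)
disqualifies a model in `compare_models`. Ranking uses
`AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with `k = p + 1` (the noise
variance counts as a parameter); models within 1e-4 of each other are chained
into tie groups — on single-curve data the four-rate topologies 6–9 are
empirically indistinguishable and tie to machine precision, which is the
central model-comparison message: the data identify *how many* exchange
pathways are needed, not *which* topology.

A practical identifiability fact: with a first sample at 5 s, the free-pool
diffusion coefficient is not identifiable at D ≈ 25 μm²/s (the diffusive
transient lasts `h²/D ≈ 0.02 s`); fitting `D` requires sub-second samples.
That is why `D` is fixed by default (`FitConfig.d_fixed = 25.0`).

## 6. Leading-order reduction

When weak exchange (`gamma_b, gamma_u`) is much faster than the remaining
rates, `u` and `w` equilibrate instantly in ratio `γ = gamma_b/gamma_u` and
the merged pool behaves as a single diffusing species:

```
D_eff = D/(1+γ),  k* = (kappa_b + eta_b·γ)/(1+γ),  k_off = kappa_u + eta_u.
```

`reduced_model_curve` evaluates the resulting two-population recovery;
`leading_order_adequacy` compares it with the full model on a given curve
(sup separation below 1% of the recovery range = adequate). Convergence is
first order in the scale of the fast rates (measured sup separations 0.39 /
7.1e-3 / 6.3e-5 at scale 10 / 1e3 / 1e5). The reduction also explains the
fast-exchange degeneracy: only `γ` is identified, so the RSS is flat along
rays `gamma_b = γ·gamma_u` (measured spread 3e-9 across `gamma_b ∈ [1e3,
1e4]`), while physiological-scale data give a unique optimum.
`invert_leading_order(D_eff, D) = D/D_eff − 1` recovers `γ` from a fitted
effective diffusion coefficient.

## 7. Group comparison

`ks_group_compare` runs a two-sample Kolmogorov–Smirnov test per rate
(exact method when both groups have ≤ 25 cells), reports direction by the
median shift and flags degenerate (all-identical) inputs. The acceptance
suite verifies 5% type-I calibration within two Monte-Carlo standard errors
over 500 null cohort pairs and ≥ 80% power for a 2× shift in `gamma_u` at
15 cells per group.

## 8. Known limitations

* The bleach is ideal (sharp band, instantaneous, complete) and acquisition
  bleaching is not modelled.
* Noise is homoscedastic Gaussian; real photon noise is signal-dependent.
* The geometry is one-dimensional; `L`, `h`, `c` are configurable but a 2-D
  nucleus outline is not.
* AICc assumes independent residuals; temporally correlated noise would
  overstate the confidence of model ranking.
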