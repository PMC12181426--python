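# Methods

## Model and assumptions

The package models RNA silencing as a well-mixed, continuous-concentration
kinetic system in four pools: dsRNA trigger `S`, loaded RISC `R`, RISC–mRNA
complex `C`, and target mRNA `M`. Dicer degrades dsRNA (rate `ι_a`, per
molecule per time unit), releasing `n` siRNA-loaded RISCs per molecule;
RISC binds mRNA by mass action (`ι_b`, per molecule² per time unit); the
complex collapses (`ι_c`) or regenerates dsRNA (`ι_g`), which closes the
amplification loop; mRNA is produced at `ι_h` (per cell per time unit) and
decays nonspecifically at `ι_m`; RISC decays at `ι_r`. All parameters are
strictly positive by construction; `n` is a positive real, not an integer —
it enters every formula only as a rate multiplier. The reference set is
`n=5, ι_a=10, ι_b=0.001, ι_c=1, ι_h=1000, ι_g=1, ι_m=1, ι_r=0.1`.

Environmental fluctuation is modelled as multiplicative white noise on the
four degradation/collapse rates (`ι_a, ι_r, ι_c, ι_m → rate + σᵢ dBᵢ/dt`),
giving a four-channel Itô SDE whose `σ=0` limit is the deterministic model.
The `σ₁` channel appears in both the `S` and `R` equations (with coefficient
`−σ₁S` and `+σ₁nS`), because the same Dicer event removes a dsRNA and
produces `n` RISCs.

## Equilibria and feasibility

Setting the right-hand side to zero and writing `d = ι_g(n−1) − ι_c`:

```
M* = (ι_g+ι_c) ι_r / (ι_b d)
C* = ι_h/(ι_g+ι_c) − ι_m M*/(ι_g+ι_c)
R* = C* d / ι_r
S* = (ι_g/ι_a) C*
```

A variant of `C*` circulates in the literature with the `ι_b` dropped from
the second term's denominator; substituting it back into the steady-state
system leaves a residual of ≈ −66.6 at the reference values, so this package
derives `C*` from the equations directly and *enforces* correctness by a
residual check: the max-norm of the right-hand side at `ξ*` must be ≤ 1e-9
(double precision comfortably achieves ~1e-13 at reference magnitudes up to
1.5e4). The literature's companion inequality
`ι_h(ι_g(n−1)−ι_c) > ι_m ι_c ι_r` is likewise inconsistent with the
steady-state algebra; it is still evaluated and reported
(`printed_inequality_holds`) for transparency, but feasibility is defined
operationally as strict positivity of all four components of `ξ*`. Under
the corrected algebra this is exactly equivalent to `R₀ > 1`
(`C* > 0 ⇔ ι_b ι_h d > ι_m ι_r (ι_g+ι_c) ⇔ R₀ > 1`), and the equivalence is
verified on a 1000-draw random parameter sweep in the tests.

`R₀` itself is computed twice — closed form and numeric spectral radius of
`F V⁻¹` at `ξ⁰` — and the two must agree to 1e-10 relative; the closed form
is returned.

The diagnostic linear-growth/Lipschitz constants follow the standard
sup-norm bounding of the right-hand side. One reading choice: the mRNA
Lipschitz constant is `ι_m + ι_b N_R` (the factor multiplying `ι_b` in
`|−(M₁−M₂)(ι_m+ι_b R)|` is `R`, so it is bounded by the RISC bound `N_R`,
not the mRNA bound).

## Discretisation

Three schemes share one stepper:

* **euler** — Euler–Maruyama: drift increment plus raw diffusion increments.
  With all `σ = 0` it is forward Euler for the ODE; the stochastic branch is
  skipped entirely in that case, so the Milstein variants collapse to it
  *bitwise*.
* **milstein_ito** (default) — adds the diagonal Itô–Milstein correction
  `½ b (∂b/∂x)(ΔB² − Δt)` per diffusion term. For the `R` equation's `B₁`
  term the coefficient `σ₁nS` depends on `S`, whose own `B₁` diffusion is
  `−σ₁S`; the chain rule therefore gives `−½σ₁²nS(ΔB₁²−Δt)`. Cross-channel
  Lévy-area integrals are not simulated (standard practice), so the scheme
  is exactly strong order 1 only with a single active channel — the `R`
  equation mixes `B₁` and `B₂` with state-dependent coefficients, and the
  convergence-order estimator refuses multi-channel noise for this reason.
* **milstein_paper_literal** — reproduces, term for term, the printed
  discretisation this implementation is modelled on: all correction terms
  carry a negative sign and the `R` correction carries `n²` rather than `n`.
  These choices do not follow from Itô calculus for the stated SDE and the
  intended derivation is not recoverable; the variant is provided for
  fidelity and comparison, never silently substituted.

A claim sometimes attached to this scheme — convergence at `O(Δt²)` — does
not match standard strong-convergence theory (order 1 for diagonal Milstein,
½ for Euler–Maruyama); the package's empirical order estimator measures ≈1.0
for single-channel Milstein and this is what the tests assert.

**RNG contract.** One `numpy` generator per trajectory, created from the
seed; each step consumes exactly four N(0,1) draws in the fixed order
(τ₁..τ₄), whether or not a channel is active, so switching a `σ` on or off
never shifts the stream. Ensemble replicate `k` uses a seed derived from
`(base_seed, k)` via `numpy.random.SeedSequence`, and equals a standalone
run at that seed. Ensembles are integrated as one vectorised array; the
per-replicate batched draws preserve the per-step order.

**Grid.** Uniform `dt` with a shortened final step when `dt` does not
divide `t_end`; diffusion terms always use the square root of the actual
step. Defaults `dt = 0.001`, `t_end = 50` were chosen so the deterministic
run visibly saturates at `ξ*` (no reference step size or horizon exists to
inherit).

**Negativity.** The exact solution is positive with probability one, but
the discretisation is not; grid points with any negative component are
counted (`positivity_violations`) and, only if `clip_at_zero` is set,
clipped — clipping is off by default because it biases moments. At the
reference parameters with `σ = 0.2` on all channels and `dt = 0.001`,
excursions are rare (0–3 points per 50 000).

**Strong-order estimation.** For each sample path the Brownian increments
are drawn once on the reference grid (`dt_ref`) and coarsened by summation
for each test `dt` (nested grids required); the strong error at `dt` is the
mean end-time max-norm gap to the same scheme's `dt_ref` solution, and the
order is the least-squares slope of `log err` vs `log dt`.

## Stability analysis

The p-stability conditions (`p ≥ 2`) bound `σᵢ²(p−1)/2` strictly below
`ι_a`, `ι_r + ι_b ι_h/ι_m`, `ι_g + ι_c` for i = 1, 2, 3; no condition
constrains `σ₄`, and none is invented. Inequalities are evaluated exactly —
boundary equality reports not-satisfied. Two Lyapunov functions are
exposed: the logarithmic one, `Σ(x − 1 − log x)`, used in the
global-existence argument together with its drift bound

```
F = ½Σσᵢ² + σ₁²n²S²/(2R²) + ι_a + ι_a n S + ι_r + ι_b M
    + ι_g + ι_c + ι_h + ι_m + ι_b R
```

(one token in the circulating form of this bound is ambiguous and is read
as `ι_b M`, matching the symmetric `ι_b R` term and the `RM` products of
the derivation), and the power-law one,
`(1/p)(S^p + R^p + C^p + (ι_h/ι_m − M)^p)`, defined for `S,R,C ≥ 0` and
`M ≤ ι_h/ι_m`.

**Scope of the stability conditions.** With `σ₄ > 0` the mRNA diffusion
`−σ₄ M dB₄` does not vanish at `ξ⁰`, so `ξ⁰` is not a fixed point of the
SDE and `E‖X_t − ξ⁰‖^p` cannot decay to zero: it plateaus near the
stationary mRNA variance, approximately
`σ₄²(ι_h/ι_m)²/(2ι_m − σ₄²)` (≈ 2.0e4 at the reference values with
`σ₄ = 0.2`). The empirical probe `empirical_moment_decay` makes this
visible: in the subcritical regime (`n = 1`, so `R₀ ≈ 0.45 < 1`) with noise
0.2 on channels 1–3 and `σ₄ = 0` the fitted second-half slope of
`log E‖X − ξ⁰‖²` is ≈ −0.84 for every seed, whereas adding `σ₄ = 0.2`
produces a plateau with slopes scattered around zero. The analytic
conditions should therefore be read as controlling the `S`, `R`, `C`
moments; global decay of the full distance additionally requires the mRNA
channel to be noiseless.

There is a second, distinct tension: at the reference parameters `R₀ > 1`,
so the deterministic `ξ⁰` is not attracting even though the p = 2 noise
conditions hold at `σ = 0.2`. The decay probe therefore defaults to the
subcritical `n = 1` set in tests; the package exposes both the condition
check and the probe and lets the user compare.

## Deterministic relaxation timescale

The Jacobian at the interior equilibrium (reference parameters) has
eigenvalues ≈ {−10.08, −15.01, −1.98, −0.0933}: after the fast transient,
convergence proceeds at rate 0.0933 per time unit. Consequently the
low-dose run (`S(0)=10`) is still ≈1.8% from `ξ*` in the RISC and mRNA
components at `t = 50` and first comes within 1% of every component near
`t ≈ 56`; the high-dose run (`S(0)=1000`) is inside 1% by `t = 50`. The
integrator itself matches an adaptive reference (LSODA, rtol 1e-10) to four
digits at `t = 50`. The scientifically meaningful dose-independence
statement — both doses converge to the *same* silencing level — holds and
is tested as agreement of the two final states.

Relatedly, at moderate noise (`σ₁ = 0.2`) and step sizes `2⁻⁶..2⁻¹⁰`, the
end-time max-norm strong error of Euler–Maruyama is dominated by the shared
deterministic `O(Δt)` truncation error of the stiff mRNA/RISC components
(the EM and Milstein error tables agree to three digits), so a fitted EM
slope in that regime sits near 1 rather than the asymptotic ½; the ½ regime
emerges only below `dt ≈ 2⁻¹³` at this noise level, or at larger `σ₁`
(σ₁ = 1.2 gives slope ≈ 0.69 over the same grid).

## Test and simulation sizes

Problem sizes used in the suite are the package's own defaults balancing
statistical resolution against runtime: 1000-draw parameter sweeps
(log-uniform over [0.3×, 3×] each reference rate, `n` over [1.2, 15] — a
realistic spread of rate constants), 200 coupled paths for order
estimation, 500 replicates for small-noise ensemble means, 200 replicates ×
5 base seeds for moment-decay probes, and `dt = 0.001` for production-grade
trajectories.

## What the simulations do not capture

Concentrations are continuous and well-mixed: no discrete-copy-number
effects (relevant at the ~10-molecule dsRNA doses modelled), no spatial
transport or localisation, no transcriptional delays, and rate fluctuations
are idealised as white (uncorrelated) noise. Passing tests therefore
validate the mathematical model and its integrators, not the biology at low
copy number; conclusions near `S ≈ 0` in particular should be treated as
properties of the SDE idealisation.
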