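# rnasilencing

Deterministic and stochastic kinetics of RNA interference: steady states,
basic reproduction number, moment-stability conditions, and seeded
Milstein/Euler SDE simulation.

## The problem

RNA silencing (RNA interference) is triggered by double-stranded RNA: Dicer
cleaves each dsRNA molecule into siRNA fragments that load the RNA-induced
silencing complex (RISC), RISC binds its target mRNA, and collapse of the
bound complex degrades the message. Because the complex can also regenerate
dsRNA, the pathway contains a positive feedback loop — a small trigger dose
can amplify into a self-sustaining silencing reaction that holds mRNA at a
persistently reduced level. This package is for modellers who want to ask
quantitative questions about that loop: when does silencing take off, how
robust is it to random fluctuations of the enzymatic rates, and how should
the stochastic dynamics be simulated reproducibly.

## The model

Four molecular pools — dsRNA `S`, RISC `R`, RISC–mRNA complex `C`, and mRNA
`M` — evolve under mass-action kinetics:

```
dS/dt = −ι_a S + ι_g C
dR/dt =  n ι_a S − ι_r R − ι_b R M
dC/dt =  ι_b R M − (ι_g + ι_c) C
dM/dt =  ι_h − ι_m M − ι_b R M
```

with reference rates `n = 5`, `ι_a = 10`, `ι_b = 0.001`, `ι_c = 1`,
`ι_h = 1000`, `ι_g = 1`, `ι_m = 1`, `ι_r = 0.1`. The system has a
silencing-free steady state `ξ⁰ = (0, 0, 0, ι_h/ι_m)` and, when the loop is
self-sustaining, an interior silencing state `ξ*` with mRNA strongly
reduced. Take-off is governed by the next-generation-matrix reproduction
number

```
R₀ = n ι_g ι_b ι_h / ((ι_g + ι_c)(ι_b ι_h + ι_r ι_m)),
```

and `ξ*` exists (all components positive) exactly when `R₀ > 1`.

The stochastic extension perturbs the four degradation/collapse rates with
independent multiplicative white noise `σ₁..σ₄`:

```
dS = (−ι_a S + ι_g C) dt − σ₁ S dB₁
dR = (n ι_a S − ι_r R − ι_b R M) dt + σ₁ n S dB₁ − σ₂ R dB₂
dC = (ι_b R M − (ι_g + ι_c) C) dt − σ₃ C dB₃
dM = (ι_h − ι_m M − ι_b R M) dt − σ₄ M dB₄
```

Sufficient conditions for exponential p-stability of `ξ⁰` bound
`σᵢ²(p−1)/2` (i = 1, 2, 3) strictly below `ι_a`, `ι_r + ι_b ι_h/ι_m`, and
`ι_g + ι_c` respectively. The package evaluates these conditions, the
Lyapunov functions behind them, and integrates the SDE with Euler–Maruyama
or Milstein discretisations (both the conventional Itô–Milstein correction
and a literal legacy variant; see `docs/methods.md`).

## Worked example

```
$ rnasilencing equilibria
{
 "feasible": true,
 "residual_xi0": 0.0,
 "residual_xi_star": 1.1368683772161603e-13,
 "xi0":     {"S": 0.0, "R": 0.0, "C": 0.0, "M": 1000.0},
 "xi_star": {"S": 46.66666666666667, "R": 14000.0,
             "C": 466.6666666666667, "M": 66.66666666666667},
 ...
}
```

Without silencing, mRNA sits at `ι_h/ι_m = 1000` molecules. The feasible
interior state pins mRNA at ~67 molecules — a 15-fold knockdown sustained by
~14 000 RISC complexes — and the residual shows it satisfies the
steady-state equations to machine precision.

```
$ rnasilencing r0
{"r0_closed_form": 2.2727272727272725, "r0_spectral_radius": 2.2727272727272725, ...}
```

`R₀ = 25/11 ≈ 2.27 > 1`: the silencing reaction self-amplifies, which is why
the interior state above exists. The closed form and the numeric spectral
radius of `F V⁻¹` agree to 13 digits.

```
$ rnasilencing stability --sigma 0.2 0.2 0.2 0.2 --p 2
{"all_satisfied": true, "lhs": [0.02, 0.02, 0.02],
 "thresholds": [10.0, 1.1, 2.0], "margins": [9.98, 1.08, 1.98], ...}
```

Noise of intensity 0.2 on every channel sits far inside the p = 2 stability
region: each `σᵢ²/2 = 0.02` is two to three orders of magnitude below its
threshold.

```
$ rnasilencing simulate --scenario fig2a --out run.csv   # σᵢ = 0.2, S(0) = 10
$ rnasilencing converge --sigma 0.2 0 0 0 --scheme milstein_ito
```

`simulate` writes a seeded trajectory CSV (`t,S,R,C,M`) with a JSON metadata
sidecar; `converge` estimates the empirical strong order of a scheme along
coupled Brownian paths (≈1.0 for single-channel Milstein). Predefined
scenarios `fig1a…fig6b` cover the studied regimes: the deterministic model
from a low (10) or high (1000) dsRNA dose, uniform noise 0.2, and each
channel varied between 0.02 and 1.2. Configuration can also come from a
flat TOML/JSON file (keys: the eight rates, `sigma1..sigma4`,
`S0 R0 C0 M0`, `dt t_end scheme seed clip_at_zero`, `scenario`).

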