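"""Deterministic and stochastic kinetics of RNA interference.

The model tracks four molecular pools in a cell undergoing RNA silencing:
``S`` (double-stranded RNA, the silencing trigger), ``R`` (RNA-induced
silencing complex, RISC), ``C`` (RISC–mRNA complex) and ``M`` (target mRNA).
Dicer degrades dsRNA at rate ``iota_a``, releasing ``n`` siRNA-loaded RISCs
per molecule; RISC binds mRNA by mass action at rate ``iota_b``; the bound
complex either collapses (``iota_c``) or regenerates dsRNA (``iota_g``),
closing the amplification loop; mRNA is synthesised at ``iota_h`` and decays
nonspecifically at ``iota_m``; RISC decays at ``iota_r``:

    dS/dt = -iota_a S + iota_g C
    dR/dt =  n iota_a S - iota_r R - iota_b R M
    dC/dt =  iota_b R M - (iota_g + iota_c) C
    dM/dt =  iota_h - iota_m M - iota_b R M

The stochastic extension perturbs the four degradation/collapse rates
(iota_a, iota_r, iota_c, iota_m) with independent multiplicative white
noise of intensities sigma1..sigma4:

    dS = (-iota_a S + iota_g C) dt             - sigma1 S   dB1
    dR = ( n iota_a S - iota_r R - iota_b R M) dt + sigma1 n S dB1 - sigma2 R dB2
    dC = ( iota_b R M - (iota_g+iota_c) C) dt  - sigma3 C   dB3
    dM = ( iota_h - iota_m M - iota_b R M) dt  - sigma4 M   dB4

This module provides, in the order the analysis runs:

* the deterministic right-hand side, the two steady states (silencing-free
  ``xi0 = (0, 0, 0, iota_h/iota_m)`` and the interior silencing state
  ``xi*``), feasibility, and the next-generation-matrix basic reproduction
  number R0;
* linear-growth and Lipschitz diagnostic constants for the
  existence/uniqueness argument;
* Euler and Milstein discretisations of the SDE, seeded trajectory and
  ensemble simulation, ensemble moments, and empirical strong-convergence
  order estimation;
* exponential p-stability condition checking for ``xi0``, Lyapunov function
  evaluation, the drift bound used in the global-existence argument, and an
  empirical moment-decay probe;
* flat TOML/JSON run configuration, CSV trajectory serialisation with a JSON
  metadata sidecar, regression-fixture generation, and a command-line
  interface.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import json
import logging
import math
import sys
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import click
import numpy as np

__version__ = "1.0.0"

logger = logging.getLogger("rnasilencing")

__all__ = [
    "ModelParameters",
    "State",
    "Derivative",
    "EquilibriumSet",
    "NGMResult",
    "BoundConstants",
    "NoiseIntensities",
    "StepNoise",
    "Scheme",
    "IntegrationSettings",
    "Trajectory",
    "Ensemble",
    "EnsembleMoments",
    "OrderEstimate",
    "StabilityReport",
    "LyapunovValue",
    "MomentDecayResult",
    "RunConfig",
    "SCENARIOS",
    "rhs",
    "equilibria",
    "feasibility",
    "ngm_r0",
    "bound_constants",
    "euler_step",
    "milstein_step",
    "simulate",
    "simulate_ensemble",
    "derive_replicate_seed",
    "ensemble_moments",
    "strong_order_estimate",
    "p_stability_thresholds",
    "check_noise",
    "lyapunov_v",
    "lyapunov_vp",
    "drift_bound_f",
    "empirical_moment_decay",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "generate_fixtures",
    "run_cli",
    "InvalidInputError",
    "UsageError",
    "DomainError",
    "FormatError",
    "ConfigError",
    "SimulationOverflowError",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class InvalidInputError(ValueError):
    """A value violates a type invariant (non-finite, non-positive, ...)."""


class UsageError(ValueError):
    """An operation was called outside its contract (bad mode, bad grid)."""


class DomainError(ValueError):
    """A mathematical function was evaluated outside its domain."""


class FormatError(ValueError):
    """A serialized file does not match the documented layout."""


class ConfigError(ValueError):
    """A run configuration is unparseable or inconsistent."""


class SimulationOverflowError(FloatingPointError):
    """A trajectory became non-finite mid-run.

    Carries the step index at which the overflow occurred, the partial
    trajectory values computed so far, and (for ensembles) the replicate.
    """

    def __init__(self, message: str, step: int, partial: np.ndarray,
                 replicate: Optional[int] = None):
        super().__init__(message)
        self.step = step
        self.partial = partial
        self.replicate = replicate


# ---------------------------------------------------------------------------
# Deterministic model: parameters, state, right-hand side
# ---------------------------------------------------------------------------

#: Reference parameter values (rates per time unit, n dimensionless).
_DEFAULTS = dict(n=5.0, iota_a=10.0, iota_b=0.001, iota_c=1.0,
                 iota_h=1000.0, iota_g=1.0, iota_m=1.0, iota_r=0.1)


@dataclass(frozen=True)
class ModelParameters:
    """The eight positive rate constants of the silencing kinetics.

    Defaults are the reference parameter set used throughout: n=5,
    iota_a=10, iota_b=0.001, iota_c=1, iota_h=1000, iota_g=1, iota_m=1,
    iota_r=0.1.  All parameters must be strictly positive; ``n`` is a
    positive real (it enters every formula as a rate multiplier, so integer
    siRNA counts are not enforced).
    """

    n: float = 5.0          #: siRNAs per degraded dsRNA molecule
    iota_a: float = 10.0    #: Dicer-mediated dsRNA degradation rate
    iota_b: float = 0.001   #: RISC–mRNA mass-action binding rate
    iota_c: float = 1.0     #: complex collapse rate
    iota_h: float = 1000.0  #: mRNA synthesis rate
    iota_g: float = 1.0     #: dsRNA synthesis rate by the complex
    iota_m: float = 1.0     #: nonspecific mRNA degradation rate
    iota_r: float = 0.1     #: RISC degradation rate

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise InvalidInputError(f"parameter {f.name} must be finite, got {v!r}")
            object.__setattr__(self, f.name, float(v))
            if getattr(self, f.name) <= 0.0:
                raise InvalidInputError(
                    f"parameter {f.name} must be strictly positive, got {v!r}")

    @classmethod
    def _unvalidated(cls, **kwargs) -> "ModelParameters":
        # Bypasses the positivity check.  Used only for boundary-limit
        # studies (e.g. iota_b -> 0 inside ngm_r0); not part of the API.
        obj = object.__new__(cls)
        values = dict(_DEFAULTS)
        values.update(kwargs)
        for k, v in values.items():
            object.__setattr__(obj, k, float(v))
        return obj

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class State:
    """Molecule counts (S, R, C, M) at one time point.

    Components are real numbers; the constructor rejects NaN/inf.  Validity
    of a *model* state additionally requires non-negativity, which is
    checked explicitly via :meth:`is_nonnegative` rather than enforced
    silently (stochastic discretisations can and do produce negative
    excursions that the caller may want to observe).
    """

    S: float
    R: float
    C: float
    M: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise InvalidInputError(f"state component {f.name} must be finite, got {v!r}")
            object.__setattr__(self, f.name, float(v))

    def is_nonnegative(self) -> bool:
        """True iff all four components are >= 0 (a valid physical state)."""
        return self.S >= 0.0 and self.R >= 0.0 and self.C >= 0.0 and self.M >= 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.R, self.C, self.M], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "State":
        return cls(float(x[0]), float(x[1]), float(x[2]), float(x[3]))

    def to_dict(self) -> dict:
        return {"S": self.S, "R": self.R, "C": self.C, "M": self.M}


@dataclass(frozen=True)
class Derivative:
    """Rates of change (dS, dR, dC, dM), molecules per time unit."""

    dS: float
    dR: float
    dC: float
    dM: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise InvalidInputError(f"derivative component {f.name} is non-finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.dS, self.dR, self.dC, self.dM], dtype=float)

    def max_norm(self) -> float:
        return max(abs(self.dS), abs(self.dR), abs(self.dC), abs(self.dM))


def _drift_array(x: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Vectorised deterministic right-hand side; x has shape (..., 4)."""
    S, R, C, M = x[..., 0], x[..., 1], x[..., 2], x[..., 3]
    bRM = p.iota_b * R * M
    return np.stack([
        -p.iota_a * S + p.iota_g * C,
        p.n * p.iota_a * S - p.iota_r * R - bRM,
        bRM - (p.iota_g + p.iota_c) * C,
        p.iota_h - p.iota_m * M - bRM,
    ], axis=-1)


def rhs(state: State, params: ModelParameters) -> Derivative:
    """Deterministic right-hand side of the silencing kinetics.

    Returns (dS, dR, dC, dM) = (-iota_a S + iota_g C,
    n iota_a S - iota_r R - iota_b R M, iota_b R M - (iota_g+iota_c) C,
    iota_h - iota_m M - iota_b R M).
    """
    if not isinstance(state, State):
        state = State(*state)
    d = _drift_array(state.as_array(), params)
    return Derivative(*[float(v) for v in d])


# ---------------------------------------------------------------------------
# Equilibria, feasibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumSet:
    """The steady states of the deterministic model.

    ``xi0 = (0, 0, 0, iota_h/iota_m)`` always exists (silencing never takes
    off, mRNA sits at its synthesis/degradation balance).  The interior
    state ``xi_star`` — dsRNA, RISC, complex and mRNA all positive, mRNA
    persistently reduced — exists iff all four of its components are
    strictly positive (``feasible``).

    ``printed_inequality_holds`` reports the literal condition
    iota_h (iota_g (n-1) - iota_c) > iota_m iota_c iota_r that circulates in
    the literature for this model.  It is reported for reference only: it is
    not consistent with the steady-state algebra (the correct condition
    carries iota_b and (iota_g+iota_c); see ``equilibria``), so the
    ``feasible`` flag is defined by component positivity instead.
    """

    xi0: State
    xi_star: Optional[State]
    feasible: bool
    residual_xi0: float
    residual_xi_star: Optional[float]
    printed_inequality_holds: bool


def equilibria(params: ModelParameters) -> EquilibriumSet:
    """Solve the steady-state system exactly.

    Setting the right-hand side to zero gives, with
    d = iota_g (n - 1) - iota_c:

        M* = (iota_g + iota_c) iota_r / (iota_b d)
        C* = iota_h / (iota_g + iota_c) - iota_m M* / (iota_g + iota_c)
        R* = C* d / iota_r
        S* = (iota_g / iota_a) C*

    (the widely printed variant of C* drops the iota_b in the second term's
    denominator and does not satisfy the steady-state system; the form above
    does, and is enforced by the residual invariant).  ``xi_star`` is
    returned iff d > 0 and all four components are strictly positive; a
    non-positive branch yields ``feasible=False`` without raising.
    """
    p = params
    xi0 = State(0.0, 0.0, 0.0, p.iota_h / p.iota_m)
    residual_xi0 = rhs(xi0, p).max_norm()

    printed = p.iota_h * (p.iota_g * (p.n - 1.0) - p.iota_c) > p.iota_m * p.iota_c * p.iota_r

    d = p.iota_g * (p.n - 1.0) - p.iota_c
    xi_star = None
    residual_star = None
    feasible = False
    if d > 0.0:
        gc = p.iota_g + p.iota_c
        M_star = gc * p.iota_r / (p.iota_b * d)
        C_star = p.iota_h / gc - p.iota_m * M_star / gc
        R_star = C_star * d / p.iota_r
        S_star = (p.iota_g / p.iota_a) * C_star
        if min(S_star, R_star, C_star, M_star) > 0.0:
            xi_star = State(S_star, R_star, C_star, M_star)
            residual_star = rhs(xi_star, p).max_norm()
            feasible = True
    return EquilibriumSet(xi0=xi0, xi_star=xi_star, feasible=feasible,
                          residual_xi0=residual_xi0,
                          residual_xi_star=residual_star,
                          printed_inequality_holds=printed)


def feasibility(params: ModelParameters) -> bool:
    """True iff the interior silencing steady state exists with all
    components strictly positive (equivalently, R0 > 1)."""
    return equilibria(params).feasible


# ---------------------------------------------------------------------------
# Next-generation matrix and basic reproduction number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NGMResult:
    """Next-generation-matrix decomposition at the silencing-free state.

    ``F`` holds the new-"infection" derivatives (the single production term
    iota_b R M of the complex compartment, linearised at xi0 where
    M = iota_h/iota_m, so its only nonzero entry is iota_b iota_h / iota_m
    in the C row, R column).  ``V`` holds the remaining transition terms.
    ``r0`` is the spectral radius of F V^-1, returned as the closed form

        R0 = n iota_g iota_b iota_h
             / ((iota_g + iota_c) (iota_b iota_h + iota_r iota_m))

    after cross-checking it against the numeric spectral radius to 1e-10
    relative accuracy.
    """

    F: np.ndarray
    V: np.ndarray
    r0: float
    r0_spectral: float


def ngm_r0(params: ModelParameters) -> NGMResult:
    """Compute R0 by the next-generation-matrix method.

    Both routes — the closed form and the numeric spectral radius of
    F V^-1 — are evaluated and must agree to 1e-10 relative; disagreement
    or a singular V (impossible for positive parameters) raises a
    diagnostic error.
    """
    p = params
    bh_m = p.iota_b * p.iota_h / p.iota_m
    F = np.zeros((4, 4))
    F[2, 1] = bh_m
    V = np.array([
        [p.iota_a, 0.0, -p.iota_g, 0.0],
        [-p.iota_a * p.n, p.iota_r + bh_m, 0.0, 0.0],
        [0.0, 0.0, p.iota_g + p.iota_c, 0.0],
        [0.0, bh_m, 0.0, p.iota_m],
    ])
    try:
        K = F @ np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"transition matrix V is singular for parameters {p.to_dict()}: {exc}")
    r0_spec = float(np.max(np.abs(np.linalg.eigvals(K))))
    r0_closed = (p.n * p.iota_g * p.iota_b * p.iota_h
                 / ((p.iota_g + p.iota_c) * (p.iota_b * p.iota_h + p.iota_r * p.iota_m)))
    scale = max(abs(r0_closed), 1e-300)
    if abs(r0_closed - r0_spec) / scale > 1e-10 and abs(r0_closed - r0_spec) > 1e-12:
        raise FloatingPointError(
            f"closed-form R0 {r0_closed!r} and spectral radius {r0_spec!r} disagree")
    return NGMResult(F=F, V=V, r0=r0_closed, r0_spectral=r0_spec)


# ---------------------------------------------------------------------------
# Linear-growth and Lipschitz diagnostic constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundConstants:
    """Diagnostic constants of the existence/uniqueness argument.

    Given assumed sup-norm bounds (N_S, N_R, N_C, N_M) on the four
    components, the right-hand side is bounded (linear growth) by
    N_SS..N_MM and is Lipschitz in each component with constants
    kappa_S = iota_a, kappa_R, kappa_C, kappa_M.  kappa_M uses
    iota_m + iota_b N_R: the factor multiplying iota_b in the difference
    |-(M1-M2)(iota_m + iota_b R)| is R, so it is bounded by N_R.
    """

    N_S: float
    N_R: float
    N_C: float
    N_M: float
    N_SS: float
    N_RR: float
    N_CC: float
    N_MM: float
    kappa_S: float
    kappa_R: float
    kappa_C: float
    kappa_M: float


def bound_constants(sup_bounds: Sequence[float], params: ModelParameters) -> BoundConstants:
    """Fill the linear-growth and Lipschitz constants for given sup bounds."""
    if len(sup_bounds) != 4:
        raise InvalidInputError("sup_bounds must be (N_S, N_R, N_C, N_M)")
    N_S, N_R, N_C, N_M = (float(v) for v in sup_bounds)
    if not all(math.isfinite(v) and v > 0 for v in (N_S, N_R, N_C, N_M)):
        raise InvalidInputError("sup bounds must be finite and strictly positive")
    p = params
    return BoundConstants(
        N_S=N_S, N_R=N_R, N_C=N_C, N_M=N_M,
        N_SS=p.iota_a * N_S + p.iota_g * N_C,
        N_RR=p.iota_a * p.n * N_S + p.iota_r * N_R + p.iota_b * N_R * N_M,
        N_CC=p.iota_b * N_R * N_M + (p.iota_g + p.iota_c) * N_C,
        N_MM=p.iota_h + p.iota_m * N_M + p.iota_b * N_R * N_M,
        kappa_S=p.iota_a,
        kappa_R=p.iota_r + p.iota_b * N_M,
        kappa_C=p.iota_g + p.iota_c,
        kappa_M=p.iota_m + p.iota_b * N_R,
    )


# ---------------------------------------------------------------------------
# Stochastic model: noise, schemes, integration settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseIntensities:
    """White-noise intensities sigma1..sigma4 (per sqrt time unit).

    sigma1 perturbs the dsRNA degradation rate iota_a (its diffusion feeds
    both the S and R equations through the n-fold siRNA release), sigma2
    the RISC degradation rate iota_r, sigma3 the complex collapse rate
    iota_c, sigma4 the mRNA degradation rate iota_m.  All zero recovers
    the deterministic model.
    """

    sigma1: float = 0.0
    sigma2: float = 0.0
    sigma3: float = 0.0
    sigma4: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)) or v < 0:
                raise InvalidInputError(
                    f"noise intensity {f.name} must be finite and >= 0, got {v!r}")
            object.__setattr__(self, f.name, float(v))

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2, self.sigma3, self.sigma4])

    @property
    def is_zero(self) -> bool:
        return self.sigma1 == self.sigma2 == self.sigma3 == self.sigma4 == 0.0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class StepNoise:
    """Standard-normal draws (tau1..tau4) for one step, one per Brownian
    channel B1..B4.  The engine draws them i.i.d. N(0,1)."""

    tau1: float
    tau2: float
    tau3: float
    tau4: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise InvalidInputError(f"step noise {f.name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.tau1, self.tau2, self.tau3, self.tau4])


class Scheme(str, enum.Enum):
    """Discretisation schemes.

    ``euler``: Euler(–Maruyama): drift step plus raw diffusion increments,
    no correction terms; with all sigma = 0 it is the plain forward Euler
    ODE step.

    ``milstein_ito``: Euler–Maruyama plus the standard diagonal
    Itô–Milstein correction 1/2 b (db/dx) (tau^2 - 1) dt per diffusion
    term.  For the R equation's B1 diffusion (sigma1 n S) the coefficient
    depends on S, whose own B1 diffusion is -sigma1 S, so the chain rule
    gives the correction -1/2 sigma1^2 n S (tau1^2 - 1) dt.  Cross-channel
    Lévy-area terms are omitted (standard practice without iterated-integral
    simulation); the scheme is exactly strong order 1 with at most one
    active channel.  Default for convergence studies.

    ``milstein_paper_literal``: reproduces, term for term, the printed
    discretisation this implementation is modelled on — including its
    negative correction signs throughout and the n^2 factor in the R
    correction, which differ from the Itô–Milstein calculus.  Provided for
    fidelity; each equation uses the draw of the Brownian channel it
    discretises (tau1 for B1 terms, ... tau4 for B4).
    """

    EULER = "euler"
    MILSTEIN_PAPER_LITERAL = "milstein_paper_literal"
    MILSTEIN_ITO = "milstein_ito"


def _coerce_scheme(value) -> Scheme:
    if isinstance(value, Scheme):
        return value
    try:
        return Scheme(str(value))
    except ValueError:
        raise UsageError(
            f"unknown scheme {value!r}; expected one of "
            f"{[s.value for s in Scheme]}") from None


@dataclass(frozen=True)
class IntegrationSettings:
    """Grid and RNG contract for one trajectory.

    The grid is uniform with step ``dt`` and a shortened final step when
    ``dt`` does not divide ``t_end`` (diffusion terms use the square root
    of the actual step length).  One generator is created per trajectory
    from ``seed``; every step consumes exactly four N(0,1) draws in the
    fixed order (tau1, tau2, tau3, tau4) regardless of which sigmas are
    zero, so changing a noise intensity never shifts the stream.

    ``clip_at_zero``: negative components after a step are set to zero and
    the clip counted (off by default — silent clipping biases moments;
    negative excursions are counted either way in
    ``positivity_violations``).
    """

    dt: float = 0.001
    t_end: float = 50.0
    scheme: Scheme = Scheme.MILSTEIN_ITO
    seed: int = 0
    clip_at_zero: bool = False

    def __post_init__(self):
        object.__setattr__(self, "scheme", _coerce_scheme(self.scheme))
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise UsageError(f"dt must be > 0, got {self.dt!r}")
        if not (math.isfinite(self.t_end) and self.t_end > 0):
            raise UsageError(f"t_end must be > 0, got {self.t_end!r}")
        if self.dt > self.t_end:
            raise UsageError(f"dt={self.dt!r} exceeds t_end={self.t_end!r}")
        object.__setattr__(self, "seed", int(self.seed))

    def grid(self) -> np.ndarray:
        """Time grid: 0, dt, 2dt, ..., t_end (final step possibly short)."""
        n_steps = int(math.ceil(self.t_end / self.dt - 1e-9))
        times = np.minimum(self.dt * np.arange(n_steps + 1), self.t_end)
        times[-1] = self.t_end
        return times

    def to_dict(self) -> dict:
        return {"dt": self.dt, "t_end": self.t_end, "scheme": self.scheme.value,
                "seed": self.seed, "clip_at_zero": self.clip_at_zero}


# ---------------------------------------------------------------------------
# Steppers
# ---------------------------------------------------------------------------

_ZERO_NOISE = NoiseIntensities()


def _step_array(x: np.ndarray, p: ModelParameters, noise: NoiseIntensities,
                h: float, dB: np.ndarray, scheme: Scheme) -> np.ndarray:
    """One discretisation step, vectorised over leading axes.

    ``x`` and ``dB`` have shape (..., 4); ``dB`` carries the Brownian
    increments of the four channels over the step (tau_i * sqrt(h)).
    With all sigmas zero the noise branch is skipped entirely, so the
    result is bit-identical to the deterministic Euler step.

    Overflow is not trapped here: non-finite values propagate and are
    surfaced by the callers' explicit finiteness checks.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        return _step_array_impl(x, p, noise, h, dB, scheme)


def _step_array_impl(x, p, noise, h, dB, scheme):
    y = x + _drift_array(x, p) * h
    s1, s2, s3, s4 = noise.sigma1, noise.sigma2, noise.sigma3, noise.sigma4
    if noise.is_zero:
        return y
    S, R, C, M = x[..., 0], x[..., 1], x[..., 2], x[..., 3]
    dB1, dB2, dB3, dB4 = dB[..., 0], dB[..., 1], dB[..., 2], dB[..., 3]
    out = y.copy()
    out[..., 0] += -s1 * S * dB1
    out[..., 1] += s1 * p.n * S * dB1 - s2 * R * dB2
    out[..., 2] += -s3 * C * dB3
    out[..., 3] += -s4 * M * dB4
    if scheme is Scheme.EULER:
        return out
    # Milstein corrections, written in increment form:
    # (tau^2 - 1) dt == dB^2 - h.
    q1 = dB1 * dB1 - h
    q2 = dB2 * dB2 - h
    q3 = dB3 * dB3 - h
    q4 = dB4 * dB4 - h
    if scheme is Scheme.MILSTEIN_ITO:
        out[..., 0] += 0.5 * s1 * s1 * S * q1
        out[..., 1] += -0.5 * s1 * s1 * p.n * S * q1 + 0.5 * s2 * s2 * R * q2
        out[..., 2] += 0.5 * s3 * s3 * C * q3
        out[..., 3] += 0.5 * s4 * s4 * M * q4
    elif scheme is Scheme.MILSTEIN_PAPER_LITERAL:
        out[..., 0] += -0.5 * s1 * s1 * S * q1
        out[..., 1] += 0.5 * s1 * s1 * p.n * p.n * S * q1 - 0.5 * s2 * s2 * R * q2
        out[..., 2] += -0.5 * s3 * s3 * C * q3
        out[..., 3] += -0.5 * s4 * s4 * M * q4
    else:  # pragma: no cover - _coerce_scheme guards this
        raise UsageError(f"unknown scheme {scheme!r}")
    return out


_COMPONENTS = ("S", "R", "C", "M")


def _check_finite_step(y: np.ndarray, context: str) -> None:
    if np.isfinite(y).all():
        return
    bad = np.nonzero(~np.isfinite(np.atleast_2d(y)))
    comp = _COMPONENTS[int(bad[-1][0])]
    raise OverflowError(f"{context}: component {comp} became non-finite")


def euler_step(state: State, params: ModelParameters, dt: float) -> State:
    """One deterministic forward-Euler step: state + rhs(state) * dt."""
    if not (math.isfinite(dt) and dt > 0):
        raise UsageError(f"dt must be > 0, got {dt!r}")
    if not isinstance(state, State):
        state = State(*state)
    y = _step_array(state.as_array(), params, _ZERO_NOISE, dt,
                    np.zeros(4), Scheme.EULER)
    _check_finite_step(y, "euler_step")
    return State.from_array(y)


def milstein_step(state: State, params: ModelParameters,
                  noise: NoiseIntensities, dt: float, draws: StepNoise,
                  mode: Scheme | str = Scheme.MILSTEIN_ITO) -> State:
    """One Milstein step of the stochastic model.

    ``mode`` selects between the conventional Itô–Milstein correction
    (``milstein_ito``) and the literal printed discretisation
    (``milstein_paper_literal``); see :class:`Scheme`.  With all sigmas
    zero both modes reduce bitwise to :func:`euler_step`.
    """
    mode = _coerce_scheme(mode)
    if mode is Scheme.EULER:
        raise UsageError("mode must be a Milstein variant; use euler_step "
                         "or Scheme.EULER inside simulate() for Euler-Maruyama")
    if not (math.isfinite(dt) and dt > 0):
        raise UsageError(f"dt must be > 0, got {dt!r}")
    if not isinstance(state, State):
        state = State(*state)
    dB = draws.as_array() * math.sqrt(dt)
    y = _step_array(state.as_array(), params, noise, dt, dB, mode)
    _check_finite_step(y, "milstein_step")
    return State.from_array(y)


# ---------------------------------------------------------------------------
# Trajectories and ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """A seeded time series of the model state.

    ``values`` has shape (len(times), 4) with columns (S, R, C, M);
    ``positivity_violations`` counts grid points at which any component was
    negative (before clipping, if clipping is on).  The exact solution of
    the stochastic model stays positive with probability one, but its
    discretisation need not — the count makes excursions observable.
    """

    times: np.ndarray
    values: np.ndarray
    settings: IntegrationSettings
    params: ModelParameters
    noise: NoiseIntensities
    positivity_violations: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if v.shape != (t.shape[0], 4):
            raise InvalidInputError(
                f"values shape {v.shape} does not match grid of {t.shape[0]} points")
        if t.shape[0] == 0 or t[0] != 0.0:
            raise InvalidInputError("time grid must start at 0")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time grid must be strictly increasing")

    @property
    def states(self) -> tuple[State, ...]:
        return tuple(State.from_array(row) for row in self.values)

    @property
    def initial_state(self) -> State:
        return State.from_array(self.values[0])

    @property
    def final_state(self) -> State:
        return State.from_array(self.values[-1])


@dataclass(frozen=True)
class Ensemble:
    """Replicate trajectories sharing grid, parameters and noise."""

    replicates: tuple[Trajectory, ...]
    seeds: tuple[int, ...]

    def __post_init__(self):
        reps = tuple(self.replicates)
        seeds = tuple(int(s) for s in self.seeds)
        object.__setattr__(self, "replicates", reps)
        object.__setattr__(self, "seeds", seeds)
        if len(reps) == 0:
            raise InvalidInputError("ensemble needs at least one replicate")
        if len(seeds) != len(reps):
            raise InvalidInputError("one seed per replicate required")
        if len(set(seeds)) != len(seeds):
            raise InvalidInputError("replicate seeds must be pairwise distinct")
        t0 = reps[0].times
        for k, r in enumerate(reps[1:], start=1):
            if not np.array_equal(r.times, t0):
                raise InvalidInputError(f"replicate {k} grid differs from replicate 0")


@dataclass(frozen=True)
class EnsembleMoments:
    """Pointwise sample mean and unbiased sample variance, shape (T, 4)."""

    times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    n_replicates: int


def _simulate_paths(x0: np.ndarray, params: ModelParameters,
                    noise: NoiseIntensities, times: np.ndarray,
                    draws: np.ndarray, scheme: Scheme, clip_at_zero: bool):
    """Integrate P paths over a shared grid.

    ``x0``: (P, 4); ``draws``: (n_steps, P, 4) standard-normal.  Returns
    (values (T, P, 4), violations (P,)).  Raises SimulationOverflowError
    with the partial trajectory on the first non-finite step.
    """
    n_steps = len(times) - 1
    P = x0.shape[0]
    values = np.empty((n_steps + 1, P, 4))
    values[0] = x0
    violations = np.zeros(P, dtype=int)
    violations += (x0 < 0).any(axis=-1)
    x = x0.copy()
    for i in range(n_steps):
        h = float(times[i + 1] - times[i])
        dB = draws[i] * math.sqrt(h)
        x = _step_array(x, params, noise, h, dB, scheme)
        if not np.isfinite(x).all():
            bad_path = int(np.nonzero(~np.isfinite(x).all(axis=-1))[0][0])
            raise SimulationOverflowError(
                f"trajectory became non-finite at step {i + 1} "
                f"(t={times[i + 1]:g}), replicate {bad_path}",
                step=i + 1, partial=values[: i + 1], replicate=bad_path)
        neg = (x < 0).any(axis=-1)
        violations += neg
        if clip_at_zero:
            np.maximum(x, 0.0, out=x)
        values[i + 1] = x
    return values, violations


def simulate(initial: State, params: ModelParameters,
             noise: NoiseIntensities, settings: IntegrationSettings) -> Trajectory:
    """Integrate one seeded trajectory of the (stochastic) model.

    Per step the generator yields the four channel draws (tau1..tau4) in
    that fixed order; identical settings and seed give bitwise-identical
    trajectories.
    """
    if not isinstance(initial, State):
        initial = State(*initial)
    times = settings.grid()
    n_steps = len(times) - 1
    rng = np.random.default_rng(settings.seed)
    draws = rng.standard_normal((n_steps, 1, 4))
    values, violations = _simulate_paths(
        initial.as_array()[None, :], params, noise, times, draws,
        settings.scheme, settings.clip_at_zero)
    return Trajectory(times=times, values=values[:, 0, :], settings=settings,
                      params=params, noise=noise,
                      positivity_violations=int(violations[0]))


def derive_replicate_seed(base_seed: int, replicate: int) -> int:
    """Deterministic seed-splitting rule for ensemble replicates."""
    ss = np.random.SeedSequence(entropy=[int(base_seed), int(replicate)])
    return int(ss.generate_state(1, np.uint64)[0] >> 1)  # keep < 2**63


def simulate_ensemble(initial: State, params: ModelParameters,
                      noise: NoiseIntensities, settings: IntegrationSettings,
                      n_reps: int, base_seed: int) -> Ensemble:
    """Simulate independent replicates; replicate k runs with the seed
    derived deterministically from (base_seed, k) and is identical to a
    standalone :func:`simulate` call at that seed."""
    if n_reps < 1:
        raise UsageError(f"n_reps must be >= 1, got {n_reps}")
    if not isinstance(initial, State):
        initial = State(*initial)
    seeds = []
    for k in range(n_reps):
        s = derive_replicate_seed(base_seed, k)
        while s in seeds:  # pragma: no cover - astronomically unlikely
            s = (s + 1) % (1 << 63)
        seeds.append(s)
    times = settings.grid()
    n_steps = len(times) - 1
    # Each replicate draws from its own generator; batching the per-step
    # (tau1..tau4) draws into one array preserves the stream order.
    draws = np.empty((n_steps, n_reps, 4))
    for k, s in enumerate(seeds):
        draws[:, k, :] = np.random.default_rng(s).standard_normal((n_steps, 4))
    x0 = np.tile(initial.as_array(), (n_reps, 1))
    try:
        values, violations = _simulate_paths(
            x0, params, noise, times, draws, settings.scheme,
            settings.clip_at_zero)
    except SimulationOverflowError as exc:
        raise SimulationOverflowError(
            str(exc), step=exc.step, partial=exc.partial,
            replicate=exc.replicate) from None
    reps = tuple(
        Trajectory(times=times, values=values[:, k, :],
                   settings=replace(settings, seed=seeds[k]),
                   params=params, noise=noise,
                   positivity_violations=int(violations[k]))
        for k in range(n_reps))
    return Ensemble(replicates=reps, seeds=tuple(seeds))


def ensemble_moments(ens: Ensemble) -> EnsembleMoments:
    """Pointwise sample mean and unbiased (ddof=1) sample variance of each
    component; variance is defined as 0 for a single replicate."""
    times = ens.replicates[0].times
    stack = np.stack([r.values for r in ens.replicates], axis=0)  # (P, T, 4)
    mean = stack.mean(axis=0)
    # bitwise-identical replicates (e.g. zero noise) get an exact zero:
    # np.var would otherwise leave ~1e-26 residue from the mean subtraction
    if stack.shape[0] == 1 or (stack == stack[0]).all():
        variance = np.zeros_like(mean)
    else:
        variance = stack.var(axis=0, ddof=1)
    return EnsembleMoments(times=times, mean=mean, variance=variance,
                           n_replicates=stack.shape[0])


# ---------------------------------------------------------------------------
# Strong convergence order
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderEstimate:
    """Fitted strong-convergence order: slope of log(error) vs log(dt)."""

    slope: float
    dts: np.ndarray
    errors: np.ndarray
    scheme: Scheme
    n_paths: int


def strong_order_estimate(initial: State, params: ModelParameters,
                          noise: NoiseIntensities, scheme: Scheme | str,
                          dt_list: Sequence[float], dt_ref: float,
                          n_paths: int, base_seed: int,
                          t_end: float = 1.0) -> OrderEstimate:
    """Estimate the empirical strong order of a scheme.

    For each sample path one Brownian path is drawn on the ``dt_ref`` grid
    and coarsened (increments summed) for each test ``dt``; the strong
    error at ``dt`` is the mean over paths of the end-time max-norm gap to
    the ``dt_ref`` reference solution of the same scheme.  The returned
    slope is the least-squares fit of log(error) against log(dt).

    At most one noise channel may be active: the Milstein scheme without
    Lévy areas is exactly strong order 1 only then (the R equation mixes
    two channels with state-dependent coefficients).
    """
    scheme = _coerce_scheme(scheme)
    if sum(s > 0 for s in noise.as_array()) > 1:
        raise UsageError("strong_order_estimate requires at most one active "
                         "noise channel (Levy areas are not simulated)")
    if not isinstance(initial, State):
        initial = State(*initial)
    n_ref = round(t_end / dt_ref)
    if abs(n_ref * dt_ref - t_end) > 1e-9 * t_end:
        raise UsageError(f"dt_ref={dt_ref!r} must divide t_end={t_end!r}")
    ratios = []
    for dt in dt_list:
        ratio = dt / dt_ref
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise UsageError(f"dt_ref={dt_ref!r} must divide dt={dt!r} (nested grids)")
        n_coarse = t_end / dt
        if abs(n_coarse - round(n_coarse)) > 1e-9:
            raise UsageError(f"dt={dt!r} must divide t_end={t_end!r}")
        ratios.append(int(round(ratio)))

    x0 = np.tile(initial.as_array(), (n_paths, 1))
    rngs = [np.random.default_rng(derive_replicate_seed(base_seed, k))
            for k in range(n_paths)]
    dB_fine = np.empty((n_ref, n_paths, 4))
    for k, rng in enumerate(rngs):
        dB_fine[:, k, :] = rng.standard_normal((n_ref, 4)) * math.sqrt(dt_ref)

    def integrate(dB: np.ndarray, h: float) -> np.ndarray:
        x = x0.copy()
        for i in range(dB.shape[0]):
            x = _step_array(x, params, noise, h, dB[i], scheme)
            _check_finite_step(x, f"strong_order_estimate (dt={h:g}, step {i})")
        return x

    x_ref = integrate(dB_fine, dt_ref)
    errors = []
    for dt, m in zip(dt_list, ratios):
        n_coarse = n_ref // m
        dB_coarse = dB_fine[: n_coarse * m].reshape(n_coarse, m, n_paths, 4).sum(axis=1)
        x_dt = integrate(dB_coarse, dt)
        gap = np.max(np.abs(x_dt - x_ref), axis=-1)  # end-time max-norm
        errors.append(float(gap.mean()))
    dts = np.asarray(list(dt_list), dtype=float)
    errs = np.asarray(errors)
    slope = float(np.polyfit(np.log(dts), np.log(errs), 1)[0])
    return OrderEstimate(slope=slope, dts=dts, errors=errs, scheme=scheme,
                         n_paths=n_paths)


# ---------------------------------------------------------------------------
# Stability analysis of the silencing-free state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityReport:
    """Exponential p-stability condition check for xi0.

    The sufficient conditions bound sigma_i^2 (p-1)/2 strictly below, for
    i = 1, 2, 3 respectively:

        iota_a,   iota_r + iota_b iota_h / iota_m,   iota_g + iota_c.

    No condition constrains sigma4 and none is invented.  ``margins`` are
    thresholds minus left-hand sides (positive = satisfied); inequalities
    are strict and evaluated without tolerance (boundary equality reports
    not-satisfied).
    """

    p: float
    lhs: tuple[float, float, float]
    thresholds: tuple[float, float, float]
    satisfied: tuple[bool, bool, bool]
    all_satisfied: bool
    margins: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {"p": self.p, "lhs": list(self.lhs),
                "thresholds": list(self.thresholds),
                "satisfied": list(self.satisfied),
                "all_satisfied": self.all_satisfied,
                "margins": list(self.margins)}


@dataclass(frozen=True)
class LyapunovValue:
    """Values of the two Lyapunov functions and the drift bound."""

    v: float
    vp: float
    f_bound: float


def p_stability_thresholds(params: ModelParameters, p: float) -> tuple[float, float, float]:
    """Thresholds that sigma_i^2 (p-1)/2 must stay strictly below
    (i = 1, 2, 3).  The triple itself does not depend on p; only the
    left-hand side scales with (p-1).  The conditions are stated for
    moment orders p >= 2."""
    if not (math.isfinite(p) and p >= 2):
        raise UsageError(f"p must be >= 2, got {p!r}")
    q = params
    return (q.iota_a,
            q.iota_r + q.iota_b * q.iota_h / q.iota_m,
            q.iota_g + q.iota_c)


def check_noise(params: ModelParameters, noise: NoiseIntensities,
                p: float) -> StabilityReport:
    """Evaluate the p-stability conditions for the given noise intensities."""
    thresholds = p_stability_thresholds(params, p)
    factor = (p - 1.0) / 2.0
    lhs = (noise.sigma1 ** 2 * factor,
           noise.sigma2 ** 2 * factor,
           noise.sigma3 ** 2 * factor)
    satisfied = tuple(l < t for l, t in zip(lhs, thresholds))
    margins = tuple(t - l for l, t in zip(lhs, thresholds))
    return StabilityReport(p=float(p), lhs=lhs, thresholds=thresholds,
                           satisfied=satisfied,
                           all_satisfied=all(satisfied), margins=margins)


def lyapunov_v(state: State) -> float:
    """Logarithmic Lyapunov function of the global-existence argument:
    sum over components x of (x - 1 - log x).  Nonnegative, zero only at
    (1, 1, 1, 1); requires a strictly positive state."""
    if not isinstance(state, State):
        state = State(*state)
    x = state.as_array()
    if np.any(x <= 0):
        raise DomainError("lyapunov_v requires strictly positive components")
    return float(np.sum(x - 1.0 - np.log(x)))


def lyapunov_vp(state: State, params: ModelParameters, p: float) -> float:
    """Power-law Lyapunov function of the p-stability argument:
    (1/p) (S^p + R^p + C^p + (iota_h/iota_m - M)^p), defined for
    S, R, C >= 0 and M <= iota_h/iota_m (the real power of the last term
    is only defined for a nonnegative base)."""
    if not (math.isfinite(p) and p >= 2):
        raise UsageError(f"p must be >= 2, got {p!r}")
    if not isinstance(state, State):
        state = State(*state)
    ceiling = params.iota_h / params.iota_m
    if state.M > ceiling:
        raise DomainError(f"M={state.M!r} exceeds iota_h/iota_m={ceiling!r}")
    if min(state.S, state.R, state.C) < 0:
        raise DomainError("lyapunov_vp requires S, R, C >= 0")
    return float((state.S ** p + state.R ** p + state.C ** p
                  + (ceiling - state.M) ** p) / p)


def drift_bound_f(state: State, params: ModelParameters,
                  noise: NoiseIntensities) -> float:
    """Upper bound on the Itô drift of the logarithmic Lyapunov function:

        1/2 (sigma1^2 + sigma2^2 + sigma3^2 + sigma4^2)
        + sigma1^2 n^2 S^2 / (2 R^2)
        + iota_a + iota_a n S + iota_r + iota_b M + iota_g + iota_c
        + iota_h + iota_m + iota_b R

    Requires R > 0 (the S/R ratio term).  Nondecreasing in each sigma_i^2.
    """
    if not isinstance(state, State):
        state = State(*state)
    if state.R <= 0:
        raise DomainError("drift_bound_f requires R > 0")
    p, s = params, noise
    sigma_sum = 0.5 * (s.sigma1 ** 2 + s.sigma2 ** 2 + s.sigma3 ** 2 + s.sigma4 ** 2)
    ratio = s.sigma1 ** 2 * p.n ** 2 * state.S ** 2 / (2.0 * state.R ** 2)
    return float(sigma_sum + ratio
                 + p.iota_a + p.iota_a * p.n * state.S + p.iota_r
                 + p.iota_b * state.M + p.iota_g + p.iota_c
                 + p.iota_h + p.iota_m + p.iota_b * state.R)


@dataclass(frozen=True)
class MomentDecayResult:
    """Empirical p-th moment decay of the distance to xi0.

    ``slope`` is the least-squares slope of log E[||X_t - xi0||_inf^p]
    against t over the second half of the time window; ``stability`` is the
    analytic condition check attached for comparison.  Note the analytic
    conditions bound only sigma1..sigma3: with sigma4 > 0 the mRNA noise
    does not vanish at xi0 and the moment plateaus at a noise floor instead
    of decaying.
    """

    slope: float
    times: np.ndarray
    moments: np.ndarray
    p: float
    stability: StabilityReport


def empirical_moment_decay(params: ModelParameters, noise: NoiseIntensities,
                           p: float, initial: State,
                           settings: IntegrationSettings, n_reps: int,
                           base_seed: int) -> MomentDecayResult:
    """Probe the decay of E[||X_t - xi0||_inf^p] by ensemble simulation.

    A meaningful moment estimate needs tens of replicates or more; a single
    replicate is accepted (it reproduces the deterministic decay exactly
    when all sigmas are zero).
    """
    report = check_noise(params, noise, p)
    ens = simulate_ensemble(initial, params, noise, settings, n_reps, base_seed)
    xi0 = equilibria(params).xi0.as_array()
    stack = np.stack([r.values for r in ens.replicates], axis=0)  # (P, T, 4)
    dist = np.max(np.abs(stack - xi0), axis=-1)  # (P, T)
    moments = np.mean(dist ** p, axis=0)  # (T,)
    times = ens.replicates[0].times
    half = times >= times[-1] / 2.0
    ok = half & (moments > 0)
    if ok.sum() < 2:
        raise InvalidInputError("not enough positive moment values in the "
                                "second half of the window to fit a slope")
    slope = float(np.polyfit(times[ok], np.log(moments[ok]), 1)[0])
    return MomentDecayResult(slope=slope, times=times, moments=moments,
                             p=float(p), stability=report)


# ---------------------------------------------------------------------------
# Configuration and scenarios
# ---------------------------------------------------------------------------

#: Simulation regimes studied with the reference parameter set.  fig1 is the
#: deterministic model from a low (a) and high (b) initial dsRNA dose; fig2
#: adds noise 0.2 on all four channels; fig3..fig6 vary one channel between
#: a weak (0.02) and strong (1.2) intensity with the others held at 0.2,
#: always from the low dose.
SCENARIOS: dict[str, dict] = {
    "fig1a": dict(sigma1=0.0, sigma2=0.0, sigma3=0.0, sigma4=0.0, S0=10.0),
    "fig1b": dict(sigma1=0.0, sigma2=0.0, sigma3=0.0, sigma4=0.0, S0=1000.0),
    "fig2a": dict(sigma1=0.2, sigma2=0.2, sigma3=0.2, sigma4=0.2, S0=10.0),
    "fig2b": dict(sigma1=0.2, sigma2=0.2, sigma3=0.2, sigma4=0.2, S0=1000.0),
    "fig3a": dict(sigma1=0.02, sigma2=0.2, sigma3=0.2, sigma4=0.2, S0=10.0),
    "fig3b": dict(sigma1=1.2, sigma2=0.2, sigma3=0.2, sigma4=0.2, S0=10.0),
    "fig4a": dict(sigma1=0.2, sigma2=0.02, sigma3=0.2, sigma4=0.2, S0=10.0),
    "fig4b": dict(sigma1=0.2, sigma2=1.2, sigma3=0.2, sigma4=0.2, S0=10.0),
    "fig5a": dict(sigma1=0.2, sigma2=0.2, sigma3=0.02, sigma4=0.2, S0=10.0),
    "fig5b": dict(sigma1=0.2, sigma2=0.2, sigma3=1.2, sigma4=0.2, S0=10.0),
    "fig6a": dict(sigma1=0.2, sigma2=0.2, sigma3=0.2, sigma4=0.02, S0=10.0),
    "fig6b": dict(sigma1=0.2, sigma2=0.2, sigma3=0.2, sigma4=1.2, S0=10.0),
}

_PARAM_KEYS = tuple(_DEFAULTS)
_NOISE_KEYS = ("sigma1", "sigma2", "sigma3", "sigma4")
_INITIAL_KEYS = ("S0", "R0", "C0", "M0")
_SETTINGS_KEYS = ("dt", "t_end", "scheme", "seed", "clip_at_zero")
_CONFIG_KEYS = _PARAM_KEYS + _NOISE_KEYS + _INITIAL_KEYS + _SETTINGS_KEYS + ("scenario",)

_DEFAULT_INITIAL = dict(S0=10.0, R0=0.0, C0=0.0, M0=1000.0)


@dataclass(frozen=True)
class RunConfig:
    """A fully-resolved simulation run: parameters, noise, initial state,
    integration settings and the (optional) named scenario."""

    params: ModelParameters
    noise: NoiseIntensities
    initial: State
    settings: IntegrationSettings
    scenario: Optional[str] = None

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "noise": self.noise.to_dict(),
                "initial": self.initial.to_dict(),
                "settings": self.settings.to_dict(), "scenario": self.scenario}


def _build_config(raw: dict, source: str = "config") -> RunConfig:
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"{source}: unknown keys {sorted(unknown)}; "
                          f"allowed keys are {sorted(_CONFIG_KEYS)}")
    scenario = raw.get("scenario")
    if scenario is not None:
        if scenario not in SCENARIOS:
            raise ConfigError(f"{source}: unknown scenario {scenario!r}; "
                              f"choose from {sorted(SCENARIOS)}")
        for key, val in SCENARIOS[scenario].items():
            if key in raw and float(raw[key]) != val:
                raise ConfigError(
                    f"{source}: field {key}={raw[key]!r} conflicts with "
                    f"scenario {scenario} (which sets {key}={val!r})")
        raw = {**raw, **SCENARIOS[scenario]}

    def section(keys, defaults):
        return {k: raw.get(k, defaults[k]) for k in keys}

    try:
        params = ModelParameters(**section(_PARAM_KEYS, _DEFAULTS))
        noise = NoiseIntensities(**{k: raw.get(k, 0.0) for k in _NOISE_KEYS})
        init = section(_INITIAL_KEYS, _DEFAULT_INITIAL)
        initial = State(init["S0"], init["R0"], init["C0"], init["M0"])
        settings = IntegrationSettings(
            dt=raw.get("dt", 0.001), t_end=raw.get("t_end", 50.0),
            scheme=raw.get("scheme", Scheme.MILSTEIN_ITO),
            seed=raw.get("seed", 0),
            clip_at_zero=bool(raw.get("clip_at_zero", False)))
    except (InvalidInputError, UsageError) as exc:
        raise ConfigError(f"{source}: {exc}") from exc
    return RunConfig(params=params, noise=noise, initial=initial,
                     settings=settings, scenario=scenario)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat TOML (``.toml``) or JSON (``.json``) run configuration.

    Recognised keys: the eight rate parameters (``n``, ``iota_a``, ...),
    ``sigma1..sigma4``, initial values ``S0 R0 C0 M0``, integration settings
    ``dt t_end scheme seed clip_at_zero`` and an optional ``scenario``.
    Missing keys fall back to the reference parameter set with zero noise
    and initial (10, 0, 0, 1000); unknown keys are an error.  A scenario
    fixes its sigma values and S0 — explicitly setting one of those keys to
    a different value is a conflict error, not a silent override.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: JSON parse error at line {exc.lineno}: "
                              f"{exc.msg}") from exc
    else:
        try:
            raw = tomllib.loads(text.decode("utf-8"))
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: TOML parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a table/object")
    return _build_config(raw, source=str(path))


# ---------------------------------------------------------------------------
# Trajectory serialization
# ---------------------------------------------------------------------------

_CSV_HEADER = ["t", "S", "R", "C", "M"]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV (header ``t,S,R,C,M``) plus a JSON sidecar.

    Floats are rendered with 17 significant digits so the read/write round
    trip is exact; the sidecar ``<name>.meta.json`` records parameters,
    noise, settings and the positivity-violation count.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_HEADER)
        for t, row in zip(traj.times, traj.values):
            writer.writerow([format(t, ".17g")] + [format(v, ".17g") for v in row])
    meta = {
        "params": traj.params.to_dict(),
        "noise": traj.noise.to_dict(),
        "initial": traj.initial_state.to_dict(),
        **traj.settings.to_dict(),
        "positivity_violations": traj.positivity_violations,
        "package_version": __version__,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n",
                                   encoding="utf-8")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Reading is the exact inverse of writing: states round-trip bitwise.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header != _CSV_HEADER:
            raise FormatError(f"{path}: bad header {header!r}, "
                              f"expected {_CSV_HEADER!r}")
        times, values = [], []
        for idx, row in enumerate(reader, start=1):
            if len(row) != 5:
                raise FormatError(f"{path}: row {idx} has {len(row)} fields, expected 5")
            try:
                nums = [float(v) for v in row]
            except ValueError as exc:
                raise FormatError(f"{path}: row {idx}: {exc}") from None
            times.append(nums[0])
            values.append(nums[1:])
    if not times:
        raise FormatError(f"{path}: no data rows")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: metadata sidecar {sidecar.name} is missing")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    params = ModelParameters(**meta["params"])
    noise = NoiseIntensities(**meta["noise"])
    settings = IntegrationSettings(dt=meta["dt"], t_end=meta["t_end"],
                                   scheme=meta["scheme"], seed=meta["seed"],
                                   clip_at_zero=meta["clip_at_zero"])
    return Trajectory(times=np.asarray(times), values=np.asarray(values),
                      settings=settings, params=params, noise=noise,
                      positivity_violations=int(meta["positivity_violations"]))


# ---------------------------------------------------------------------------
# Regression fixtures
# ---------------------------------------------------------------------------

_FIXTURE_DT = 0.01
_FIXTURE_T_STOCHASTIC = 2.0
_FIXTURE_T_DETERMINISTIC = 5.0
_FIXTURE_BASE_SEED = 20250620


def generate_fixtures(out_dir: str | Path) -> dict:
    """Emit small seeded reference trajectories plus a checksum manifest.

    One stochastic run per scenario (dt=0.01 to t=2, fixed per-scenario
    seeds) and a deterministic pair (fig1a/fig1b regimes, dt=0.01 to t=5).
    Re-invocation reproduces identical files and checksums; regression
    tests compare against the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"dt": _FIXTURE_DT, "files": {}}
    for idx, name in enumerate(sorted(SCENARIOS)):
        cfg = _build_config({"scenario": name, "dt": _FIXTURE_DT,
                             "t_end": _FIXTURE_T_STOCHASTIC,
                             "seed": _FIXTURE_BASE_SEED + idx})
        traj = simulate(cfg.initial, cfg.params, cfg.noise, cfg.settings)
        fname = f"{name}.csv"
        write_trajectory(traj, out_dir / fname)
        manifest["files"][fname] = _sha256(out_dir / fname)
    for name in ("fig1a", "fig1b"):
        cfg = _build_config({"scenario": name, "dt": _FIXTURE_DT,
                             "t_end": _FIXTURE_T_DETERMINISTIC, "seed": 0})
        traj = simulate(cfg.initial, cfg.params, cfg.noise, cfg.settings)
        fname = f"deterministic_{name}.csv"
        write_trajectory(traj, out_dir / fname)
        manifest["files"][fname] = _sha256(out_dir / fname)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Command-line interface
# ---------------------------------------------------------------------------

def _setup_logging(verbose: int) -> None:
    level = logging.WARNING - 10 * min(verbose, 2)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def _emit(obj: dict) -> None:
    click.echo(json.dumps(obj, indent=1, sort_keys=True))


def _config_from_options(config, scenario, dt, t_end, seed, scheme, sigma) -> RunConfig:
    raw: dict = {}
    if config:
        cfg = load_config(config)
        raw.update({**cfg.params.to_dict(), **cfg.noise.to_dict()})
        raw.update(S0=cfg.initial.S, R0=cfg.initial.R, C0=cfg.initial.C,
                   M0=cfg.initial.M, **cfg.settings.to_dict())
        if cfg.scenario:
            raw["scenario"] = cfg.scenario
    if scenario:
        raw.pop("scenario", None)
        # command-line scenario replaces any sigma/S0 inherited from the file
        for key in (*_NOISE_KEYS, "S0"):
            raw.pop(key, None)
        raw["scenario"] = scenario
    if sigma is not None:
        raw.update(sigma1=sigma[0], sigma2=sigma[1], sigma3=sigma[2], sigma4=sigma[3])
    if dt is not None:
        raw["dt"] = dt
    if t_end is not None:
        raw["t_end"] = t_end
    if seed is not None:
        raw["seed"] = seed
    if scheme is not None:
        raw["scheme"] = scheme
    return _build_config(raw, source="command line")


_scheme_choice = click.Choice([s.value for s in Scheme])


@click.group(name="rnasilencing")
@click.option("-v", "--verbose", count=True, help="Increase log verbosity (stderr).")
@click.version_option(__version__)
def main(verbose: int) -> None:
    """Deterministic and stochastic RNA-silencing kinetics toolkit."""
    _setup_logging(verbose)


_common = [
    click.option("--config", type=click.Path(), default=None,
                 help="Flat TOML/JSON run configuration."),
    click.option("--scenario", type=click.Choice(sorted(SCENARIOS)), default=None),
    click.option("--dt", type=float, default=None),
    click.option("--t-end", type=float, default=None),
    click.option("--seed", type=int, default=None),
    click.option("--scheme", type=_scheme_choice, default=None),
    click.option("--sigma", type=float, nargs=4, default=None,
                 help="sigma1 sigma2 sigma3 sigma4"),
]


def _add_options(options):
    def wrap(fn):
        for opt in reversed(options):
            fn = opt(fn)
        return fn
    return wrap


@main.command("equilibria")
@_add_options(_common)
def cli_equilibria(config, scenario, dt, t_end, seed, scheme, sigma) -> None:
    """Steady states, feasibility and residuals."""
    cfg = _config_from_options(config, scenario, dt, t_end, seed, scheme, sigma)
    eq = equilibria(cfg.params)
    logger.info("xi0 = %s, feasible interior state: %s", eq.xi0.to_dict(), eq.feasible)
    _emit({
        "xi0": eq.xi0.to_dict(),
        "xi_star": eq.xi_star.to_dict() if eq.xi_star else None,
        "feasible": eq.feasible,
        "residual_xi0": eq.residual_xi0,
        "residual_xi_star": eq.residual_xi_star,
        "printed_inequality_holds": eq.printed_inequality_holds,
    })


@main.command("r0")
@_add_options(_common)
def cli_r0(config, scenario, dt, t_end, seed, scheme, sigma) -> None:
    """Basic reproduction number by the next-generation-matrix method."""
    cfg = _config_from_options(config, scenario, dt, t_end, seed, scheme, sigma)
    res = ngm_r0(cfg.params)
    logger.info("R0 = %.6f (spectral radius %.6f)", res.r0, res.r0_spectral)
    _emit({"r0_closed_form": res.r0, "r0_spectral_radius": res.r0_spectral,
           "F": res.F.tolist(), "V": res.V.tolist()})


@main.command("stability")
@_add_options(_common)
@click.option("--p", "p_order", type=float, default=2.0, show_default=True,
              help="Moment order p (>= 2).")
def cli_stability(config, scenario, dt, t_end, seed, scheme, sigma, p_order) -> None:
    """Exponential p-stability condition check for the given noise."""
    cfg = _config_from_options(config, scenario, dt, t_end, seed, scheme, sigma)
    report = check_noise(cfg.params, cfg.noise, p_order)
    logger.info("all_satisfied = %s (margins %s)", report.all_satisfied, report.margins)
    _emit(report.to_dict())


@main.command("simulate")
@_add_options(_common)
@click.option("--out", type=click.Path(), required=True, help="Output CSV path.")
def cli_simulate(config, scenario, dt, t_end, seed, scheme, sigma, out) -> None:
    """Integrate one seeded trajectory and write it as CSV."""
    cfg = _config_from_options(config, scenario, dt, t_end, seed, scheme, sigma)
    traj = simulate(cfg.initial, cfg.params, cfg.noise, cfg.settings)
    write_trajectory(traj, out)
    logger.info("wrote %s (%d points, %d positivity violations)",
                out, len(traj.times), traj.positivity_violations)
    _emit({"out": str(out), "points": len(traj.times),
           "positivity_violations": traj.positivity_violations,
           "final_state": traj.final_state.to_dict()})


@main.command("ensemble")
@_add_options(_common)
@click.option("--out-dir", type=click.Path(), required=True)
@click.option("--reps", type=int, default=10, show_default=True)
@click.option("--base-seed", type=int, default=0, show_default=True)
def cli_ensemble(config, scenario, dt, t_end, seed, scheme, sigma,
                 out_dir, reps, base_seed) -> None:
    """Simulate replicate trajectories and write them plus their moments."""
    cfg = _config_from_options(config, scenario, dt, t_end, seed, scheme, sigma)
    ens = simulate_ensemble(cfg.initial, cfg.params, cfg.noise, cfg.settings,
                            reps, base_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, traj in enumerate(ens.replicates):
        write_trajectory(traj, out / f"rep{k:04d}.csv")
    mom = ensemble_moments(ens)
    with (out / "moments.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["t"] + [f"mean_{c}" for c in _COMPONENTS]
                        + [f"var_{c}" for c in _COMPONENTS])
        for t, m, v in zip(mom.times, mom.mean, mom.variance):
            writer.writerow([format(t, ".17g")]
                            + [format(x, ".17g") for x in m]
                            + [format(x, ".17g") for x in v])
    logger.info("wrote %d replicates to %s", reps, out)
    _emit({"out_dir": str(out), "replicates": reps,
           "seeds": list(ens.seeds)})


@main.command("converge")
@_add_options(_common)
@click.option("--paths", type=int, default=200, show_default=True)
@click.option("--base-seed", type=int, default=0, show_default=True)
@click.option("--dt-exponents", type=int, nargs=2, default=(6, 10),
              show_default=True, help="Test dts 2^-a .. 2^-b.")
@click.option("--dt-ref-exponent", type=int, default=14, show_default=True)
def cli_converge(config, scenario, dt, t_end, seed, scheme, sigma,
                 paths, base_seed, dt_exponents, dt_ref_exponent) -> None:
    """Estimate the empirical strong convergence order of a scheme."""
    cfg = _config_from_options(config, scenario, dt, t_end, seed, scheme, sigma)
    a, b = sorted(dt_exponents)
    dt_list = [2.0 ** -k for k in range(a, b + 1)]
    est = strong_order_estimate(cfg.initial, cfg.params, cfg.noise,
                                cfg.settings.scheme, dt_list,
                                2.0 ** -dt_ref_exponent, paths, base_seed,
                                t_end=t_end if t_end is not None else 1.0)
    logger.info("fitted strong order %.3f", est.slope)
    _emit({"scheme": est.scheme.value, "slope": est.slope,
           "dts": est.dts.tolist(), "errors": est.errors.tolist(),
           "n_paths": est.n_paths})


@main.command("fixtures")
@click.option("--out-dir", type=click.Path(), required=True)
def cli_fixtures(out_dir) -> None:
    """Generate the seeded regression-fixture set and its manifest."""
    manifest = generate_fixtures(out_dir)
    _emit(manifest)


def run_cli(argv: Sequence[str]) -> int:
    """Run the CLI on an argument vector and return the exit code
    (0 success, 2 usage error, 1 runtime error)."""
    try:
        main.main(args=list(argv), standalone_mode=False)
    except click.exceptions.Exit as exc:
        return int(exc.exit_code)
    except click.UsageError as exc:
        click.echo(f"Usage error: {exc.format_message()}", err=True)
        return 2
    except (UsageError, ConfigError) as exc:
        click.echo(f"Usage error: {exc}", err=True)
        return 2
    except click.ClickException as exc:
        exc.show()
        return 1
    except (InvalidInputError, DomainError, FormatError, OverflowError,
            FloatingPointError, OSError) as exc:
        click.echo(f"Error: {exc}", err=True)
        return 1
    return 0
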