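"""Stochastic vegetation-rainfall model core.

A non-dimensional vegetation cover v, ranging from shrubland (+1, "green")
to desert (-1, "yellow"), relaxes towards tanh of a rainfall index R on a
timescale tau_v:

    dv/dt = [tanh(R) - v] / tau_v
    R     = a + b*P + c*F + d*v + N

where P is climatic precession, F the CO2 radiative forcing, d*v the
vegetation-rainfall feedback and N a red-noise term representing
interannual soil-moisture variability:

    dN/dt = (sigma * xi(t) - N) / tau_N,      xi ~ unit white noise.

Integration uses the explicit forward scheme with a 1-year timestep:

    v_{k+1} = v_k + (dt/tau_v) * [tanh(a + b P_k + c F_k + d v_k + N_k) - v_k]
    N_{k+1} = N_k - N_k*dt/tau_N + sqrt(dt)*sigma*W_k/tau_N

with W_k a unit-normal draw.  The explicit 1-year scheme is part of the
method, not a numerical convenience; no adaptive integrator is offered.

Because tanh is bounded by 1, with sigma = 0 and dt <= tau_v the drift can
never carry v outside [-1, 1].  The stationary standard deviation of N is
sqrt(sigma^2*dt/tau_N^2 / (1 - (1 - dt/tau_N)^2)) — an AR(1) process with
lag-1 coefficient (1 - dt/tau_N).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .forcing import ForcingSeries

__all__ = [
    "ModelParams",
    "SimulationConfig",
    "Trajectory",
    "rainfall",
    "background_rainfall",
    "step",
    "simulate",
    "stable_equilibrium",
]

logger = logging.getLogger("greensahara")

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class ModelParams:
    """The seven tunable scalars of the idealised model.

    a : background-rainfall offset (dimensionless)
    b : precession coefficient (dimensionless)
    c : radiative-forcing coefficient (per W m^-2)
    d : vegetation-rainfall feedback strength (dimensionless)
    tau_v : vegetation timescale (years)
    tau_N : soil-moisture (noise) timescale (years)
    sigma : noise scaling (dimensionless)
    """

    a: float
    b: float
    c: float
    d: float
    tau_v: float
    tau_N: float
    sigma: float

    def __post_init__(self):
        vals = (self.a, self.b, self.c, self.d, self.tau_v, self.tau_N, self.sigma)
        if not all(math.isfinite(x) for x in vals):
            raise ValueError("all parameters must be finite")
        if self.tau_v <= 0 or self.tau_N <= 0:
            raise ValueError("tau_v and tau_N must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    dt : timestep in years (default 1; must equal the forcing grid step and
        may not exceed min(tau_v, tau_N)).
    seed : RNG seed for the member's noise stream (ignored when an explicit
        generator is passed to :func:`simulate`).
    v0 : initial vegetation state; ``None`` means the noiseless equilibrium
        at the first forcing value, found by root-finding.
    N0 : initial noise state (default 0).
    spinup_years : years of discarded spin-up at the first forcing value,
        default 1000 (removes transients of order tau_v).
    thin : store every k-th step of the output trajectory (1 = store all).
    """

    dt: float = 1.0
    seed: Optional[int] = None
    v0: Optional[float] = None
    N0: float = 0.0
    spinup_years: float = 1000.0
    thin: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.spinup_years < 0:
            raise ValueError("spinup_years must be non-negative")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class Trajectory:
    """One simulated member: vegetation v(t) and noise N(t) on a years-BP axis."""

    time: np.ndarray
    v: np.ndarray
    N: np.ndarray
    R_det: Optional[np.ndarray] = None  # deterministic rainfall a+bP+cF+d*v

    def __post_init__(self):
        if not (len(self.time) == len(self.v) == len(self.N)):
            raise ValueError("time, v, N must have equal length")

    def thin(self, k: int) -> "Trajectory":
        # copies, not views: a thinned trajectory must not pin the full arrays
        r = None if self.R_det is None else np.ascontiguousarray(self.R_det[::k])
        return Trajectory(
            np.ascontiguousarray(self.time[::k]),
            np.ascontiguousarray(self.v[::k]),
            np.ascontiguousarray(self.N[::k]),
            r,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_yrBP": self.time, "v": self.v, "N": self.N})

    def to_csv(self, path, thin: int = 1) -> None:
        (self.thin(thin) if thin > 1 else self).to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time_yrBP"].to_numpy(), df["v"].to_numpy(), df["N"].to_numpy())


# ----------------------------------------------------------------------
# rainfall and single steps
# ----------------------------------------------------------------------

def rainfall(params: ModelParams, P, F, v, N):
    """Non-dimensional rainfall R = a + b*P + c*F + d*v + N (elementwise)."""
    return params.a + params.b * np.asarray(P) + params.c * np.asarray(F) \
        + params.d * np.asarray(v) + np.asarray(N)


def background_rainfall(params: ModelParams, P, F):
    """The external part of the rainfall, r = a + b*P + c*F.

    This is the quantity whose sign change defines threshold times; the
    feedback (d*v) and noise terms are excluded.
    """
    return params.a + params.b * np.asarray(P) + params.c * np.asarray(F)


def _check_dt(params: ModelParams, dt: float) -> None:
    if dt > min(params.tau_v, params.tau_N):
        raise ValueError(
            f"dt={dt} exceeds min(tau_v, tau_N)="
            f"{min(params.tau_v, params.tau_N)}; the explicit scheme is unstable"
        )


def step(
    v_k: float,
    N_k: float,
    P_k: float,
    F_k: float,
    params: ModelParams,
    dt: float = 1.0,
    noise_draw: float = 0.0,
) -> Tuple[float, float]:
    """One forward step of the coupled (v, N) system.

    ``noise_draw`` is a unit-normal sample W_k supplied by the caller; it
    enters N only, never v directly.
    """
    _check_dt(params, dt)
    R = params.a + params.b * P_k + params.c * F_k + params.d * v_k + N_k
    v_next = v_k + (dt / params.tau_v) * (math.tanh(R) - v_k)
    N_next = N_k - N_k * dt / params.tau_N \
        + math.sqrt(dt) * params.sigma * noise_draw / params.tau_N
    return v_next, N_next


@njit(cache=False)
def _step_loop(v0, N0, P, F, a, b, c, d, tau_v, tau_N, sigma, dt, W):  # pragma: no cover
    n = P.shape[0]
    v = np.empty(n)
    N = np.empty(n)
    v[0] = v0
    N[0] = N0
    sq = math.sqrt(dt) * sigma / tau_N
    for k in range(n - 1):
        R = a + b * P[k] + c * F[k] + d * v[k] + N[k]
        v[k + 1] = v[k] + (dt / tau_v) * (math.tanh(R) - v[k])
        N[k + 1] = N[k] - N[k] * dt / tau_N + sq * W[k]
    return v, N


# ----------------------------------------------------------------------
# equilibria of the noiseless system
# ----------------------------------------------------------------------

def stable_equilibrium(r: float, d: float) -> float:
    """Stable root of v = tanh(r + d*v) on the side selected by sign(r).

    For r > 0 (r < 0) returns the positive (negative) stable fixed point;
    for r == 0 returns 0 when d <= 1, and the positive well for d > 1
    (sgn(0) is treated as positive throughout the package).
    """
    if r < 0.0:
        return -stable_equilibrium(-r, d)

    def g(v):
        return math.tanh(r + d * v) - v

    if r == 0.0 and d <= 1.0:
        return 0.0
    lo = 1e-12 if r == 0.0 else 0.0
    if g(lo) <= 0.0:  # degenerate: no well strictly inside (lo, 1.5)
        return 0.0
    return float(brentq(g, lo, 1.5, xtol=1e-14))


# ----------------------------------------------------------------------
# full simulation
# ----------------------------------------------------------------------

def simulate(
    params: ModelParams,
    forcing: ForcingSeries,
    config: Optional[SimulationConfig] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    initial: Optional[Tuple[float, float]] = None,
    store_rainfall: bool = False,
) -> Trajectory:
    """Integrate the model over a forcing series.

    The trajectory is deterministic given (params, forcing, seed): the noise
    stream is drawn from a single member-specific generator, consumed in step
    order (spin-up first).  Pass ``rng`` to continue an existing stream —
    e.g. extending a run into the Holocene without re-randomising — together
    with ``initial=(v, N)`` to carry the state over (no spin-up is applied
    then).

    Parameters
    ----------
    initial : (v, N), optional
        Start state; overrides config.v0/N0 and disables spin-up.
    store_rainfall : bool
        Also record the deterministic rainfall a+bP+cF+d*v in ``R_det``.
    """
    config = config or SimulationConfig()
    _check_dt(params, config.dt)
    if len(forcing) < 2:
        raise ValueError("empty forcing window")
    if not math.isclose(forcing.dt, config.dt):
        raise ValueError(
            f"forcing grid step {forcing.dt} differs from configured dt {config.dt}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if initial is not None:
        v0, N0 = float(initial[0]), float(initial[1])
        n_spin = 0
    else:
        r0 = background_rainfall(params, forcing.P[0], forcing.F[0])
        v0 = config.v0 if config.v0 is not None else stable_equilibrium(float(r0), params.d)
        N0 = config.N0
        n_spin = int(round(config.spinup_years / config.dt))

    if n_spin > 0:
        Wspin = rng.standard_normal(n_spin)
        Pc = np.full(n_spin + 1, forcing.P[0])
        Fc = np.full(n_spin + 1, forcing.F[0])
        vs, Ns = _step_loop(
            v0, N0, Pc, Fc,
            params.a, params.b, params.c, params.d,
            params.tau_v, params.tau_N, params.sigma, config.dt, Wspin,
        )
        v0, N0 = vs[-1], Ns[-1]

    W = rng.standard_normal(len(forcing) - 1)
    v, N = _step_loop(
        v0, N0, forcing.P, forcing.F,
        params.a, params.b, params.c, params.d,
        params.tau_v, params.tau_N, params.sigma, config.dt, W,
    )
    R_det = None
    if store_rainfall:
        R_det = background_rainfall(params, forcing.P, forcing.F) + params.d * v
    traj = Trajectory(forcing.time.copy(), v, N, R_det)
    return traj.thin(config.thin) if config.thin > 1 else traj
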