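"""The SCPW differential equations, in four equivalent forms.

The super compact pairwise model tracks expected counts of susceptible and
infectious nodes ([S], [I]) and of connected pairs ([SI], [SS], [II]) under
SIS dynamics with transmission rate tau and recovery rate gamma.  Triples are
closed with the factor Q, a function of the pair counts and the first three
degree moments.  Two conserved quantities, [S]+[I] = N and
2[SI]+[SS]+[II] = <k>N, allow the five equations to be reduced to three.

Forms implemented here:

* dimensional — the raw five-equation system in counts;
* nondimensional — proportions (v, w, x, y, z) on the rescaled time T = gamma*t,
  with the single parameter delta = tau/gamma;
* reduced (w, x, z) — conservation laws eliminate v and y; convenient for the
  disease-free equilibrium, where w = x = z = 0;
* reduced (v, x, y) — eliminates w and z and is written with the constants
  sigma, lambda, mu and the ratio delta/delta_c; the steady-state polynomial
  system is derived from this form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .degree_moments import ModelConstants, NetworkMoments

__all__ = [
    "EpiParams",
    "DimensionalState",
    "NondimState",
    "Trajectory",
    "q_closure",
    "rhs_dimensional",
    "rhs_nondimensional",
    "rhs_reduced_wxz",
    "rhs_reduced_vxy",
    "integrate",
    "default_initial_state",
]

#: The pair closure divides by [SI]+[SS] (nondimensionally x+y): the mean
#: degree of susceptible nodes is undefined with no susceptible-anchored
#: pairs.  We refuse to evaluate rather than regularize.
DENOMINATOR_GUARD = 1e-12

#: Conservation drift beyond this along a trajectory fails the run loudly.
CONSERVATION_TOL = 1e-6


class SingularStateError(ValueError):
    """The closure denominator [SI]+[SS] (or x+y) has vanished."""


class IntegrationFailure(RuntimeError):
    """Adaptive integration failed; carries the last valid state."""

    def __init__(self, message: str, last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class EpiParams:
    """Transmission rate tau and recovery rate gamma; delta = tau/gamma."""

    tau: float
    gamma: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")

    @property
    def delta(self) -> float:
        return self.tau / self.gamma


@dataclass(frozen=True)
class DimensionalState:
    """Expected counts ([S], [I], [SI], [SS], [II]) for N nodes, mean degree kmean."""

    S: float
    I: float
    SI: float
    SS: float
    II: float
    N: float
    kmean: float

    def __post_init__(self) -> None:
        vals = (self.S, self.I, self.SI, self.SS, self.II)
        if any(v < 0 for v in vals):
            raise ValueError("state counts must be nonnegative")
        if abs(self.S + self.I - self.N) > 1e-9 * self.N:
            raise ValueError("[S] + [I] != N")
        pair_total = self.kmean * self.N
        if abs(2 * self.SI + self.SS + self.II - pair_total) > 1e-9 * pair_total:
            raise ValueError("2[SI] + [SS] + [II] != <k>N")


@dataclass(frozen=True)
class NondimState:
    """Proportions (v, w, x, y, z); v+w = 1 and 2x+y+z = 1."""

    v: float
    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name, val in zip("vwxyz", (self.v, self.w, self.x, self.y, self.z)):
            if not -1e-9 <= val <= 1 + 1e-9:
                raise ValueError(f"{name} = {val} outside [0, 1]")
        if abs(self.v + self.w - 1) > 1e-9:
            raise ValueError("v + w != 1")
        if abs(2 * self.x + self.y + self.z - 1) > 1e-9:
            raise ValueError("2x + y + z != 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.w, self.x, self.y, self.z])


@dataclass(frozen=True)
class Trajectory:
    """Integrated path: nondimensional times, full (v,w,x,y,z) states, the delta used."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 5), columns v, w, x, y, z
    delta: float
    converged: bool

    @property
    def terminal(self) -> NondimState:
        v, w, x, y, z = self.states[-1]
        return NondimState(v, w, x, y, z)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.states, columns=["v", "w", "x", "y", "z"])
        df.insert(0, "T", self.times)
        df.to_csv(path, index=False, float_format="%.12g")


def q_closure(state: DimensionalState, m: NetworkMoments) -> float:
    """Closure factor Q = alpha*[S]/([SI]+[SS])^2 + beta/([SI]+[SS]).

    Q approximates (S2 - S1)/S1^2, where S1, S2 are the first two moments of
    the susceptible-node degree distribution; it equals the form written in
    terms of the mean susceptible degree n_S = ([SI]+[SS])/[S].
    """
    from .degree_moments import derived_constants

    den = state.SI + state.SS
    if den <= DENOMINATOR_GUARD:
        raise SingularStateError(
            f"[SI]+[SS] = {den} <= {DENOMINATOR_GUARD}: closure undefined"
        )
    c = derived_constants(m)
    return c.alpha * state.S / den**2 + c.beta / den


def rhs_dimensional(
    state: DimensionalState, p: EpiParams, m: NetworkMoments
) -> np.ndarray:
    """Time derivatives (d[S], d[I], d[SI], d[SS], d[II])/dt."""
    q = q_closure(state, m)
    tau, gamma = p.tau, p.gamma
    S, I, SI, SS, II = state.S, state.I, state.SI, state.SS, state.II
    dS = gamma * I - tau * SI
    dI = tau * SI - gamma * I
    dSI = gamma * (II - SI) - tau * SI + tau * SI * (SS - SI) * q
    dSS = 2 * gamma * SI - 2 * tau * SI * SS * q
    dII = -2 * gamma * II + 2 * tau * SI + 2 * tau * SI**2 * q
    return np.array([dS, dI, dSI, dSS, dII])


def _rhs_nondim(
    u: np.ndarray, delta: float, alpha: float, beta: float, kmean: float
) -> np.ndarray:
    v, w, x, y, z = u
    s = x + y
    if s <= DENOMINATOR_GUARD:
        raise SingularStateError(f"x + y = {s} <= {DENOMINATOR_GUARD}")
    a = alpha * delta / kmean
    b = beta * delta
    closure_xy = a * v * x / s**2 + b * x / s  # shared factor of the closure terms
    dv = w - kmean * delta * x
    dw = kmean * delta * x - w
    dx = z - (delta + 1) * x + closure_xy * (y - x)
    dy = 2 * x - 2 * closure_xy * y
    dz = -2 * z + 2 * delta * x + 2 * closure_xy * x
    return np.array([dv, dw, dx, dy, dz])


def rhs_nondimensional(
    state: NondimState | Sequence[float],
    delta: float,
    c: ModelConstants,
    kmean: float,
) -> np.ndarray:
    """T-derivatives of (v, w, x, y, z) on the rescaled time T = gamma*t."""
    u = state.as_array() if isinstance(state, NondimState) else np.asarray(state, float)
    return _rhs_nondim(u, delta, c.alpha, c.beta, kmean)


def rhs_reduced_wxz(
    state3: Sequence[float], delta: float, c: ModelConstants, kmean: float
) -> np.ndarray:
    """T-derivatives of (w, x, z) after eliminating v = 1-w, y = 1-2x-z."""
    w, x, z = np.asarray(state3, dtype=float)
    s = 1.0 - x - z  # x + y
    if s <= DENOMINATOR_GUARD:
        raise SingularStateError(f"1 - x - z = {s} <= {DENOMINATOR_GUARD}")
    a = c.alpha * delta / kmean
    b = c.beta * delta
    closure = a * (1 - w) * x / s**2 + b * x / s
    dw = kmean * delta * x - w
    dx = z - (delta + 1) * x + closure * (1 - 3 * x - z)
    dz = -2 * z + 2 * delta * x + 2 * closure * x
    return np.array([dw, dx, dz])


def rhs_reduced_vxy(
    state3: Sequence[float], delta: float, c: ModelConstants
) -> np.ndarray:
    """T-derivatives of (v, x, y), written with sigma, lambda, mu and delta/delta_c."""
    v, x, y = np.asarray(state3, dtype=float)
    s = x + y
    if s <= DENOMINATOR_GUARD:
        raise SingularStateError(f"x + y = {s} <= {DENOMINATOR_GUARD}")
    r = delta / c.delta_c
    closure = c.lam * r * v * x / s**2 + c.mu * r * x / s
    dv = 1.0 - v - c.sigma * r * x
    dx = 1.0 - y - (3.0 + c.delta_c * r) * x + closure * (y - x)
    dy = 2.0 * x - 2.0 * closure * y
    return np.array([dv, dx, dy])


def default_initial_state(init_w: float = 1e-2) -> NondimState:
    """Proportionate-mixing seed: w infectious, pairs split as v*w : v^2 : w^2.

    The raw products x = v*w, y = v*v, z = w*w are renormalized so the pair
    fractions satisfy 2x + y + z = 1 exactly.
    """
    if not 0 < init_w < 1:
        raise ValueError("init_w must lie in (0, 1)")
    v = 1.0 - init_w
    x, y, z = v * init_w, v * v, init_w * init_w
    total = 2 * x + y + z
    return NondimState(v, init_w, x / total, y / total, z / total)


_SYSTEMS = ("nondim", "wxz", "vxy")


def _full_state(system: str, u: np.ndarray) -> np.ndarray:
    """Lift a (possibly reduced) state vector to (v, w, x, y, z)."""
    if system == "nondim":
        return u
    if system == "wxz":
        w, x, z = u
        return np.array([1 - w, w, x, 1 - 2 * x - z, z])
    v, x, y = u
    return np.array([v, 1 - v, x, y, 1 - 2 * x - y])


def integrate(
    system: Literal["nondim", "wxz", "vxy"],
    init: NondimState | Sequence[float],
    delta: float,
    c: ModelConstants,
    kmean: float | None = None,
    t_end: float = 200.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    rate_norm_tol: float = 1e-10,
) -> Trajectory:
    """Adaptively integrate one of the three nondimensional system forms.

    Stops early once the rate norm falls below ``rate_norm_tol`` (terminal
    state flagged converged).  Conservation of v+w = 1 and 2x+y+z = 1 is
    monitored along the trajectory, not enforced: drift beyond 1e-6 raises.
    """
    if system not in _SYSTEMS:
        raise ValueError(f"unknown system {system!r}; expected one of {_SYSTEMS}")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if system != "vxy" and kmean is None:
        raise ValueError(f"system {system!r} requires kmean")

    if isinstance(init, NondimState):
        full0 = init.as_array()
        if system == "nondim":
            u0 = full0
        elif system == "wxz":
            u0 = full0[[1, 2, 4]]
        else:
            u0 = full0[[0, 2, 3]]
    else:
        u0 = np.asarray(init, dtype=float)

    if system == "nondim":
        def f(t: float, u: np.ndarray) -> np.ndarray:
            return _rhs_nondim(u, delta, c.alpha, c.beta, kmean)
    elif system == "wxz":
        def f(t: float, u: np.ndarray) -> np.ndarray:
            return rhs_reduced_wxz(u, delta, c, kmean)
    else:
        def f(t: float, u: np.ndarray) -> np.ndarray:
            return rhs_reduced_vxy(u, delta, c)

    def settled(t: float, u: np.ndarray) -> float:
        return float(np.linalg.norm(f(t, u))) - rate_norm_tol

    settled.terminal = True  # type: ignore[attr-defined]
    settled.direction = -1  # type: ignore[attr-defined]

    try:
        sol = solve_ivp(
            f, (0.0, t_end), u0, method="LSODA", rtol=rtol, atol=atol,
            events=settled, dense_output=False,
        )
    except SingularStateError as exc:
        raise IntegrationFailure(f"singular state during integration: {exc}") from exc
    if not sol.success:
        raise IntegrationFailure(
            f"integration failed: {sol.message}",
            last_state=sol.y[:, -1] if sol.y.size else None,
        )

    states = np.array([_full_state(system, u) for u in sol.y.T])
    node_drift = np.abs(states[:, 0] + states[:, 1] - 1).max()
    pair_drift = np.abs(2 * states[:, 2] + states[:, 3] + states[:, 4] - 1).max()
    if max(node_drift, pair_drift) > CONSERVATION_TOL:
        raise IntegrationFailure(
            f"conservation drift {max(node_drift, pair_drift):.3e} exceeds "
            f"{CONSERVATION_TOL}", last_state=sol.y[:, -1],
        )
    converged = bool(sol.t_events[0].size) or settled(sol.t[-1], sol.y[:, -1]) < 0
    return Trajectory(sol.t, states, delta, converged)
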