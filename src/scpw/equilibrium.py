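"""Disease-free and endemic equilibria of the SCPW model.

The disease-free equilibrium (DFE) loses stability as delta = tau/gamma
crosses the epidemic threshold delta_c = <k>/(<k^2> - <k>): the reduced
(w, x, z) Jacobian is block-triangular with one eigenvalue -1 and a 2x2
block B whose determinant 2(1 - delta*kbar) changes sign exactly at
delta_c = 1/kbar (a forward transcritical bifurcation).

Above threshold, the endemic steady state solves a pair of polynomials
P(x, y) = Q(x, y) = 0 in the pair fractions, obtained from the reduced
(v, x, y) system after eliminating v and dividing out the trivial x = 0
(DFE) factor.  We solve them by damped Newton iteration seeded from the
regime-appropriate asymptotic expansion, and assemble bifurcation diagrams
by continuation along a delta grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .asymptotics import far_equilibrium, far_linearization, near_threshold_equilibrium
from .degree_moments import ModelConstants
from .dynamics import rhs_reduced_vxy

__all__ = [
    "DfeAnalysis",
    "EndemicEquilibrium",
    "BifurcationDiagram",
    "dfe_analysis",
    "steady_state_P",
    "steady_state_Q",
    "solve_endemic",
    "endemic_jacobian",
    "bifurcation_diagram",
]

RESIDUAL_TOL = 1e-10  # acceptance residual for a converged endemic root
_NEWTON_TOL = 1e-12
_STEP_TOL = 1e-14
_MAX_ITER = 100
SEED_SWITCH = 2.0  # delta/delta_c below this uses the near seed


class SolverError(RuntimeError):
    """Newton iteration failed from all seeds; carries diagnostics."""


@dataclass(frozen=True)
class DfeAnalysis:
    """Stability analysis of the disease-free equilibrium."""

    jacobian: np.ndarray
    traceB: float
    detB: float
    eigenvalues: np.ndarray
    stable: bool


@dataclass(frozen=True)
class EndemicEquilibrium:
    """Endemic steady state in pair/node fractions, with solve residuals."""

    delta: float
    x: float
    y: float
    v: float
    w: float
    residP: float
    residQ: float
    exists: bool
    stable: bool


@dataclass
class BifurcationDiagram:
    """Equilibrium branches over a delta grid (delta_c always on the grid)."""

    deltas: np.ndarray
    dfe_stable: np.ndarray
    endemic: list[EndemicEquilibrium]
    near_approx: np.ndarray
    far_approx: np.ndarray
    delta_c: float
    idx_nearest_dc: int
    failures: dict[float, str] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "delta": self.deltas,
                "dfe_stable": self.dfe_stable,
                "endemic_exists": [e.exists for e in self.endemic],
                "w_exact": [e.w if e.exists else np.nan for e in self.endemic],
                "w_near": self.near_approx,
                "w_far": self.far_approx,
                "residP": [e.residP if e.exists else np.nan for e in self.endemic],
                "residQ": [e.residQ if e.exists else np.nan for e in self.endemic],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def summary(self) -> dict:
        """Branch extent and worst approximation errors on their sub-ranges."""
        w = np.array([e.w if e.exists else np.nan for e in self.endemic])
        on_branch = ~np.isnan(w)
        near_err = np.nanmax(np.abs(w - self.near_approx)) if on_branch.any() else None
        far_err = np.nanmax(np.abs(w - self.far_approx)) if on_branch.any() else None
        return {
            "delta_c": self.delta_c,
            "branch_delta_min": float(self.deltas[on_branch].min()) if on_branch.any() else None,
            "branch_delta_max": float(self.deltas[on_branch].max()) if on_branch.any() else None,
            "max_abs_err_near": None if near_err is None or math.isnan(near_err) else float(near_err),
            "max_abs_err_far": None if far_err is None or math.isnan(far_err) else float(far_err),
            "n_failures": len(self.failures),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def dfe_analysis(delta: float, c: ModelConstants, kmean: float) -> DfeAnalysis:
    """Jacobian of the reduced (w, x, z) system at the DFE and its stability.

    The matrix is block triangular: eigenvalue -1 plus the eigenvalues of the
    2x2 block B with Tr(B) = (kbar - 1)*delta - 3 and Det(B) = 2(1 - delta*kbar);
    both B-eigenvalues are real, and the DFE is stable iff delta < 1/kbar.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    kbar = c.alpha / kmean + c.beta  # equals c.kbar; assembled per the Jacobian
    jac = np.array(
        [
            [-1.0, kmean * delta, 0.0],
            [0.0, kbar * delta - (delta + 1.0), 1.0],
            [0.0, 2.0 * delta, -2.0],
        ]
    )
    B = jac[1:, 1:]
    traceB = float(np.trace(B))
    detB = float(np.linalg.det(B))
    eigs = np.sort(np.linalg.eigvals(jac).real)
    return DfeAnalysis(jac, traceB, detB, eigs, stable=(detB > 0 and traceB < 0))


# ---------------------------------------------------------------------------
# Steady-state polynomial system, in eps = delta_c/delta


def steady_state_P(x: float, y: float, delta: float, c: ModelConstants) -> float:
    """First steady-state polynomial (the trivial DFE factor x is retained).

    P = eps^2 (1-y-2x)(x+y)^2 - eps (delta_c x (x+y)^2 + lam x^2 + mu x^2 (x+y))
        + lam sig x^3,  with eps = delta_c/delta.
    """
    eps = c.delta_c / delta
    s = x + y
    return (
        eps**2 * (1 - y - 2 * x) * s**2
        - eps * (c.delta_c * x * s**2 + c.lam * x**2 + c.mu * x**2 * s)
        + c.lam * c.sigma * x**3
    )


def steady_state_Q(x: float, y: float, delta: float, c: ModelConstants) -> float:
    """Second steady-state polynomial, after removing the DFE factor x.

    Q = eps^2 (x+y)^2 - eps (lam y + mu y (x+y)) + lam sig x y.
    """
    eps = c.delta_c / delta
    s = x + y
    return eps**2 * s**2 - eps * (c.lam * y + c.mu * y * s) + c.lam * c.sigma * x * y


def _pq_jacobian(x: float, y: float, eps: float, c: ModelConstants) -> np.ndarray:
    dc, lam, mu, sig = c.delta_c, c.lam, c.mu, c.sigma
    s = x + y
    Px = (
        eps**2 * (-2 * s**2 + 2 * (1 - y - 2 * x) * s)
        - eps * (dc * (s**2 + 2 * x * s) + 2 * lam * x + mu * (2 * x * s + x**2))
        + 3 * lam * sig * x**2
    )
    Py = (
        eps**2 * (-(s**2) + 2 * (1 - y - 2 * x) * s)
        - eps * (2 * dc * x * s + mu * x**2)
    )
    Qx = 2 * eps**2 * s - eps * mu * y + lam * sig * y
    Qy = 2 * eps**2 * s - eps * (lam + mu * (x + 2 * y)) + lam * sig * x
    return np.array([[Px, Py], [Qx, Qy]])


def _in_feasible_region(x: float, y: float) -> bool:
    return x > 0 and y >= 0 and x + y < 1 and 2 * x + y < 1


def _newton(
    x0: float, y0: float, delta: float, c: ModelConstants
) -> tuple[float, float] | None:
    eps = c.delta_c / delta
    u = np.array([x0, y0], dtype=float)

    def resid(u: np.ndarray) -> np.ndarray:
        return np.array(
            [steady_state_P(u[0], u[1], delta, c), steady_state_Q(u[0], u[1], delta, c)]
        )

    r = resid(u)
    for _ in range(_MAX_ITER):
        rn = np.linalg.norm(r)
        if rn < _NEWTON_TOL:
            break
        jac = _pq_jacobian(u[0], u[1], eps, c)
        try:
            step = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError:
            return None
        # damp by halving while the residual increases
        lam_damp = 1.0
        for _ in range(40):
            trial = u + lam_damp * step
            r_trial = resid(trial)
            if np.linalg.norm(r_trial) < rn:
                break
            lam_damp *= 0.5
        else:
            return None
        u, r = trial, r_trial
        if np.linalg.norm(lam_damp * step) < _STEP_TOL:
            break
    if max(abs(r[0]), abs(r[1])) > RESIDUAL_TOL:
        return None
    return float(u[0]), float(u[1])


def _seed_near(delta: float, c: ModelConstants) -> tuple[float, float]:
    near = near_threshold_equilibrium(delta, c, max_eta=1.0)
    x0 = near.x_star
    return x0, max(1.0 - near.lin_slope * x0, 0.0)


def _seed_far(delta: float, c: ModelConstants) -> tuple[float, float]:
    far = far_equilibrium(delta, c, max_eps=1.0)
    phi, psi = far_linearization(far.eps, c)
    x0 = far.x_star
    return x0, max(psi * (x0 - phi), 0.0)


def endemic_jacobian(
    eq: EndemicEquilibrium, c: ModelConstants, fd_step: float = 1e-7
) -> np.ndarray:
    """Jacobian of the reduced (v, x, y) flow at the equilibrium, by central
    finite differences (stability is only proven near the threshold, so it is
    assessed numerically)."""
    u0 = np.array([eq.v, eq.x, eq.y])
    jac = np.empty((3, 3))
    for j in range(3):
        up, dn = u0.copy(), u0.copy()
        up[j] += fd_step
        dn[j] -= fd_step
        jac[:, j] = (
            rhs_reduced_vxy(up, eq.delta, c) - rhs_reduced_vxy(dn, eq.delta, c)
        ) / (2 * fd_step)
    return jac


def _no_endemic(delta: float) -> EndemicEquilibrium:
    nan = float("nan")
    return EndemicEquilibrium(delta, nan, nan, nan, nan, nan, nan, False, False)


def solve_endemic(
    delta: float,
    c: ModelConstants,
    seed_hint: tuple[float, float] | None = None,
    seed_switch: float = SEED_SWITCH,
) -> EndemicEquilibrium:
    """Endemic equilibrium at a given delta by seeded, damped Newton iteration.

    Below (or at) the threshold there is no endemic state and ``exists`` is
    False.  Above it, the Newton solve is seeded from the near-threshold
    expansion when delta/delta_c < ``seed_switch`` and from the far expansion
    otherwise (``seed_hint`` overrides both); if both seeds fail, a short
    continuation from just above delta_c retries.  The solution must land in
    the open feasible region x > 0, y >= 0, x + y < 1, 2x + y < 1; stability
    is judged from the numerically differenced (v, x, y) Jacobian.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    if delta <= c.delta_c:
        return _no_endemic(delta)

    seeds: list[tuple[float, float]] = []
    if seed_hint is not None:
        seeds.append(tuple(seed_hint))
    if delta / c.delta_c < seed_switch:
        seeds += [_seed_near(delta, c), _seed_far(delta, c)]
    else:
        seeds += [_seed_far(delta, c), _seed_near(delta, c)]

    sol = None
    for x0, y0 in seeds:
        cand = _newton(x0, y0, delta, c)
        if cand is not None and _in_feasible_region(*cand):
            sol = cand
            break
    if sol is None:
        # continuation fallback: walk up from just above delta_c
        prev = None
        for d in np.geomspace(c.delta_c * 1.001, delta, 40):
            seed = prev if prev is not None else _seed_near(d, c)
            cand = _newton(seed[0], seed[1], d, c)
            if cand is None or not _in_feasible_region(*cand):
                prev = None
                continue
            prev = cand
        if prev is not None:
            sol = prev
    if sol is None:
        raise SolverError(
            f"endemic solve failed at delta = {delta} (delta/delta_c = "
            f"{delta / c.delta_c:.3g}); seeds tried: {seeds}"
        )

    x, y = sol
    w = c.sigma * (delta / c.delta_c) * x
    eq = EndemicEquilibrium(
        delta,
        x,
        y,
        1.0 - w,
        w,
        abs(steady_state_P(x, y, delta, c)),
        abs(steady_state_Q(x, y, delta, c)),
        True,
        False,
    )
    stable = bool(np.all(np.linalg.eigvals(endemic_jacobian(eq, c)).real < 0))
    return EndemicEquilibrium(
        eq.delta, eq.x, eq.y, eq.v, eq.w, eq.residP, eq.residQ, True, stable
    )


def bifurcation_diagram(
    c: ModelConstants,
    kmean: float,
    delta_min: float,
    delta_max: float,
    n_points: int,
) -> BifurcationDiagram:
    """Equilibrium branches over a uniform delta grid (delta_c appended).

    The endemic branch is continued along the grid, each solution seeding the
    next; per-point solver failures are recorded, not fatal.  Near/far
    approximation columns are evaluated wherever their formulas are defined
    (regime guards relaxed for plotting).
    """
    if not (0 <= delta_min < delta_max):
        raise ValueError("need 0 <= delta_min < delta_max")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    deltas = np.linspace(delta_min, delta_max, n_points)
    if delta_min <= c.delta_c <= delta_max and c.delta_c not in deltas:
        deltas = np.sort(np.append(deltas, c.delta_c))
    idx_nearest = int(np.argmin(np.abs(deltas - c.delta_c)))

    dfe_stable = np.empty(deltas.size, dtype=bool)
    endemic: list[EndemicEquilibrium] = []
    near = np.full(deltas.size, np.nan)
    far = np.full(deltas.size, np.nan)
    failures: dict[float, str] = {}
    prev_seed: tuple[float, float] | None = None
    for i, d in enumerate(deltas):
        dfe_stable[i] = dfe_analysis(d, c, kmean).stable
        if d > c.delta_c:
            near[i] = near_threshold_equilibrium(d, c, max_eta=1.0).w_star
            far[i] = far_equilibrium(d, c, max_eps=1.0).w_star
        elif d == c.delta_c:
            near[i] = 0.0
        try:
            eq = solve_endemic(d, c, seed_hint=prev_seed) if d > 0 else _no_endemic(d)
        except SolverError as exc:
            failures[float(d)] = str(exc)
            eq = _no_endemic(d)
            prev_seed = None
        else:
            prev_seed = (eq.x, eq.y) if eq.exists else None
        endemic.append(eq)
    return BifurcationDiagram(
        deltas, dfe_stable, endemic, near, far, c.delta_c, idx_nearest, failures
    )
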