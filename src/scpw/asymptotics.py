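"""Perturbation approximations of the endemic equilibrium.

The endemic steady state of the SCPW model solves a pair of polynomial
equations in the pair fractions (x, y) with no usable closed form.  Two
regimes admit asymptotic approximations:

* **near threshold** (delta slightly above delta_c): small parameter
  ``eta = 1 - delta_c/delta``; the equilibrium is a perturbation of the
  disease-free point (x, y) = (0, 1), giving prevalence
  ``w* ~ sigma/(lam*sigma + mu*delta_c + mu - delta_c) * eta``;
* **far from threshold** (delta >> delta_c): small parameter
  ``eps = delta_c/delta``; few S-S links survive so y ~ 0; linearizing the
  first steady-state polynomial on the y = 0 slice around its root phi(eps)
  with slope psi(eps) yields ``x* ~ eps/sigma + (delta_c+mu-sigma)/
  (lam*sigma^2) * eps^2`` and ``w* ~ 1 + (delta_c+mu-sigma)/(lam*sigma) * eps``.

There is no good approximation in the intermediate regime, so both
evaluators enforce configurable domain guards rather than extrapolating
silently.  Setting the far-regime prevalence to zero also yields an implied
epidemic threshold, which over- or underestimates the true delta_c depending
on the degree moments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .degree_moments import ModelConstants, NetworkMoments

__all__ = [
    "NearExpansion",
    "FarExpansion",
    "FarThresholdEstimate",
    "near_threshold_equilibrium",
    "far_linearization",
    "far_equilibrium",
    "far_threshold_estimate",
]

#: Default regime guards: the expansions are first-order and degrade away
#: from their regime; refuse rather than extrapolate.
MAX_ETA = 0.5
MAX_EPS = 0.9

_IDENTITY_TOL = 1e-10


class RegimeError(ValueError):
    """delta lies outside the validity domain of the requested expansion."""


class DegenerateExpansionError(ValueError):
    """A series denominator vanishes for these model constants."""


@dataclass(frozen=True)
class NearExpansion:
    """First-order endemic equilibrium near the threshold.

    ``slope`` is dw*/d(eta); ``lin_slope`` is the coefficient in the seeding
    linearization ``y ~ 1 - lin_slope * x`` around the disease-free point.
    """

    eta: float
    x_star: float
    w_star: float
    slope: float
    lin_slope: float


@dataclass(frozen=True)
class FarExpansion:
    """Far-from-threshold endemic equilibrium (x* to two orders in eps)."""

    eps: float
    phi: float
    psi: float
    phi_coeffs: tuple[float, float]
    psi_coeffs: tuple[float, float]
    x_star: float
    w_star: float


@dataclass(frozen=True)
class FarThresholdEstimate:
    """Implied threshold from the far approximation's w* = 0 crossing."""

    delta_estimate: float
    classification: str  # 'overestimate' | 'underestimate' | 'equal'
    jensen_rule_overestimate: bool  # <k^2> >= <k>^2 + <k> predicts overestimate


def _check_identity(c: ModelConstants) -> None:
    # lam + mu = delta_c * kbar = 1 is what cancels the constant term of the
    # near expansion; a violation means the constants are inconsistent.
    if abs(c.lam + c.mu - 1.0) > _IDENTITY_TOL:
        raise ValueError(
            f"inconsistent constants: lam + mu = {c.lam + c.mu!r} != 1"
        )


def near_threshold_equilibrium(
    delta: float, c: ModelConstants, max_eta: float = MAX_ETA
) -> NearExpansion:
    """First-order expansion of the endemic equilibrium in eta = 1 - delta_c/delta."""
    _check_identity(c)
    if delta < c.delta_c:
        raise RegimeError(
            f"delta = {delta} < delta_c = {c.delta_c}: no endemic state to expand"
        )
    eta = 1.0 - c.delta_c / delta
    if eta > max_eta:
        raise RegimeError(
            f"eta = {eta:.4g} > {max_eta}: outside the near-threshold regime"
        )
    denom = c.lam * c.sigma + c.mu * c.delta_c + c.mu - c.delta_c
    if abs(denom) < 1e-14:
        raise DegenerateExpansionError(
            "near expansion denominator lam*sigma + mu*delta_c + mu - delta_c vanishes"
        )
    x_star = eta / denom
    lin_slope = 2.0 + c.delta_c / (1.0 - eta)
    return NearExpansion(eta, x_star, c.sigma * x_star, c.sigma / denom, lin_slope)


def far_linearization(eps: float, c: ModelConstants) -> tuple[float, float]:
    """Root phi and slope psi of the y = 0 linearization of the first
    steady-state polynomial: ``y ~ psi * (x - phi)``.

    phi solves P(phi, 0) = 0; psi = -P_x(phi, 0)/P_y(phi, 0).
    """
    if not eps > 0:
        raise ValueError("eps must be positive")
    dc, lam, mu, sig = c.delta_c, c.lam, c.mu, c.sigma
    den_phi = 2 * eps**2 + (dc + mu) * eps - lam * sig
    if abs(den_phi) < 1e-14:
        raise DegenerateExpansionError("phi denominator vanishes")
    phi = (eps**2 - lam * eps) / den_phi
    den_psi = eps * (eps**2 - (mu + 5 * lam) * eps - lam * (2 * dc + mu - 2 * sig))
    if abs(den_psi) < 1e-14:
        raise DegenerateExpansionError("psi denominator vanishes")
    psi = -(eps - lam) * den_phi / den_psi
    return phi, psi


def far_equilibrium(
    delta: float, c: ModelConstants, max_eps: float = MAX_EPS
) -> FarExpansion:
    """Far-from-threshold expansion in eps = delta_c/delta.

    x* keeps two orders (its coefficients coincide with those of phi);
    w* = sigma * x*/eps, first order in eps.
    """
    _check_identity(c)
    if not delta > c.delta_c:
        raise RegimeError(
            f"delta = {delta} <= delta_c = {c.delta_c}: no endemic state"
        )
    eps = c.delta_c / delta
    if eps > max_eps:
        raise RegimeError(
            f"eps = {eps:.4g} > {max_eps}: outside the far-from-threshold regime"
        )
    dc, lam, mu, sig = c.delta_c, c.lam, c.mu, c.sigma
    if abs(lam) < 1e-14:
        raise DegenerateExpansionError("lam = 0: second-order coefficient undefined")
    phi, psi = far_linearization(eps, c)
    phi1 = 1.0 / sig
    phi2 = (dc + mu - sig) / (lam * sig**2)
    den = 2 * dc + mu - 2 * sig
    if abs(den) < 1e-14:
        raise DegenerateExpansionError("psi series denominator 2*delta_c+mu-2*sigma vanishes")
    psi_m1 = lam * sig / den
    psi_0 = -(2 * dc**2 + 3 * dc * mu + sig * (5 * lam + 2 * sig) + mu**2) / den**2
    x_star = phi1 * eps + phi2 * eps**2
    w_star = sig * x_star / eps
    return FarExpansion(eps, phi, psi, (phi1, phi2), (psi_m1, psi_0), x_star, w_star)


def far_threshold_estimate(
    c: ModelConstants, m: NetworkMoments
) -> FarThresholdEstimate:
    """Implied epidemic threshold from the far approximation.

    The far prevalence ``w* ~ 1 + G*eps`` with ``G = (delta_c+mu-sigma)/
    (lam*sigma)`` crosses zero at ``eps* = -1/G``, i.e. at
    ``delta* = -G*delta_c``, provided G < 0.  The estimate overestimates
    delta_c when ``<k^2> >= <k>^2 + <k>`` and otherwise may fall on either
    side depending on the third moment.
    """
    G = (c.delta_c + c.mu - c.sigma) / (c.lam * c.sigma)
    if G >= 0:
        raise DegenerateExpansionError(
            f"far-regime prevalence coefficient G = {G:.4g} >= 0: "
            "w* never crosses zero at positive eps"
        )
    delta_est = -G * c.delta_c
    if abs(delta_est - c.delta_c) <= 1e-12 * c.delta_c:
        classification = "equal"
    elif delta_est > c.delta_c:
        classification = "overestimate"
    else:
        classification = "underestimate"
    return FarThresholdEstimate(
        delta_est, classification, m.k2 >= m.k1**2 + m.k1
    )
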