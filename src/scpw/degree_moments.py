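"""Degree-distribution moments and derived model constants.

The super compact pairwise (SCPW) SIS model sees the contact network only
through the first three raw moments of its degree distribution,
``<k^n> = sum_k k^n p_k``.  Everything downstream — the moment-closure
constants alpha and beta, the epidemic threshold delta_c, and the rescaled
constants sigma, lambda, mu used by the steady-state analysis — is a pure
function of those three numbers.  This module computes them from any of the
supported network inputs (a degree sequence, an explicit distribution table,
or a named parametric family).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DegreeDistribution",
    "NetworkMoments",
    "ModelConstants",
    "moments_from_sequence",
    "moments_from_distribution",
    "poisson_distribution",
    "bimodal_distribution",
    "derived_constants",
    "epidemic_threshold",
    "read_degree_sequence",
    "write_degree_sequence",
    "read_distribution_csv",
    "write_distribution_csv",
    "constants_to_json",
]

#: Relative tolerance (w.r.t. <k>^2) below which the degree variance is
#: treated as zero.  alpha and beta are 0/0 for a regular network, so we
#: refuse rather than guess a limit.
VARIANCE_TOL = 1e-10

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class DegreeDistribution:
    """A probability distribution over node degrees.

    Parameters
    ----------
    support : tuple of int
        Distinct nonnegative degrees, strictly increasing.
    mass : tuple of float
        Matching probabilities; nonnegative, summing to 1 within 1e-12.
    """

    support: tuple[int, ...]
    mass: tuple[float, ...]

    def __post_init__(self) -> None:
        support = tuple(int(k) for k in self.support)
        mass = tuple(float(p) for p in self.mass)
        if len(support) != len(mass) or not support:
            raise ValueError("support and mass must be equal-length and nonempty")
        if any(k < 0 for k in support):
            raise ValueError("degrees must be nonnegative integers")
        if any(a >= b for a, b in zip(support, support[1:])):
            raise ValueError("support must be strictly increasing (distinct degrees)")
        if any(p < 0 for p in mass):
            raise ValueError("probabilities must be nonnegative")
        total = math.fsum(mass)
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"probabilities sum to {total!r}, not 1 (tol {_MASS_TOL})")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)


@dataclass(frozen=True)
class NetworkMoments:
    """First three raw moments <k>, <k^2>, <k^3> of a degree distribution."""

    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError("<k> must be positive (network has edges)")
        scale1 = self.k1**2
        if self.k2 - scale1 < -1e-12 * max(scale1, 1.0):
            raise ValueError("moments violate Jensen: <k^2> < <k>^2")
        cs = self.k3 * self.k1
        if self.k2**2 - cs > 1e-12 * max(cs, 1.0):
            raise ValueError("moments violate Cauchy-Schwarz: <k^2>^2 > <k^3><k>")


@dataclass(frozen=True)
class ModelConstants:
    """Constants derived from the degree moments.

    alpha, beta
        Moment-closure constants of the SCPW pair closure.
    kbar
        Mean excess degree ``(<k^2> - <k>)/<k>``; satisfies
        ``alpha/<k> + beta = kbar``.
    delta_c
        Epidemic threshold of the transmission/recovery ratio,
        ``delta_c = 1/kbar``.
    sigma, lam, mu
        Rescaled constants ``sigma = <k> delta_c``, ``lam = alpha delta_c/<k>``,
        ``mu = beta delta_c`` used by the steady-state polynomial system.
        ``lam + mu = 1`` always (a consequence of alpha/<k> + beta = kbar).
    """

    alpha: float
    beta: float
    kbar: float
    delta_c: float
    sigma: float
    lam: float
    mu: float


def _validated_degrees(degrees: Iterable[object]) -> np.ndarray:
    arr = np.asarray(list(degrees))
    if arr.size == 0:
        raise ValueError("degree sequence is empty")
    if arr.dtype.kind == "f":
        if not np.all(arr == np.floor(arr)):
            raise ValueError("degree sequence contains non-integer entries")
        arr = arr.astype(np.int64)
    elif arr.dtype.kind not in "iu":
        raise ValueError("degree sequence entries must be integers")
    if np.any(arr < 0):
        raise ValueError("degree sequence contains negative entries")
    if not np.any(arr > 0):
        raise ValueError("degree sequence is all zeros; network has no edges")
    return arr


def moments_from_sequence(degrees: Sequence[int]) -> NetworkMoments:
    """Empirical raw moments ``(1/N) sum k_i^n`` of a degree sequence.

    Degree-0 nodes are allowed and contribute to the averages.
    """
    arr = _validated_degrees(degrees).astype(np.float64)
    n = arr.size
    # fsum keeps the averages stable to ~1e-12 relative for sequences up to 1e7
    k1 = math.fsum(arr) / n
    k2 = math.fsum(arr**2) / n
    k3 = math.fsum(arr**3) / n
    return NetworkMoments(k1, k2, k3)


def moments_from_distribution(dist: DegreeDistribution) -> NetworkMoments:
    """Raw moments ``sum_k k^n p_k`` of an explicit degree distribution."""
    k = np.asarray(dist.support, dtype=np.float64)
    p = np.asarray(dist.mass, dtype=np.float64)
    return NetworkMoments(
        math.fsum(k * p), math.fsum(k**2 * p), math.fsum(k**3 * p)
    )


def poisson_distribution(mean: float, tail_mass: float = 1e-12) -> DegreeDistribution:
    """Truncated, renormalized Poisson degree distribution.

    The support is {0, ..., K} where K is the smallest degree whose upper-tail
    mass falls below ``tail_mass``; the retained mass is renormalized to sum
    to 1 exactly.
    """
    if not mean > 0:
        raise ValueError("Poisson mean must be positive")
    if not 0 < tail_mass < 1e-6:
        raise ValueError("tail_mass must lie in (0, 1e-6)")
    kmax = int(stats.poisson.isf(tail_mass, mean)) + 1
    while stats.poisson.sf(kmax, mean) >= tail_mass:  # guard against isf slack
        kmax += 1
    support = np.arange(kmax + 1)
    mass = stats.poisson.pmf(support, mean)
    mass /= math.fsum(mass)
    return DegreeDistribution(tuple(int(k) for k in support), tuple(mass))


def bimodal_distribution(k_lo: int, k_hi: int, frac_lo: float = 0.5) -> DegreeDistribution:
    """Two-point degree distribution: degree ``k_lo`` w.p. ``frac_lo``, else ``k_hi``."""
    if not 0 < frac_lo < 1:
        raise ValueError("frac_lo must lie in (0, 1)")
    if not 0 <= k_lo < k_hi:
        raise ValueError("need 0 <= k_lo < k_hi")
    return DegreeDistribution((k_lo, k_hi), (frac_lo, 1.0 - frac_lo))


def epidemic_threshold(m: NetworkMoments) -> float:
    """Epidemic threshold ``delta_c = <k>/(<k^2> - <k>)``.

    Valid for any network with <k^2> > <k> (including regular networks,
    where it reduces to 1/(k-1)).
    """
    if not m.k2 > m.k1:
        raise ValueError(
            "epidemic threshold undefined: requires <k^2> > <k> "
            f"(got <k^2>={m.k2}, <k>={m.k1})"
        )
    return m.k1 / (m.k2 - m.k1)


def derived_constants(m: NetworkMoments, variance_tol: float = VARIANCE_TOL) -> ModelConstants:
    """All SCPW model constants from the first three degree moments.

    Raises for (near-)regular networks, where the closure constants alpha and
    beta have the vanishing denominator <k^2> - <k>^2.
    """
    variance = m.k2 - m.k1**2
    if variance <= variance_tol * m.k1**2:
        raise ValueError(
            "degenerate distribution: <k^2> - <k>^2 = "
            f"{variance:.3e} vanishes (regular network), so the closure "
            "constants alpha and beta (denominator <k^2> - <k>^2) are undefined"
        )
    delta_c = epidemic_threshold(m)
    alpha = (m.k2**2 - m.k1 * m.k3) / variance
    beta = (m.k3 - m.k2 * m.k1) / variance - 1.0
    kbar = (m.k2 - m.k1) / m.k1
    sigma = m.k1 * delta_c
    lam = alpha * delta_c / m.k1
    mu = beta * delta_c
    return ModelConstants(alpha, beta, kbar, delta_c, sigma, lam, mu)


# ---------------------------------------------------------------------------
# File I/O


def read_degree_sequence(path: str | Path) -> list[int]:
    """Read a degree sequence: one nonnegative integer per line, '#' comments."""
    degrees: list[int] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            k = int(line)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not an integer: {line!r}") from exc
        if k < 0:
            raise ValueError(f"{path}:{lineno}: negative degree {k}")
        degrees.append(k)
    if not degrees:
        raise ValueError(f"{path}: no degrees found")
    return degrees


def write_degree_sequence(path: str | Path, degrees: Sequence[int]) -> None:
    Path(path).write_text("\n".join(str(int(k)) for k in degrees) + "\n")


def read_distribution_csv(path: str | Path) -> DegreeDistribution:
    """Read a two-column CSV with header ``k,p``."""
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns) != ["k", "p"]:
        raise ValueError(f"{path}: expected header 'k,p', got {list(df.columns)}")
    order = np.argsort(df["k"].to_numpy())
    return DegreeDistribution(
        tuple(int(k) for k in df["k"].to_numpy()[order]),
        tuple(float(p) for p in df["p"].to_numpy()[order]),
    )


def write_distribution_csv(path: str | Path, dist: DegreeDistribution) -> None:
    lines = ["k,p"] + [f"{k},{p:.12g}" for k, p in zip(dist.support, dist.mass)]
    Path(path).write_text("\n".join(lines) + "\n")


def constants_to_json(m: NetworkMoments, c: ModelConstants) -> str:
    """JSON export of moments and derived constants."""
    return json.dumps(
        {
            "k1": m.k1,
            "k2": m.k2,
            "k3": m.k3,
            "alpha": c.alpha,
            "beta": c.beta,
            "kbar": c.kbar,
            "delta_c": c.delta_c,
            "sigma": c.sigma,
            "lambda": c.lam,
            "mu": c.mu,
        },
        indent=2,
    )
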