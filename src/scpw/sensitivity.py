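"""Sensitivity of endemic prevalence to the degree-distribution moments.

Because the asymptotic approximations of the endemic prevalence w* are
explicit in the first three degree moments, their partial derivatives are
closed forms.  Near the threshold (evaluated at delta = delta_c):

    dw*/d<k>   = -<k^2> / (<k> - 2<k^2> + <k^3>),
    dw*/d<k^2> =  <k>  / (<k> - 2<k^2> + <k^3>),
    dw*/d<k^3> =  0,

so prevalence falls with mean degree and rises with the second moment.  Far
from the threshold all three partials carry a common 1/delta factor and the
first two reverse sign — control measures that lower endemic prevalence must
target different moments in the two regimes.

Moment triples live in the wedge-shaped feasible region cut out by Jensen
(<k^2> >= <k>^2) and Cauchy-Schwarz (<k^2>^2 <= <k^3><k>); grids for heat
maps are masked outside it, and the far-regime partials blow up (and are
masked) on the Cauchy-Schwarz boundary where their denominator vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .degree_moments import NetworkMoments

__all__ = [
    "SensitivityTriple",
    "SensitivityGrid",
    "feasible",
    "sens_near",
    "sens_far",
    "sensitivity_grid",
    "plot_sensitivity_grid",
]

_BOUNDARY_RTOL = 1e-12


@dataclass(frozen=True)
class SensitivityTriple:
    """Partial derivatives of endemic prevalence w.r.t. <k>, <k^2>, <k^3>."""

    d_k1: float
    d_k2: float
    d_k3: float


@dataclass(frozen=True)
class SensitivityGrid:
    """Sensitivities on a (<k>, <k^2>) grid at fixed <k^3>, masked to feasibility."""

    k3: float
    k1_axis: np.ndarray
    k2_axis: np.ndarray
    d_k1: np.ndarray  # shape (len(k2_axis), len(k1_axis)); NaN where masked
    d_k2: np.ndarray
    d_k3: np.ndarray
    feasible_mask: np.ndarray
    delta: float
    regime: str

    def to_frame(self):
        import pandas as pd

        K1, K2 = np.meshgrid(self.k1_axis, self.k2_axis)
        return pd.DataFrame(
            {
                "k1": K1.ravel(),
                "k2": K2.ravel(),
                "k3": self.k3,
                "regime": self.regime,
                "delta": self.delta,
                "feasible": self.feasible_mask.ravel(),
                "d_k1": self.d_k1.ravel(),
                "d_k2": self.d_k2.ravel(),
                "d_k3": self.d_k3.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def feasible(k1: float, k2: float, k3: float) -> bool:
    """True iff (k1, k2, k3) can be moments of a degree distribution:
    Jensen <k^2> >= <k>^2 and Cauchy-Schwarz <k^2>^2 <= <k^3><k> (non-strict)."""
    if not k1 > 0:
        raise ValueError("<k> must be positive")
    return k2 >= k1**2 and k2**2 <= k3 * k1


def _near_raw(k1: float, k2: float, k3: float, delta: float | None) -> SensitivityTriple:
    denom = k1 - 2 * k2 + k3
    if denom == 0:
        raise ZeroDivisionError(
            "degenerate near-threshold sensitivity: <k> - 2<k^2> + <k^3> = 0"
        )
    if delta is None:
        return SensitivityTriple(-k2 / denom, k1 / denom, 0.0)
    # full derivative of w*(delta) = C * (1 - delta_c/delta) at fixed delta,
    # with C = <k>(<k^2>-<k>)/(<k> - 2<k^2> + <k^3>) and delta_c = <k>/(<k^2>-<k>)
    E = k2 - k1
    delta_c = k1 / E
    eta = 1.0 - delta_c / delta
    C = k1 * E / denom
    dC_k1 = ((k2 - 2 * k1) * denom - k1 * E) / denom**2
    dC_k2 = k1 * (denom + 2 * E) / denom**2
    dC_k3 = -k1 * E / denom**2
    ddc_k1 = k2 / E**2
    ddc_k2 = -k1 / E**2
    return SensitivityTriple(
        dC_k1 * eta - C * ddc_k1 / delta,
        dC_k2 * eta - C * ddc_k2 / delta,
        dC_k3 * eta,
    )


def _far_raw(k1: float, k2: float, k3: float, delta: float) -> SensitivityTriple:
    M = k2**2 - k3 * k1
    if abs(M) <= _BOUNDARY_RTOL * max(k2**2, abs(k3 * k1)):
        raise ZeroDivisionError(
            "far-regime sensitivities undefined on the Cauchy-Schwarz "
            "boundary <k^2>^2 = <k^3><k>"
        )
    d_k1 = (k3**2 + 3 * k1**2 * k2**2 - 2 * (k1**3 * k3 + k2**3)) / M**2 / delta
    d_k2 = -2 * (k1**2 - k2) * (k1 * k2 - k3) / M**2 / delta
    d_k3 = (k1**2 - k2) ** 2 / M**2 / delta
    return SensitivityTriple(d_k1, d_k2, d_k3)


def sens_near(m: NetworkMoments, delta: float | None = None) -> SensitivityTriple:
    """Near-threshold sensitivities.

    By default these are the delta -> delta_c limit values (the tabulated
    closed forms, with dw*/d<k^3> exactly 0); pass ``delta`` for the full
    delta-dependent derivative of the near approximation at fixed delta.
    """
    if not feasible(m.k1, m.k2, m.k3):
        raise ValueError("moments are infeasible (Jensen/Cauchy-Schwarz violated)")
    return _near_raw(m.k1, m.k2, m.k3, delta)


def sens_far(m: NetworkMoments, delta: float) -> SensitivityTriple:
    """Far-from-threshold sensitivities at a given delta (all scale as 1/delta)."""
    if not delta > 0:
        raise ValueError("delta must be positive")
    if not feasible(m.k1, m.k2, m.k3):
        raise ValueError("moments are infeasible (Jensen/Cauchy-Schwarz violated)")
    return _far_raw(m.k1, m.k2, m.k3, delta)


def sensitivity_grid(
    k3: float,
    k1_range: tuple[float, float],
    k2_range: tuple[float, float],
    n: int,
    regime: Literal["near", "far"],
    delta: float = 1.5,
) -> SensitivityGrid:
    """Evaluate sensitivities on an n-by-n (<k>, <k^2>) grid at fixed <k^3>.

    Cells outside the feasible wedge — or on the Cauchy-Schwarz boundary,
    where the far partials are undefined — are masked (NaN).  Grid moments
    are free reals; they need not arise from an integer-support distribution.
    """
    if regime not in ("near", "far"):
        raise ValueError("regime must be 'near' or 'far'")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (k1_range[0] > 0 and k2_range[0] > 0):
        raise ValueError("ranges must be positive")
    k1_axis = np.linspace(*k1_range, n)
    k2_axis = np.linspace(*k2_range, n)
    shape = (n, n)
    d1 = np.full(shape, np.nan)
    d2 = np.full(shape, np.nan)
    d3 = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    for i, k2 in enumerate(k2_axis):
        for j, k1 in enumerate(k1_axis):
            if not feasible(k1, k2, k3):
                continue
            try:
                t = (
                    _near_raw(k1, k2, k3, None)
                    if regime == "near"
                    else _far_raw(k1, k2, k3, delta)
                )
            except ZeroDivisionError:
                continue  # boundary/degenerate cell stays masked
            mask[i, j] = True
            d1[i, j], d2[i, j], d3[i, j] = t.d_k1, t.d_k2, t.d_k3
    return SensitivityGrid(k3, k1_axis, k2_axis, d1, d2, d3, mask, delta, regime)


def plot_sensitivity_grid(grid: SensitivityGrid, path: str | Path) -> None:
    """Render heat maps of the three partials (one panel each; infeasible
    cells white)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("d_k1", grid.d_k1), ("d_k2", grid.d_k2), ("d_k3", grid.d_k3)]
    fig, axes = plt.subplots(1, 3, figsize=(13, 4), constrained_layout=True)
    extent = (
        grid.k1_axis[0], grid.k1_axis[-1], grid.k2_axis[0], grid.k2_axis[-1]
    )
    for ax, (name, vals) in zip(axes, panels):
        im = ax.imshow(vals, origin="lower", extent=extent, aspect="auto")
        ax.set_xlabel(r"$\langle k \rangle$")
        ax.set_ylabel(r"$\langle k^2 \rangle$")
        ax.set_title(f"{name} ({grid.regime}, $k_3$={grid.k3:g})")
        fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120)
    plt.close(fig)
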