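"""Single-society model: vector field, fixed points, stability, thresholds.

The extraction rate ``alpha`` organizes the long-term behaviour:

* ``alpha < alpha_star``: the resource-only equilibrium ``N = (0, K, 0)``
  is stable — extraction is too weak to sustain any capacity.
* ``alpha_star < alpha < alpha_hopf``: a transcritical bifurcation has
  handed stability to the interior equilibrium ``E`` (the sustainable
  regime); capacity at ``E`` is maximal at ``alpha = 2 alpha_star``.
* ``alpha > alpha_hopf``: a supercritical Hopf bifurcation replaces ``E``
  by a limit cycle whose large-amplitude swings approach the origin
  (recurrent collapse; the unsustainable regime).

All analysis here is performed on the unregularized vector field
(``epsilon -> 0``): the factor ``1 - exp(-z/epsilon)`` is taken as 1 at
interior points and as 0 on the invariant plane ``z = 0``, and
``x + epsilon`` as ``x``.  The regularization is a numerical device for
integration, not part of the model's phase-space structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (
    BoundaryRegimeError,
    BracketError,
    FormulaDomainError,
    InvalidStateError,
)
from .params import ModelParams

__all__ = [
    "FixedPoint",
    "BifurcationThresholds",
    "rhs_single",
    "alpha_star",
    "alpha_hopf",
    "fixed_points",
    "jacobian_interior",
    "hopf_detect_numeric",
    "bifurcation_thresholds",
]

_MARGINAL_TOL = 1e-6


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the single-society model.

    ``label`` is "O" (origin), "N" (resource-only point ``(0, K, 0)``) or
    "E" (interior equilibrium).  ``eigenvalues`` are those of the relevant
    linearization (see :func:`fixed_points`); ``stability`` is one of
    "stable", "unstable", "marginal".
    """

    coords: np.ndarray
    label: str
    eigenvalues: np.ndarray
    stability: str

    @property
    def x(self) -> float:
        return float(self.coords[0])

    @property
    def y(self) -> float:
        return float(self.coords[1])

    @property
    def z(self) -> float:
        return float(self.coords[2])


@dataclass(frozen=True)
class BifurcationThresholds:
    """The two critical extraction rates for a parameter set.

    ``alpha_star`` marks the transcritical exchange between the
    resource-only point and the interior equilibrium; ``alpha_crit`` the
    supercritical Hopf bifurcation (closed form), with
    ``alpha_crit_numeric`` its eigenvalue-crossing cross-check.
    """

    alpha_star: float
    alpha_crit: float
    alpha_crit_numeric: float

    def __post_init__(self) -> None:
        if not (0 < self.alpha_star < self.alpha_crit):
            raise ValueError("thresholds must satisfy 0 < alpha_star < alpha_crit")

    @property
    def validated(self) -> bool:
        """True when the closed form agrees with numeric detection to 0.1%."""
        return abs(self.alpha_crit - self.alpha_crit_numeric) / self.alpha_crit < 1e-3

    def to_dict(self) -> dict:
        return {
            "alpha_star": self.alpha_star,
            "alpha_crit": self.alpha_crit,
            "alpha_crit_numeric": self.alpha_crit_numeric,
        }


def rhs_single(s: Sequence[float], p: ModelParams) -> np.ndarray:
    """Evaluate the (regularized) single-society vector field at ``s``.

    Parameters
    ----------
    s : array-like, shape (3,)
        State ``(x, y, z)``; components must be finite and ``z >= 0``.

    Returns
    -------
    ndarray, shape (3,)
        ``(dx/dt, dy/dt, dz/dt)``.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (3,):
        raise InvalidStateError(f"state must have shape (3,), got {s.shape}")
    if not np.all(np.isfinite(s)):
        raise InvalidStateError(f"non-finite state: {s}")
    x, y, z = s
    if z < 0:
        raise InvalidStateError(
            f"negative wealth z={z}: exp(-z/epsilon) would overflow; "
            "the model domain is z >= 0"
        )
    arg = z / p.epsilon
    fac = 1.0 if arg > 700.0 else 1.0 - np.exp(-arg)
    xdot = (p.b * z / (x + p.epsilon) - p.d * x) * fac
    extraction = p.alpha * x * x * y
    ydot = p.r * y * (1.0 - y / p.K) - extraction
    zdot = extraction - p.c * z
    return np.array([xdot, ydot, zdot])


def _rhs_unregularized(s: np.ndarray, p: ModelParams) -> np.ndarray:
    """Limit vector field used for fixed-point residuals.

    On the plane ``z = 0`` the regularizing factor tends to 0 and the
    capacity is frozen; at interior points the factor is 1 and
    ``x + epsilon -> x``.
    """
    x, y, z = s
    extraction = p.alpha * x * x * y
    ydot = p.r * y * (1.0 - y / p.K) - extraction
    zdot = extraction - p.c * z
    xdot = 0.0 if z == 0.0 else p.b * z / x - p.d * x
    return np.array([xdot, ydot, zdot])


def alpha_star(p: ModelParams) -> float:
    """Transcritical threshold ``c d / (K b)``.

    Below it the resource-only point ``N`` is stable; above it the
    interior equilibrium exists and takes over.  Capacity at the interior
    equilibrium is maximal at twice this value.
    """
    return p.c * p.d / (p.K * p.b)


def alpha_hopf(p: ModelParams) -> float:
    """Closed-form Hopf threshold of the interior equilibrium.

    With ``P = 2cd + (c + 2d)^2``:

    .. math::

        \\alpha_c = \\frac{P}{4Kb}\\left(1 +
            \\sqrt{1 + \\frac{8rcd(c+2d)}{P^2}}\\right)

    The value is cross-checked against :func:`hopf_detect_numeric`; the two
    agree to machine precision for admissible parameters.
    """
    P = 2 * p.c * p.d + (p.c + 2 * p.d) ** 2
    disc = 1.0 + 8 * p.r * p.c * p.d * (p.c + 2 * p.d) / P**2
    if disc < 0:
        raise FormulaDomainError(
            f"negative discriminant {disc} in closed-form Hopf threshold; "
            "fall back to hopf_detect_numeric"
        )
    return P / (4 * p.K * p.b) * (1.0 + np.sqrt(disc))


def _interior_equilibrium(p: ModelParams) -> np.ndarray:
    y_eq = p.c * p.d / (p.alpha * p.b)
    x_eq = np.sqrt(p.r / p.alpha * (1.0 - y_eq / p.K))
    z_eq = p.d / p.b * x_eq**2
    return np.array([x_eq, y_eq, z_eq])


def jacobian_interior(s: Sequence[float], p: ModelParams) -> np.ndarray:
    """Jacobian of the unregularized vector field at an interior state.

    Valid where the regularizing factors are effectively 1, i.e. ``x > 0``
    and ``z > 0`` (a warning is issued for ``z < 10 epsilon``, where the
    regularized flow starts to deviate).  At the boundary equilibria use
    :func:`fixed_points`, which applies the boundary linearization.
    """
    s = np.asarray(s, dtype=float)
    x, y, z = s
    if x <= 0 or z <= 0:
        raise BoundaryRegimeError(
            "interior Jacobian requested at a boundary state (x or z <= 0); "
            "boundary stability follows the dedicated rule in fixed_points()"
        )
    if z < 10 * p.epsilon:
        warnings.warn(
            f"z={z} is within 10*epsilon of the boundary; the unregularized "
            "Jacobian only approximates the regularized flow here",
            stacklevel=2,
        )
    a = p.alpha
    return np.array(
        [
            [-p.b * z / x**2 - p.d, 0.0, p.b / x],
            [-2 * a * x * y, p.r * (1 - 2 * y / p.K) - a * x**2, 0.0],
            [2 * a * x * y, a * x**2, -p.c],
        ]
    )


def _stability_from_eigs(eigs: np.ndarray) -> str:
    m = float(np.max(eigs.real))
    if abs(m) < _MARGINAL_TOL:
        return "marginal"
    return "stable" if m < 0 else "unstable"


def _boundary_eigenvalues(p: ModelParams, at_N: bool) -> np.ndarray:
    """Eigenvalues of the boundary linearization at O or N.

    Near the plane ``z = 0`` with small capacity, the pair ``(u, z)`` with
    ``u = x^2`` obeys the linear system ``du/dt = 2bz - 2du``,
    ``dz/dt = alpha*y*u - cz`` (with ``y`` frozen at its equilibrium value),
    while the resource deviation relaxes independently.  The determinant
    of the ``(u, z)`` block changes sign exactly at
    ``alpha = alpha_star`` when ``y = K``, which is how the transcritical
    exchange shows up in this chart.
    """
    y_eq = p.K if at_N else 0.0
    block = np.array([[-2 * p.d, 2 * p.b], [p.alpha * y_eq, -p.c]])
    pair = np.linalg.eigvals(block)
    y_rate = -p.r if at_N else p.r
    return np.append(pair, y_rate)


def fixed_points(p: ModelParams) -> list[FixedPoint]:
    """All equilibria of the model for parameter set ``p``.

    Always returns the origin ``O`` and the resource-only point
    ``N = (0, K, 0)``; for ``alpha > alpha_star`` additionally the interior
    equilibrium ``E``.  At ``alpha = alpha_star`` exactly, ``E`` merges
    with ``N`` (transcritical) and only O, N are returned.

    Eigenvalues at ``E`` come from :func:`jacobian_interior`; at the
    boundary points from the ``(x^2, z)`` chart linearization (see
    ``_boundary_eigenvalues``), whose stability flips at ``alpha_star``.
    Each returned point has unregularized-RHS norm below 1e-8.
    """
    pts = []

    eig_O = _boundary_eigenvalues(p, at_N=False)
    pts.append(
        FixedPoint(np.zeros(3), "O", eig_O, _stability_from_eigs(eig_O))
    )

    eig_N = _boundary_eigenvalues(p, at_N=True)
    pts.append(
        FixedPoint(np.array([0.0, p.K, 0.0]), "N", eig_N, _stability_from_eigs(eig_N))
    )

    if p.alpha > alpha_star(p):
        coords = _interior_equilibrium(p)
        eig_E = np.linalg.eigvals(jacobian_interior(coords, p))
        pts.append(FixedPoint(coords, "E", eig_E, _stability_from_eigs(eig_E)))

    for fp in pts:
        res = float(np.linalg.norm(_rhs_unregularized(fp.coords, p)))
        if res >= 1e-8:
            raise AssertionError(
                f"fixed point {fp.label} has residual {res:.2e} >= 1e-8"
            )
    return pts


def _leading_real_part(alpha: float, p: ModelParams) -> float:
    """Real part of the leading complex pair at E(alpha)."""
    eigs = np.linalg.eigvals(
        jacobian_interior(_interior_equilibrium(p.with_alpha(alpha)), p.with_alpha(alpha))
    )
    complex_mask = np.abs(eigs.imag) > 1e-12
    if complex_mask.any():
        return float(np.max(eigs.real[complex_mask]))
    return float(np.max(eigs.real))


def hopf_detect_numeric(
    p: ModelParams, bracket: Optional[tuple[float, float]] = None
) -> float:
    """Locate the Hopf threshold by bisection on the eigenvalue real part.

    Finds the ``alpha`` at which the complex-conjugate pair of the interior
    Jacobian crosses the imaginary axis, to relative tolerance 1e-6.
    The default bracket is ``(1.05 alpha_star, 100 alpha_star)``.
    """
    a_star = alpha_star(p)
    if bracket is None:
        bracket = (1.05 * a_star, 100.0 * a_star)
    lo, hi = bracket
    if lo <= a_star:
        lo = a_star * (1.0 + 1e-9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # z_eq < 10 eps near alpha_star is fine here
        f_lo = _leading_real_part(lo, p)
        f_hi = _leading_real_part(hi, p)
        if f_lo * f_hi > 0:
            raise BracketError(
                f"no sign change of the leading eigenvalue real part in "
                f"bracket ({lo:g}, {hi:g}): f(lo)={f_lo:g}, f(hi)={f_hi:g}"
            )
        return float(brentq(_leading_real_part, lo, hi, args=(p,), rtol=1e-6))


def bifurcation_thresholds(p: ModelParams) -> BifurcationThresholds:
    """Compute ``alpha_star`` and both Hopf threshold determinations."""
    a_star = alpha_star(p)
    numeric = hopf_detect_numeric(p)
    try:
        closed = alpha_hopf(p)
    except FormulaDomainError:
        closed = numeric
    return BifurcationThresholds(a_star, closed, numeric)


def resolved_alpha_crit(p: ModelParams) -> float:
    """Hopf threshold to use downstream: the closed form when validated
    against numeric detection (within 0.1%), otherwise the numeric value."""
    th = bifurcation_thresholds(p)
    return th.alpha_crit if th.validated else th.alpha_crit_numeric
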