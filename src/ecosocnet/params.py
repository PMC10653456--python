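"""Model parameters for the population-resource-wealth system.

The single-society model couples a bulk capacity (population) ``x``, a
regenerative resource stock ``y`` and accumulated returns (wealth) ``z``:

.. math::

    \\dot x &= (b z / (x + \\epsilon) - d x)\\,(1 - e^{-z/\\epsilon}) \\\\
    \\dot y &= r y (1 - y/K) - \\alpha x^2 y \\\\
    \\dot z &= \\alpha x^2 y - c z

All rates are per year.  The regularization ``epsilon`` only smooths the
vector field near the origin; the bifurcation analysis is carried out on
the unregularized field (``epsilon -> 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace


#: Typical parameter values for the model.
DEFAULTS = {
    "b": 2.0,        # capacity growth rate (per year)
    "d": 0.05,       # capacity decay rate (per year)
    "r": 0.05,       # resource regeneration rate (per year)
    "K": 100.0,      # maximum resource level
    "alpha": 2.5e-5,  # extraction rate (per capacity^2 per year)
    "c": 0.05,       # returns decay rate (per year)
    "epsilon": 0.01,  # regularization parameter (dimensionless)
}


@dataclass(frozen=True)
class ModelParams:
    """The seven constants of the single-society model.

    Attributes
    ----------
    b, d : float
        Capacity growth and decay rates (per year).
    r, K : float
        Resource regeneration rate (per year) and carrying capacity.
    alpha : float
        Extraction rate (per capacity^2 per year); the bifurcation
        parameter of the model.
    c : float
        Returns decay rate (per year).
    epsilon : float
        Numerical regularization; must be small and positive.
    """

    b: float = DEFAULTS["b"]
    d: float = DEFAULTS["d"]
    r: float = DEFAULTS["r"]
    K: float = DEFAULTS["K"]
    alpha: float = DEFAULTS["alpha"]
    c: float = DEFAULTS["c"]
    epsilon: float = DEFAULTS["epsilon"]

    def __post_init__(self) -> None:
        for name in ("b", "d", "r", "K", "alpha", "c", "epsilon"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        if self.epsilon > 0.1:
            warnings.warn(
                f"epsilon={self.epsilon} is large for a regularization parameter "
                "(expected << 1); the unregularized bifurcation analysis may not "
                "describe the regularized flow",
                stacklevel=2,
            )

    def with_alpha(self, alpha: float) -> "ModelParams":
        """Return a copy with a different extraction rate."""
        return replace(self, alpha=alpha)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{**DEFAULTS, **d})
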