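"""Exception types raised across the package."""


class EcosocnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(EcosocnetError):
    """A state vector contains non-finite or inadmissible components."""


class ModelViolationError(EcosocnetError):
    """Integration drove a state component below the admissible domain.

    Components may transiently undershoot zero at machine level (they are
    clamped back), but a drop below -1e-9 signals a genuine model or
    step-size problem rather than roundoff.
    """


class IntegrationError(EcosocnetError):
    """The integrator produced a non-finite state (blow-up)."""


class BoundaryRegimeError(EcosocnetError):
    """The interior Jacobian was requested at a boundary fixed point.

    Stability of the boundary equilibria (the origin and the resource-only
    point) is governed by a dedicated boundary linearization, not by the
    interior Jacobian; see :func:`ecosocnet.model.fixed_points`.
    """


class FormulaDomainError(EcosocnetError):
    """The closed-form Hopf threshold is undefined for these parameters."""


class BracketError(EcosocnetError):
    """A bisection bracket does not contain exactly one sign change."""


class ConfigError(EcosocnetError):
    """A configuration file is missing, malformed, or fails validation."""
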