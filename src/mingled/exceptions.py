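"""Exception hierarchy."""


class MingledError(Exception):
    """Base class for package errors."""


class ConfigurationError(MingledError):
    """Missing or inconsistent configuration (names, dimensions, constants)."""


class DomainError(MingledError):
    """Input outside the mathematical domain (negative pools, bad spans)."""


class IntegrationError(MingledError):
    """ODE solver failure."""


class SteadyStateError(MingledError):
    """No steady state found by any solution route."""


class EstimationError(MingledError):
    """Optimizer failure during initialization or step estimation."""


class EstimationQualityError(MingledError):
    """Too many failed Monte-Carlo iterations in an estimation run."""


class ValidationError(MingledError):
    """Dataset schema or invariant violation."""
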