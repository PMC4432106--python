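"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A model, design, or scenario configuration violates an invariant."""


class InfeasibleDesignError(ConfigurationError):
    """A sampling design cannot be realized (e.g. more replicates per
    time point than animals)."""


class InputError(ValueError):
    """Invalid data passed to a computational routine."""


class InsufficientDataError(InputError):
    """Too few observations for the requested estimate."""


class EstimationError(RuntimeError):
    """A numerical routine (ODE solve, quadrature, optimizer) failed."""
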