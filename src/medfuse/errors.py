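"""Exception types shared across the package."""


class MedfuseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MedfuseError, ValueError):
    """An input violated a documented contract (shape, range, parameter)."""


class RegistrationError(ValidationError):
    """Two images that must be co-registered have different shapes."""


class SolverError(MedfuseError, RuntimeError):
    """The primal-dual iteration produced a non-finite iterate."""
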