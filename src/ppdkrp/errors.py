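"""Exception types shared across the package."""


class PPDKError(Exception):
    """Base class for all model errors."""


class DomainError(PPDKError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class InfeasibleError(PPDKError):
    """The requested steady state does not exist (e.g. Vk >= Vp0)."""


class SolverError(PPDKError):
    """A numerical solve failed to converge; carries diagnostics."""

    def __init__(self, message: str, residual=None):
        super().__init__(message)
        self.residual = residual


class ReducibleChainError(PPDKError):
    """The master-equation chain is not a single communicating class."""


class DegenerateWalkError(PPDKError, ValueError):
    """Random-walk probability p in {0, 1}: the walk is deterministic."""


class ConfigError(PPDKError, ValueError):
    """Malformed configuration file or unknown key."""
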