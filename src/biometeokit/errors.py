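"""Exception hierarchy shared by all engines."""


class BiometeoError(Exception):
    """Base class for all package errors."""


class DomainError(BiometeoError, ValueError):
    """An input violates a documented physical/numeric bound."""


class UsageError(BiometeoError, ValueError):
    """The call signature was used incorrectly (wrong argument combination)."""


class ComputationalError(BiometeoError, RuntimeError):
    """An iterative solver failed to converge or left its bracket.

    Carries optional diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}
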