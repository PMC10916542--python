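"""Exception types shared across the package."""


class ConsortiaError(Exception):
    """Base class for all package-specific errors."""


class GEMParseError(ConsortiaError):
    """A model file could not be read or failed schema checks."""


class ModelValidationError(ConsortiaError):
    """A model violates a structural invariant (named in the message)."""


class EditError(ConsortiaError):
    """A knockout/addition/bound edit referenced an unknown or colliding id."""


class AssemblyError(ConsortiaError):
    """Community assembly preconditions were not met."""


class SolverError(ConsortiaError):
    """The LP backend failed; the solver message is preserved."""
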