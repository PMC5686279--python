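"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model parameter violates its physical constraints."""


class InputError(ValueError):
    """Malformed user input (grids, tables, configuration)."""


class SchemaError(InputError):
    """A dataset or configuration file violates the declared schema."""


class SolverError(RuntimeError):
    """Numerical integration failed; carries the offending context."""
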