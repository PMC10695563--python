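"""Exception types shared across the package.

The CLI maps these onto distinct exit codes (schema errors → 2,
degenerate-input errors → 3) so batch pipelines can tell malformed files
apart from analyses that cannot be computed on the given data.
"""


class IncertaError(Exception):
    """Base class for package errors."""


class SchemaError(IncertaError):
    """A file or table violates the declared schema (missing column,
    non-monotone timestamps, unknown identifier...)."""


class DegenerateInputError(IncertaError):
    """The input is structurally valid but the requested quantity is
    undefined on it (zero variance, empty event set, all-masked trace...)."""
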