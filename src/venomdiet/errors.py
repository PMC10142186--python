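"""Exception types shared across the package."""


class VenomdietError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(VenomdietError, ValueError):
    """An input file does not have the expected structure (missing columns,
    unparseable tree, unknown enum value)."""


class ValidationError(VenomdietError, ValueError):
    """Structurally valid input that violates a semantic constraint
    (negative abundance, duplicate toxin family, conflicting diet values)."""
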