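"""Exception hierarchy for molarmorph."""


class MolarmorphError(Exception):
    """Base class for all package errors."""


class ParseError(MolarmorphError):
    """A landmark or classifier file could not be parsed."""


class SchemaError(MolarmorphError):
    """Configurations disagree with the landmark schema."""


class ValidationError(MolarmorphError):
    """Classifier or metadata values outside the allowed vocabulary."""


class DegenerateConfigurationError(MolarmorphError):
    """A landmark configuration is degenerate (coincident or collinear)."""


class DesignError(MolarmorphError):
    """A statistical design is incomplete, unbalanced, or singular."""
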