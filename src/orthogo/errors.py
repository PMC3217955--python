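"""Exception hierarchy shared across the package."""


class OrthogoError(Exception):
    """Base class for all package-specific errors."""


class UsageError(OrthogoError, ValueError):
    """A caller supplied arguments that cannot be acted on."""


class ValidationError(OrthogoError, ValueError):
    """Input data violates a structural invariant."""


class ParseError(OrthogoError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class UnknownTermError(OrthogoError, KeyError):
    """A GO term identifier is absent from the ontology."""


class UnknownProteinError(OrthogoError, KeyError):
    """A similarity hit references a protein missing from every proteome."""
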