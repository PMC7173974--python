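"""Exception hierarchy shared across the package."""


class VncAtlasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VncAtlasError):
    """A file is missing or not in the expected on-disk format."""


class IntegrityError(VncAtlasError):
    """Files parse individually but are mutually inconsistent
    (dimension mismatches, duplicate identifiers, non-integer counts)."""


class VocabularyError(VncAtlasError):
    """A configuration table uses a role tag outside the closed vocabulary."""


class ValidationError(VncAtlasError):
    """A parameter or specification object violates its invariants."""
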