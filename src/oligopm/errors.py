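"""Exception hierarchy shared across the package."""


class OligoPMError(Exception):
    """Base class for all package errors."""


class PeptideParseError(OligoPMError):
    """A peptide display name could not be parsed."""


class ValidationError(OligoPMError):
    """An input violated a documented precondition."""


class ConfigurationError(OligoPMError):
    """A classification scheme or run configuration is inconsistent."""


class MissingControlError(OligoPMError):
    """A strain/plate lacks its negative or L-glutamine control well."""


class DegeneratePlateError(OligoPMError):
    """The positive control did not exceed the negative control on a plate."""


class CoordinateError(OligoPMError):
    """Gene coordinates fall outside the supplied contig."""
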