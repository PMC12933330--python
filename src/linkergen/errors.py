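"""Exception hierarchy.

All package-specific errors derive from :class:`LinkergenError` so callers can
catch the whole family; most also derive from a builtin (``ValueError`` /
``RuntimeError``) so they behave sensibly in generic code.
"""


class LinkergenError(Exception):
    """Base class for all errors raised by linkergen."""


class InvalidSmiles(LinkergenError, ValueError):
    """A SMILES string could not be parsed into a molecule."""


class AttachmentCountError(LinkergenError, ValueError):
    """A fragment carries the wrong number of attachment markers."""


class AssemblyError(LinkergenError, ValueError):
    """Joining linker and ligands produced a chemically invalid molecule."""


class FormatError(LinkergenError, ValueError):
    """A raw data field (e.g. a permeability entry) is malformed."""


class ConfigError(LinkergenError, ValueError):
    """A configuration value or reference dataset is missing or inconsistent."""


class TokenError(LinkergenError, ValueError):
    """A SMILES string contains symbols outside the token vocabulary."""


class FitError(LinkergenError, RuntimeError):
    """Model fitting failed (carries the cross-validation fold if relevant)."""

    def __init__(self, message: str, fold: int | None = None):
        super().__init__(message)
        self.fold = fold
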