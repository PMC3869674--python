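"""Exception hierarchy shared across the package.

All user-facing validation failures derive from :class:`ResvarError` so the
command-line layer can catch one type, print the message and exit nonzero.
"""


class ResvarError(Exception):
    """Base class for all validation and input errors raised by resvar."""


class InputError(ResvarError):
    """Malformed user input (bad codon, bad mutation token, bad file)."""


class CoordinateError(ResvarError):
    """A protein position that cannot be mapped to an alignment column."""


class ReferenceMismatchError(ResvarError):
    """The reference sequence disagrees with a mutation's stated wild type."""
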