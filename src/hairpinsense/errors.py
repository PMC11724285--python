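"""Exception hierarchy.

Everything user-facing derives from :class:`HairpinError`; the CLI maps
these to exit code 2 (validation) and any other exception to exit code 1.
"""


class HairpinError(Exception):
    """Base class for all validation and design errors raised by this package."""


class InputError(HairpinError):
    """Malformed user input (bad alphabet, missing column, bad coordinates)."""


class AlphabetError(InputError):
    """A residue outside the declared nucleotide alphabet."""

    def __init__(self, residue: str, position: int, alphabet: str):
        self.residue = residue
        self.position = position
        self.alphabet = alphabet
        super().__init__(
            f"character {residue!r} at position {position} is not a valid "
            f"{alphabet.upper()} residue"
        )


class DesignError(HairpinError):
    """A construct cannot be built under the requested geometry."""


class SiteRejectedError(DesignError):
    """A target window is unusable (e.g. the arm would introduce an in-frame stop)."""


class AssemblyError(DesignError):
    """Reporter cassette assembly failed the frame/stop audit."""


class SchemaError(InputError):
    """A tabular input is missing a required column."""
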