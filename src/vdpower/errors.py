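"""Exception hierarchy shared across the package.

Format errors (malformed input tables) and validity errors (a statistic
requested under conditions where it is undefined) are kept distinct so the
command-line layer can map them to different exit codes.
"""


class VDPError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VDPError):
    """A genotype table could not be parsed or failed validation."""


class ValidityError(VDPError):
    """A statistic was requested under conditions where it is not defined."""


class UndefinedComparisonError(ValidityError):
    """Two samples share no called locus, so their difference is undefined."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        shown = ", ".join(f"({i}, {j})" for i, j in self.pairs[:10])
        more = "" if len(self.pairs) <= 10 else f" and {len(self.pairs) - 10} more"
        super().__init__(
            f"{len(self.pairs)} sample pair(s) share no called locus: {shown}{more}. "
            "Set undefined_pairs='same' or 'different' to resolve them by policy."
        )


class CapacityError(ValidityError):
    """A simulation design asks for more distinct varieties than representable."""
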