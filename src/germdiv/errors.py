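"""Exception types shared across the package."""


class GermdivError(Exception):
    """Base class for all package errors."""


class ValidationError(GermdivError):
    """Raised when an input violates a data-type contract."""


class SaturationError(GermdivError):
    """Raised when a pairwise mismatch proportion is at or beyond the
    Jukes-Cantor saturation boundary (p >= 3/4), where the model distance
    is undefined."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        msg = ", ".join(f"{a}~{b}" for a, b in self.pairs)
        super().__init__(f"saturated sequence pair(s): {msg}")


class NoComparableSitesError(GermdivError):
    """Raised when a sequence pair shares no site at which both residues
    are determined."""
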