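"""Exception hierarchy for pdzflex.

Every error raised by the library derives from :class:`PdzflexError` so that
callers (and the CLI) can catch analysis failures without masking genuine
bugs such as ``TypeError``.
"""


class PdzflexError(Exception):
    """Base class for all pdzflex errors."""


class ParseError(PdzflexError):
    """A structure or table file could not be parsed."""


class EmptyStructureError(PdzflexError):
    """A parsed structure contains no C-alpha atoms."""


class MissingChainError(PdzflexError):
    """The requested chain is absent from the structure."""


class EmptyDomainError(PdzflexError):
    """The requested residue range contains no C-alpha-bearing residues."""


class InsufficientOverlapError(PdzflexError):
    """Ensemble members share fewer than three common residues."""


class DegenerateFitError(PdzflexError):
    """The superposition fit set is too small or collinear."""


class InvalidDistanceMatrixError(PdzflexError):
    """A pairwise matrix is not a valid symmetric non-negative distance matrix."""


class EmptyProfileError(PdzflexError):
    """All rows of an intensity table were excluded; no profile can be built."""


class MissingBFactorError(PdzflexError):
    """An ensemble member lacks a B-factor at a common residue."""


class MismatchedResiduesError(PdzflexError):
    """Per-replicate profiles do not share an identical residue set."""


class EmptySelectionError(PdzflexError):
    """A frame/time selection matched no frames."""


class ConfigError(PdzflexError):
    """Invalid run configuration (bad threshold, unresolvable preset, ...)."""
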