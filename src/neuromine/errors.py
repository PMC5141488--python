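"""Exception hierarchy shared across the package."""


class NeuromineError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(NeuromineError):
    """Structurally malformed FASTA input (reports the offending line)."""


class SequenceAlphabetError(NeuromineError):
    """A sequence contains characters outside the declared alphabet."""


class CatalogError(NeuromineError):
    """Malformed motif-catalog file or pattern."""


class ContractError(NeuromineError):
    """A caller violated a documented precondition (e.g. overlapping sites)."""


class AssemblyError(NeuromineError):
    """Mutually inconsistent inputs while assembling an architecture."""


class GenerationError(NeuromineError):
    """The synthetic generator exhausted its rejection-sampling budget."""
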