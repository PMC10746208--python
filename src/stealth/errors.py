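"""Exception hierarchy for the stealth package."""


class StealthError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(StealthError):
    """Sequence contains characters outside the permitted alphabet."""


class FastaParseError(StealthError):
    """Malformed or empty FASTA input."""


class CdsValidationError(StealthError):
    """Coding sequence violates frame/stop-codon invariants."""


class MotifTableError(StealthError):
    """Malformed motif blacklist file."""


class EmptyBlacklistError(MotifTableError):
    """A motif blacklist with zero motifs (recoding would be a no-op)."""


class ContigTooShortError(StealthError):
    """Contig shorter than the requested word length."""


class InestimableMotifError(StealthError):
    """Markov expectation undefined (middle-word count is zero)."""


class DegenerateVarianceError(StealthError):
    """Binomial-approximation variance is zero or negative (E <= 0 or E >= N)."""


class ConfigError(StealthError):
    """Invalid scan/simulation configuration."""


class UnrealizableEmbeddingError(StealthError):
    """A requested motif embedding cannot produce a valid CDS."""
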