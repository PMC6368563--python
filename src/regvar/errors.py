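"""Exception hierarchy shared across the package."""


class RegvarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RegvarError):
    """A file does not follow its declared format.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(RegvarError):
    """Logically inconsistent input (e.g. one SNP id at two coordinates)."""


class ConfigurationError(RegvarError):
    """Invalid or incomplete configuration."""


class InvalidBackgroundError(RegvarError):
    """Zero-probability background base makes log-odds undefined."""


class ResolutionError(RegvarError):
    """The integer score grid would overflow; use a smaller scale."""


class ReferenceMismatchError(RegvarError):
    """Genome base at a SNP position differs from the declared ref allele."""


class BoundaryError(RegvarError):
    """A window or flank extends past the end of a contig."""


class NoScorableWindowError(RegvarError):
    """Every candidate window contains an ambiguous base."""


class InfeasibleMatchingError(RegvarError):
    """A MAF bin has fewer pool candidates than template SNPs require."""

    def __init__(self, message: str, bins: list | None = None):
        self.bins = bins or []
        super().__init__(message)


class EmptyGeneSetError(RegvarError):
    """Gene set and expression matrix do not intersect."""


class PlacementError(RegvarError):
    """Synthetic sites cannot be placed under the stated constraints."""
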