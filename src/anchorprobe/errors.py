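"""Exception hierarchy shared across the package.

Plain ``ValueError`` is raised for malformed scalar inputs (negative
signal, bad nucleotide, probability outside [0, 1]); the classes here
mark domain-level failures a pipeline driver may want to catch
individually.
"""


class AnchorProbeError(Exception):
    """Base class for all domain errors raised by this package."""


class FormatError(AnchorProbeError):
    """A tabular or sequence input file violates its documented layout."""


class ConsistencyError(AnchorProbeError):
    """Cross-file referential integrity is broken (e.g. a sample in the
    expression matrix is missing from the sample table)."""


class DegenerateGroupError(AnchorProbeError):
    """A replicate group has zero variance, so the heteroscedastic ANOVA
    is undefined for it."""


class CoverageError(AnchorProbeError):
    """A probeset covers too small a fraction of its probes on the
    transcript to anchor a riboprobe template."""


class TemplateLengthError(AnchorProbeError):
    """The transcript is too short to host a template of the requested
    minimum length."""


class PrimerDesignError(AnchorProbeError):
    """No primer pair satisfies the design constraints; the message
    names the binding constraint."""
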