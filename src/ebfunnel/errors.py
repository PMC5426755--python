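"""Exception hierarchy shared by all pipeline stages.

Two broad families matter to callers: :class:`FormatError` for malformed
input files (CLI exit code 2) and :class:`ConsistencyError` for inputs that
parse but contradict each other (also exit code 2).  Everything derives from
:class:`EbfunnelError` so the CLI can catch one base class.
"""


class EbfunnelError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EbfunnelError):
    """A file does not conform to the supported dialect of its format."""


class GenotypeParseError(FormatError):
    """A GT token is not a diploid genotype over the documented grammar."""


class PloidyError(FormatError):
    """A GT token is haploid or polyploid; only diploid calls are supported."""


class ConsistencyError(EbfunnelError):
    """Inputs parse individually but contradict each other (e.g. a sample
    genotyped at a site but absent from the sample list)."""


class ModelError(EbfunnelError):
    """A gene model violates a structural invariant (e.g. CDS length not a
    multiple of three)."""


class DataIntegrityError(EbfunnelError):
    """A variant's stated reference allele disagrees with the genome FASTA."""


class DomainError(EbfunnelError, ValueError):
    """An argument is outside an operation's mathematical domain."""


class LayoutError(EbfunnelError):
    """A simulation configuration leaves no room for the requested content."""
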