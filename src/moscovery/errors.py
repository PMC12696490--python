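"""Exception hierarchy for moscovery."""


class MoscoveryError(Exception):
    """Base class for all moscovery errors."""


class CoordinateError(MoscoveryError):
    """An interval extends beyond its reference contig."""


class MissingContigError(MoscoveryError):
    """A contig referenced by an interval is absent from the reference."""


class PanelMismatchError(MoscoveryError):
    """The capture kit contains no exons of the requested gene panel."""


class CapacityError(MoscoveryError):
    """Not enough autosomal candidates to match without replacement."""


class CohortSizeError(MoscoveryError):
    """A cohort is too small for a stable median/quantile estimate."""


class NormalizationError(MoscoveryError):
    """No usable chrY exon survived normalization for a sample."""


class KitMismatchError(MoscoveryError):
    """A calibration from one capture kit was applied to another kit."""


class ParseError(MoscoveryError):
    """A malformed row in a tabular input file."""


class ContigError(MoscoveryError):
    """Alignment file and panel disagree on contig names."""


class ValidationError(MoscoveryError, ValueError):
    """An argument is outside its valid domain."""
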