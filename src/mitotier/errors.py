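"""Exception hierarchy shared across the package."""


class MitotierError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(MitotierError):
    """A 1-based position falls outside [1, L]."""


class ReferenceMismatchError(MitotierError):
    """A variant's declared reference allele disagrees with the genome."""


class UnsupportedAlleleError(MitotierError):
    """An allele (or a codon base) is ambiguous or not a plain nucleotide."""


class LocusTypeError(MitotierError):
    """An operation was applied to a locus of the wrong type."""


class ConfigurationError(MitotierError):
    """Invalid run configuration (empty locus-type set, bad config file...)."""


class DomainError(MitotierError):
    """A numeric input lies outside its mathematical domain (e.g. AF > 1)."""


class UndefinedFrequencyError(MitotierError):
    """Allele frequency requested over an empty stratum/denominator."""


class InsufficientDataError(MitotierError):
    """Fewer called genomes than the statistic requires."""


class DegenerateWeightsError(MitotierError):
    """All criterion weights are zero; normalization is undefined."""


class ThresholdEstimationError(MitotierError):
    """No variant qualifies for empirical allele-frequency threshold estimation."""


class SimulationSpecError(MitotierError):
    """A synthetic-cohort specification is internally inconsistent."""
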