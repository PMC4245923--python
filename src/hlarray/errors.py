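"""Exception hierarchy for the hlarray package."""


class HlarrayError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(HlarrayError):
    """A sequence is empty or contains characters outside {A,C,G,T}."""


class CatalogError(HlarrayError):
    """Malformed allele catalog (duplicate names, unparseable names, missing alleles)."""


class PositionError(HlarrayError):
    """A probe anchor lies outside the feasible range of its source sequence."""


class DegenerateArrayError(HlarrayError):
    """Raw signal vector admits no valid normalization (e.g. constant values)."""


class SignalInputError(HlarrayError):
    """Raw signals violate input requirements (non-positive values, too few probes)."""


class ConfigError(HlarrayError):
    """Invalid configuration value (window, fractions, scenario mix...)."""


class GenotypeError(HlarrayError):
    """Illegal genotype shape or comparison of identical genotypes."""


class IncompatibilityError(HlarrayError):
    """Knowledgebase and probe set fingerprints do not match."""


class ComparisonError(HlarrayError):
    """Two typing results cannot be compared (different locus sets)."""
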