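"""Exception hierarchy for the SSNS-GRS pipeline."""


class SsnsGrsError(Exception):
    """Base class for all pipeline errors."""


class DomainError(SsnsGrsError):
    """A numeric parameter is outside its mathematical domain."""


class MissingGenotypeError(SsnsGrsError):
    """A scored genotype has a missing locus under the strict policy."""


class UndefinedScoreError(SsnsGrsError):
    """All loci missing: no denominator under the rescale policy."""


class ParseError(SsnsGrsError):
    """A genotype file could not be parsed."""


class ConfigurationError(SsnsGrsError):
    """Required QC annotations absent while the corresponding filter is on."""


class MissingLocusError(SsnsGrsError):
    """A model locus is absent from the data and no acceptable proxy exists."""


class AmbiguousStrandError(SsnsGrsError):
    """An A/T or C/G site cannot be oriented under the reject policy."""


class UndefinedLdError(SsnsGrsError):
    """LD r-squared undefined (monomorphic or too few informative pairs)."""


class NoProxyError(SsnsGrsError):
    """No candidate variant exceeds the proxy r-squared floor."""


class InputError(SsnsGrsError):
    """Structurally invalid input (empty group, too few samples, ...)."""


class LabelError(SsnsGrsError):
    """Unknown or missing cohort label."""


class ProjectionError(SsnsGrsError):
    """Marker overlap between study data and PCA model below the minimum."""


class DimensionError(SsnsGrsError):
    """Requested more principal components than the data's rank."""
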