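"""Exception hierarchy shared across the toolkit.

``GenotaxError`` is the base for every data-level failure; the CLI maps it
to exit code 2 so scripted pipelines can distinguish bad data from bad usage.
"""


class GenotaxError(Exception):
    """Base class for all data/format/configuration errors."""


class FormatError(GenotaxError):
    """Malformed input file (empty FASTA, duplicate ids, bad coordinates...)."""


class ReferenceError_(GenotaxError):
    """A record refers to an unknown replicon/genome/taxon."""


class ConfigError(GenotaxError):
    """Invalid simulation or analysis configuration."""


class UndefinedValueError(GenotaxError):
    """A statistic is undefined for this input (all-N genome, no HSPs,
    zero orthologous fragments, saturated K2 distance...)."""


class MarkerError(GenotaxError):
    """A required single-copy marker gene is missing or duplicated."""
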