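"""Exception hierarchy for the chemogram pipeline."""


class ChemogramError(Exception):
    """Base class for all pipeline errors."""


class ParseError(ChemogramError):
    """A raw input file could not be parsed; the message names the offending row."""


class ConfigError(ChemogramError):
    """A configuration value is out of its valid range."""


class DataError(ChemogramError):
    """Input data violate a pipeline precondition (duplicates, missing scores, ...)."""


class NormalizationError(DataError):
    """Control wells are absent or their mean signal is not positive."""


class ScoringError(DataError):
    """A score could not be computed (e.g. drug absent from the cohort reference)."""
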