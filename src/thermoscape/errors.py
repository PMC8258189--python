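"""Exception hierarchy shared across the pipeline stages."""


class ThermoscapeError(Exception):
    """Base class for all package-specific errors."""


class DataError(ThermoscapeError):
    """Input data violates a contract (missing records, single-class labels, ...)."""


class ConfigError(ThermoscapeError):
    """A configuration mapping is missing required fields or holds invalid values."""


class SchemaError(ThermoscapeError):
    """A table is missing required columns; the message lists them."""


class TraitConsistencyError(DataError):
    """Finalized thermal traits violate ct_min < t_opt < ct_max."""


class ConsensusError(ThermoscapeError):
    """No learner cleared the validation-AUC cutoff for ensemble membership."""
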