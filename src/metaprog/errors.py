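"""Exception hierarchy for the metaprog pipeline."""


class MetaprogError(Exception):
    """Base class for all metaprog errors."""


class ConfigurationError(MetaprogError, ValueError):
    """A configuration value violates one of its invariants."""


class FormatError(MetaprogError, ValueError):
    """An on-disk file does not conform to its declared format."""


class ContractError(MetaprogError, ValueError):
    """An in-memory input violates an operation's precondition."""


class DegenerateInputError(MetaprogError, ValueError):
    """An operation would return an empty / meaningless result."""


class ScoringError(MetaprogError, ValueError):
    """A gene set cannot be scored on a given expression matrix."""
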