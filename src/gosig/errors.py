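"""Exception hierarchy for gosig.

All gosig-raised errors derive from :class:`GosigError` so callers can
catch framework failures without masking programming errors.
"""


class GosigError(Exception):
    """Base class for all gosig errors."""


class ParseError(GosigError):
    """A delimited input file could not be parsed (names file/line/column)."""


class IntegrityError(GosigError):
    """An input violates a structural invariant (duplicates, cycles, ...)."""


class SchemaError(GosigError):
    """A mandatory column or field is missing from an input table."""


class StratificationError(GosigError):
    """A cross-validation fold would contain a single class."""


class ContractError(GosigError):
    """An operation was invoked outside its stated precondition."""


class IncompleteEnsembleError(GosigError):
    """Postprocess was asked to run on an ensemble the experiment phase
    never completed."""
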