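"""Exception hierarchy shared across the package.

All errors derive from :class:`KgfuseError` so callers (notably the CLI)
can distinguish package failures from programming errors.
"""


class KgfuseError(Exception):
    """Base class for all package errors."""


class ParseError(KgfuseError):
    """A text input file violates its dialect (names the offending line)."""


class FormatError(KgfuseError):
    """Structured input is internally inconsistent (e.g. ragged feature vectors)."""


class ConfigError(KgfuseError):
    """Invalid hyper-parameter or configuration value."""


class ShapeError(KgfuseError):
    """Array arguments have incompatible shapes."""


class VocabularyError(KgfuseError):
    """An entity, relation, or category identifier is not in the vocabulary."""


class ContractError(KgfuseError):
    """A caller violated a documented precondition."""


class SamplingError(KgfuseError):
    """Negative sampling could not find a valid corruption within the retry budget."""


class TrainingError(KgfuseError):
    """Optimization produced a non-finite loss."""


class GenerationError(KgfuseError):
    """The synthetic-graph generator could not satisfy its constraints."""


class DegenerateHyperplaneError(KgfuseError):
    """A zero vector cannot define a hyperplane normal."""
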