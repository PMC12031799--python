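"""Exception hierarchy.

Everything raised on purpose derives from :class:`VurScoreError` so callers
(and the CLI exit-code mapping) can distinguish schema problems, statistical
degeneracies and configuration mistakes.
"""


class VurScoreError(Exception):
    """Base class for all package errors."""


class SchemaError(VurScoreError):
    """CSV header/value problems, or a variable name unknown to the schema."""


class CohortValidationError(VurScoreError):
    """A record violates a cohort invariant under strict validation."""


class FixtureIntegrityError(VurScoreError):
    """Packaged reference counts fail their internal consistency checks."""


class ParameterError(VurScoreError):
    """Invalid or infeasible parameter values (generator, weights, config)."""


class DegenerateTableError(VurScoreError):
    """A 2x2 table has a zero margin or no observations at all."""


class UndefinedStatisticError(VurScoreError):
    """A requested statistic is undefined for the given counts (zero cell OR
    with the correction disabled, ROC with an empty outcome class, ...)."""


class ModelDegenerateError(VurScoreError):
    """Variable selection produced an empty model."""


class BandConstructionError(VurScoreError):
    """No threshold satisfies the risk-band construction rules."""


class PipelineError(VurScoreError):
    """A pipeline stage failed; the message names the stage and the cause."""
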