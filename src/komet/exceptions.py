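"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`KometError`, so callers (and the CLI) can distinguish usage and data
problems from genuine bugs.
"""


class KometError(Exception):
    """Base class for all errors raised by komet."""


class SchemaError(KometError):
    """A required column or field is missing from an input table."""


class IntegrityError(KometError):
    """Conflicting records for the same identifier."""


class LabelError(KometError):
    """An interaction label outside {+1, -1}."""


class StructureError(KometError):
    """A molecular structure (SMILES) could not be parsed."""


class ConfigurationError(KometError):
    """No usable backend / invalid run configuration."""


class AlphabetError(KometError):
    """A sequence letter has no substitution score."""


class DegenerateInputError(KometError):
    """Mathematically undefined input (e.g. Jaccard of two empty sets)."""


class DimensionError(KometError):
    """Requested feature dimension exceeds the achievable rank."""


class ShapeError(KometError):
    """Incompatible array shapes between model and features."""


class TrainingDataError(KometError):
    """Empty or single-class training data."""


class CalibrationError(KometError):
    """Probability calibration requested on degenerate scores/labels."""


class DivergenceError(KometError):
    """The optimizer produced a non-finite objective."""


class MetricError(KometError):
    """A metric is undefined for the given labels/ranks."""


class EvaluationError(KometError):
    """Cross-validation could not produce any usable fold."""


class GenerationError(KometError):
    """A synthetic-data generator could not satisfy its constraints."""


class CaseError(KometError):
    """A scaffold-hopping case references unusable entities."""
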