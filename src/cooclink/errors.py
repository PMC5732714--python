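"""Exception hierarchy for cooclink.

Every error raised by the library derives from :class:`CooclinkError` so
callers (and the CLI) can catch one base class.
"""


class CooclinkError(Exception):
    """Base class for all cooclink errors."""


class OboParseError(CooclinkError):
    """Malformed OBO stanza; message names the offending line."""


class OntologyValidationError(CooclinkError):
    """Structural violation, e.g. a cycle in the is_a graph."""


class AnnotationFormatError(CooclinkError):
    """Annotation file dialect not recognized or record invalid."""


class CorpusParseError(CooclinkError):
    """Corpus file could not be parsed in the requested format."""


class DictionaryConfigError(CooclinkError):
    """Dictionary construction produced no usable entries."""


class IntegrityError(CooclinkError):
    """A mention references a sentence or document that does not exist."""


class NotScorableError(CooclinkError):
    """Pair cannot be scored (zero co-occurrence or no annotation)."""


class DegenerateCorpusError(CooclinkError):
    """Corpus too small for the NMD denominator (M <= min doc count)."""


class InsufficientDataError(CooclinkError):
    """Too few data points for the requested statistic."""


class UndefinedCorrelationError(CooclinkError):
    """Pearson correlation undefined (zero variance in a vector)."""


class ConfigError(CooclinkError):
    """Run configuration invalid (unknown key, bad value)."""


class InputError(CooclinkError):
    """Invalid argument to an operation."""
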