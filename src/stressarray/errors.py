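"""Exception hierarchy.

User-facing errors derive from :class:`StressArrayError`; the CLI maps them to
exit code 1. :class:`ReportInvariantError` signals an internal consistency
failure (a bug trap, exit code 2), never a user mistake.
"""


class StressArrayError(Exception):
    """Base class for all errors raised by stressarray."""


class ConfigurationError(StressArrayError):
    """Invalid configuration value or combination."""


class ParseError(StressArrayError):
    """Malformed input file; the message names the offending row/line."""


class DesignError(StressArrayError):
    """Sample/condition bookkeeping problem (unknown sample, empty map, ...)."""


class ScaleEstimationError(StressArrayError):
    """glog scale cannot be estimated (e.g. all-constant channel)."""


class CorrelationError(StressArrayError):
    """Pearson correlation undefined (constant vector, too few probes)."""


class ClassificationError(StressArrayError):
    """Dependency classification impossible (no perturbed measurement, ...)."""


class EnrichmentInputError(StressArrayError):
    """Invalid enrichment input (genes outside universe, bad p, ...)."""


class ReportInvariantError(StressArrayError):
    """Internal run-report consistency violation; indicates a pipeline bug."""
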