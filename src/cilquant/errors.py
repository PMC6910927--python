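"""Exception hierarchy for the cilquant package.

All package-specific failures derive from :class:`CilQuantError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class CilQuantError(Exception):
    """Base class for all cilquant errors."""


class FormulaError(CilQuantError, ValueError):
    """Malformed or chemically impossible elemental formula."""


class ConfigurationError(CilQuantError, ValueError):
    """Invalid panel, study design, or pipeline configuration."""


class ParameterError(CilQuantError, ValueError):
    """Out-of-range algorithm parameter (window sizes, tolerances...)."""


class UsageError(CilQuantError, ValueError):
    """An operation was called with inputs that violate its contract."""


class QuantificationError(CilQuantError, ValueError):
    """Calibration or back-calculation cannot be performed."""


class ClassificationError(CilQuantError, KeyError):
    """Analyte missing from the metabolic-pathway registry."""


class FormatError(CilQuantError, ValueError):
    """Unreadable or inconsistent chromatogram / table file."""


class ReportError(CilQuantError, ValueError):
    """A comparison report cannot be assembled from the given study."""
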