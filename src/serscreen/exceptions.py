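"""Exception hierarchy for the serscreen pipeline."""


class SerscreenError(Exception):
    """Base class for all package-specific errors."""


class SynthesisError(SerscreenError, ValueError):
    """Invalid synthetic-cohort configuration or generator arguments."""


class PreprocessingError(SerscreenError, ValueError):
    """Invalid input to baseline removal, normalization or averaging."""


class StatisticsError(SerscreenError, ValueError):
    """Invalid input to peak extraction or group comparison."""


class ChemometricsError(SerscreenError, ValueError):
    """Invalid input to PLS fitting, component selection or SVM analysis."""


class ConfigError(SerscreenError, ValueError):
    """Run configuration failed validation; message names the offending key."""
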