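"""Exception types shared across the pipeline."""


class SpectrumstError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpectrumstError, ValueError):
    """A configuration value is invalid or inconsistent (bad band, factor, sizes...)."""


class ConsistencyError(SpectrumstError, ValueError):
    """Inputs that must agree (shapes, ROI labels, bands, node sets) do not."""


class DegenerateDataError(SpectrumstError, ValueError):
    """The data admit no answer (e.g. all paired differences are zero)."""


class MissingDataError(SpectrumstError, ValueError):
    """Required cells of a score table are absent.

    ``missing`` lists the absent (subject_id, band, timepoint) tuples.
    """

    def __init__(self, message: str, missing: list[tuple] | None = None):
        super().__init__(message)
        self.missing = missing or []
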