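"""Exception types shared across the package."""


class SamflowError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SamflowError):
    """An input file violates the expected tabular schema."""


class ConfigError(SamflowError):
    """A simulation or run configuration is invalid."""


class DesignError(SamflowError):
    """A contrast design is invalid (missing samples, tiny groups, overlap)."""


class AnalysisError(SamflowError):
    """An analysis step cannot proceed (degenerate input, empty result)."""
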