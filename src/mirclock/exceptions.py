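"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


class AlignmentError(ValueError):
    """Sample/feature identifiers do not line up across inputs."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge; message carries diagnostics."""
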