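"""Exception hierarchy shared across the package."""


class PosturoError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(PosturoError, ValueError):
    """Malformed input container: mismatched lengths, bad time base, etc."""


class UnloadedPlateError(PosturoError, ValueError):
    """Vertical force too close to zero to derive a center of pressure."""

    def __init__(self, index: int, fz: float, threshold: float):
        self.index = index
        self.fz = fz
        self.threshold = threshold
        super().__init__(
            f"unloaded plate: |fz|={abs(fz):.3g} N <= {threshold:g} N "
            f"at sample index {index}"
        )


class ConfigError(PosturoError, ValueError):
    """Invalid configuration value (filter cutoff, schedule, run config)."""


class MeasureError(PosturoError, ValueError):
    """Stabilometric measure requested on an unsuitable trajectory."""


class ValidationError(PosturoError, ValueError):
    """Questionnaire response fails the instrument's range or shape rules."""
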