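"""Exception hierarchy for the electromotor model."""


class ElectromotorError(Exception):
    """Base class for all package errors."""


class IntegrationError(ElectromotorError):
    """Numerical divergence during integration (names the nucleus and time)."""

    def __init__(self, nucleus: str, t: float):
        self.nucleus = nucleus
        self.t = t
        super().__init__(
            f"non-finite state in nucleus {nucleus!r} at t = {t:.3f} ms"
        )


class CalibrationError(ElectromotorError):
    """Baseline calibration could not reach the target rhythm."""

    def __init__(self, target_ipi: float, best_ipi: float, best_input: float):
        self.target_ipi = target_ipi
        self.best_ipi = best_ipi
        self.best_input = best_input
        super().__init__(
            f"calibration failed: target mean IPI {target_ipi:.1f} ms, "
            f"best achieved {best_ipi:.1f} ms (input {best_input:.4f})"
        )


class TransformError(ElectromotorError):
    """An SPI cannot be turned into a shape vector (fewer than 2 IPIs)."""


class ConfigError(ElectromotorError):
    """Configuration file violates the schema or a parameter bound."""


class GenerationError(ElectromotorError):
    """Contradictory settings passed to the synthetic target generator."""
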