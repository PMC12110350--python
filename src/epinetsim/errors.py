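"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model, network, or stimulus parameter is out of its valid range."""


class BlowUpError(RuntimeError):
    """The integrator produced a non-finite state.

    Carries the step index and simulation time at which the divergence
    was detected.
    """

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(
            f"non-finite state at step {step} (t = {time:g}); "
            "reduce dt or check parameters"
        )


class DegenerateSignalError(ValueError):
    """A signal has no oscillatory content (constant after mean removal)."""


class UndefinedCVError(ValueError):
    """Coefficient of variation requested for a zero-mean series."""
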