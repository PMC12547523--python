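"""Exception hierarchy for the kinetics pipeline."""


class ThermokinError(Exception):
    """Base class for all package errors."""


class IntegrationError(ThermokinError):
    """The kinetic ODE integrator failed (stiff blow-up or non-convergence)."""


class BoundaryPeakError(ThermokinError):
    """The DTG maximum falls on the window boundary, so no interior peak exists."""


class MassBalanceError(ThermokinError):
    """Product masses are inconsistent with the fed mass."""


class SingularDesignError(ThermokinError):
    """The regression design is singular (e.g. all heating rates identical)."""


class PipelineStageError(ThermokinError):
    """A pipeline stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
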