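"""Exception and warning types used across the package."""


class TetFluxError(Exception):
    """Base class for all tetflux errors."""


class ValidationError(TetFluxError, ValueError):
    """An input violates a domain invariant (negative level, empty subset, ...)."""


class NoFiniteSteadyStateError(TetFluxError):
    """A species has zero total removal rate, so no finite steady state exists.

    The offending species name is available as ``species``.
    """

    def __init__(self, species: str, detail: str = ""):
        self.species = species
        msg = f"no finite steady state: species {species!r} has zero total removal rate"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class DegenerateSystemError(TetFluxError):
    """The least-squares design is degenerate (e.g. an all-zero matrix)."""


class IntegrationError(TetFluxError):
    """The ODE integrator failed to produce a solution."""


class ConditioningWarning(UserWarning):
    """The assembled design matrix is rank-deficient or badly conditioned."""
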