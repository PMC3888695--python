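"""Exception hierarchy for complexwalk."""


class ComplexWalkError(Exception):
    """Base class for all package errors."""


class FormatError(ComplexWalkError):
    """A file does not have the expected tabular shape."""


class ValidationError(ComplexWalkError):
    """A value violates a documented invariant (range, sign, symmetry)."""


class ParameterError(ComplexWalkError):
    """A model or strategy parameter is outside its admissible range."""


class AssemblyError(ComplexWalkError):
    """A bipartite link references an identifier absent from its layer."""


class DiseaseLookupError(ComplexWalkError):
    """A disease identifier is not present in the relevant table."""


class ConvergenceError(ComplexWalkError):
    """The walk did not reach the tolerance within the iteration cap."""

    def __init__(self, iterations: int, final_delta: float, epsilon: float):
        self.iterations = iterations
        self.final_delta = final_delta
        self.epsilon = epsilon
        super().__init__(
            f"walk did not converge after {iterations} iterations: "
            f"|dq|={final_delta:.3e} > epsilon={epsilon:.3e}"
        )


class ScoringError(ComplexWalkError):
    """No steady-state mass reached the complex layer (query disconnected)."""


class PerturbationError(ComplexWalkError):
    """The requested edge perturbation is infeasible (e.g. graph complete)."""
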