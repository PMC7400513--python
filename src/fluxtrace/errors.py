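"""Exception hierarchy shared across the package."""


class FluxtraceError(Exception):
    """Base class for all package-specific errors."""


class ModelFormatError(FluxtraceError):
    """Model file could not be parsed in the documented dialect."""


class AtomMapError(ModelFormatError):
    """An atom mapping string is malformed or inconsistent."""


class UndeclaredMetaboliteError(ModelFormatError):
    """A reaction references a metabolite missing from the metabolite table."""


class CarbonBalanceError(ModelFormatError):
    """Mapped carbons are not conserved across a reaction."""

    def __init__(self, reaction_id: str, detail: str):
        self.reaction_id = reaction_id
        super().__init__(f"reaction {reaction_id!r}: {detail}")


class InfeasibleConstraintError(FluxtraceError):
    """Fixed flux constraints contradict the steady-state balances."""


class FluxBoundError(FluxtraceError):
    """A flux vector violates reaction bounds (e.g. irreversible < 0)."""


class UnreachableEMUError(FluxtraceError):
    """An observed fragment cannot be traced back to any labelled input."""


class EMUSingularityError(FluxtraceError):
    """An intra-layer EMU system is singular (zero-flux dilution trap)."""

    def __init__(self, size: int, emus):
        self.size = size
        self.emus = list(emus)
        super().__init__(
            f"singular EMU system at size {size}; involved EMUs: "
            + ", ".join(map(str, self.emus))
        )


class StateSpaceError(FluxtraceError):
    """Isotopomer state space exceeds the brute-force oracle limit."""


class FragmentFormulaError(FluxtraceError):
    """A fragment ion formula is inconsistent with its tracked backbone."""


class DegenerateFitError(FluxtraceError):
    """A regression or flux fit has no degrees of freedom or no valid data."""


class ConvergenceError(FluxtraceError):
    """All optimizer starts failed to converge."""

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics or []
        super().__init__(message)
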