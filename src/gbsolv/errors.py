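"""Exception types shared across the package."""


class GBSolvError(Exception):
    """Base class for all package-specific errors."""


class XYZParseError(GBSolvError):
    """Malformed XYZ file."""


class UnsupportedElementError(GBSolvError):
    """Element outside the parametrized set."""

    def __init__(self, symbol: str, context: str = ""):
        self.symbol = symbol
        msg = f"unsupported element {symbol!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class UnknownSolventError(GBSolvError):
    """Solvent name not found in the registry."""

    def __init__(self, name: str, available):
        self.name = name
        self.available = sorted(available)
        super().__init__(
            f"unknown solvent {name!r}; available: {', '.join(self.available)}"
        )


class SingularSystemError(GBSolvError):
    """Charge-equalization linear system is numerically singular."""

    def __init__(self, cond: float):
        self.cond = cond
        super().__init__(
            f"electronegativity-equalization system is singular or "
            f"ill-conditioned (condition number {cond:.3e})"
        )
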