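"""Exception hierarchy for dimerlink."""


class DimerlinkError(Exception):
    """Base class for all dimerlink errors."""


class NotADimerError(DimerlinkError):
    """Raised when a structure does not contain two usable polymer chains."""


class ChainTooShortError(DimerlinkError):
    """Raised when a selected chain has fewer than three C-alpha atoms."""


class SingularPairError(DimerlinkError):
    """Raised when two segment midpoints (nearly) coincide.

    The Gauss kernel diverges as the midpoint distance goes to zero;
    rather than return an inflated value we abort and name the pair.
    """

    def __init__(self, i: int, j: int, distance: float):
        self.i, self.j, self.distance = i, j, distance
        super().__init__(
            f"singular segment pair: midpoints {i} (curve 1) and {j} (curve 2) "
            f"are {distance:.3e} Å apart"
        )


class DecayFitError(DimerlinkError):
    """Raised when the exponential decay fit fails or is unidentifiable."""


class FixtureError(DimerlinkError):
    """Raised for invalid synthetic-fixture requests."""
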