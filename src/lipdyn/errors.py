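"""Exception types raised across the package."""


class LipdynError(Exception):
    """Base class for all package errors."""


class ParseError(LipdynError):
    """A file could not be parsed; the message names the offending line."""


class TopologyError(LipdynError):
    """Trajectory/topology atom counts disagree."""


class SelectionSyntaxError(LipdynError):
    """Selection expression violates the grammar; message carries position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class DegenerateGeometryError(LipdynError):
    """Geometric operation received degenerate input (zero-length arm,
    collinear point set, coincident atoms...)."""


class PlacementError(LipdynError):
    """Solvated-box builder could not place all molecules without clashes."""

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved
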