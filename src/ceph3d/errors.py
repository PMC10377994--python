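"""Exception hierarchy for ceph3d."""


class Ceph3dError(Exception):
    """Base class for all ceph3d errors."""


class ParseError(Ceph3dError):
    """A landmark file could not be parsed; the message names the offending line."""


class DuplicateLandmarkError(ParseError):
    """The same landmark name appears more than once in a session file."""


class MissingLandmarkError(Ceph3dError):
    """A construction requires landmarks that are absent from the session."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(f"missing required landmarks: {', '.join(self.names)}")


class SingularFitError(Ceph3dError):
    """Least-squares plane fit is degenerate (points collinear in the l-p footprint)."""


class DegenerateAngleError(Ceph3dError):
    """Projected points coincide or a projected direction has (near-)zero length."""


class NoIntersectionError(Ceph3dError):
    """Two planes are parallel and have no intersection line."""


class OpenContourError(Ceph3dError):
    """A mesh/plane intersection produced a contour that is not a closed loop."""


class NotWatertightError(Ceph3dError):
    """Volume computation refused because the mesh has open edges."""


class PlaneOrderingError(Ceph3dError):
    """Airway bounding planes are not in the expected superior-to-inferior order."""


class UndefinedICCError(Ceph3dError):
    """The ratings matrix has zero total variance; the ICC is not defined."""
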