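"""Planes, projections, distances and angles.

Every measurement parameter is composed from the operators here.  All
reference entities are themselves landmark-derived, so the whole kernel is
(rigid-motion) equivariant: transforming every input point transforms every
derived plane and leaves every measured quantity unchanged.  The one caveat
is the Frankfort-horizontal fit: it regresses the superior coordinate on
(l, p) by ordinary least squares, which is exactly equivariant only when the
four fitted points are coplanar (then the fit is the unique plane through
them).  See the methods note for the practical consequences.

Normal orientation conventions are anatomical, hence frame-independent
(fixed per label so signed distances and signed canting/yaw angles keep a
stable clinical meaning):

* FH / HP / MP / OP normals point superior (the nasion side of gnathion);
* the SP normal points toward the anatomical left (the ``_L`` porion);
* CP / TVL normals point anterior (nasion is anterior of basion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateAngleError, MissingLandmarkError,
                     NoIntersectionError, SingularFitError)
from .landmarks import LandmarkSet, Point3

_UNIT_TOL = 1e-12
_DEGENERATE_TOL = 1e-9


def _unit(v: np.ndarray, err: str = "zero-length vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm < _DEGENERATE_TOL:
        raise DegenerateAngleError(err)
    return v / norm


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    origin: Point3
    normal: Point3
    label: str = "generic"

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            n = n / np.linalg.norm(n)
        object.__setattr__(self, "normal", n)

    @classmethod
    def from_points(cls, a, b, c, label: str = "generic",
                    orient: np.ndarray | None = None) -> "Plane":
        """Plane through three points; ``orient`` picks the normal's sign."""
        a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n)
        if norm < _DEGENERATE_TOL:
            raise SingularFitError("three points are (near-)collinear")
        n = n / norm
        if orient is not None and np.dot(n, orient) < 0:
            n = -n
        return cls(a, n, label)


@dataclass(frozen=True)
class Line3:
    """A line given by a point and a unit direction."""

    origin: Point3
    direction: Point3

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        d = _unit(self.direction, "line direction has zero length")
        object.__setattr__(self, "direction", d)

    @classmethod
    def through(cls, a, b) -> "Line3":
        a = np.asarray(a, dtype=float)
        return cls(a, np.asarray(b, dtype=float) - a)


def fit_plane_ols(points, label: str = "generic") -> Plane:
    """Least-squares plane ``s = a*l + b*p + c`` through >= 3 points.

    The superior coordinate is the response: the target plane (Frankfort
    horizontal) is near-horizontal, so vertical residuals are
    well-conditioned.  Degenerate (l, p) footprints raise
    :class:`SingularFitError`.  For exactly coplanar inputs the result is
    the exact plane through them.  The returned normal has a positive
    superior component.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need an (m, 3) array with m >= 3")
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 3:
        raise SingularFitError("points are collinear in the (l, p) footprint")
    coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    a, b, c = coef
    normal = np.array([-a, -b, 1.0])
    normal /= np.linalg.norm(normal)
    lbar, pbar = pts[:, 0].mean(), pts[:, 1].mean()
    origin = np.array([lbar, pbar, a * lbar + b * pbar + c])
    return Plane(origin, normal, label)


def fit_plane_tls(points, label: str = "generic") -> Plane:
    """Orthogonal (total-least-squares) plane fit via SVD; optional variant."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(pts - centroid)
    if svals[1] < _DEGENERATE_TOL:
        raise SingularFitError("points are (near-)collinear")
    n = vt[2]
    if n[2] < 0:
        n = -n
    return Plane(centroid, n, label)


def project_point(plane: Plane, x) -> Point3:
    """Orthogonal projection of ``x`` onto ``plane``."""
    x = np.asarray(x, dtype=float)
    return x - np.dot(x - plane.origin, plane.normal) * plane.normal


def signed_distance(plane: Plane, x) -> float:
    """Signed point-to-plane distance along the plane's oriented normal (mm)."""
    return float(np.dot(np.asarray(x, dtype=float) - plane.origin, plane.normal))


def midpoint(*points) -> Point3:
    """Arithmetic centroid of one or more points."""
    if not points:
        raise ValueError("midpoint of no points")
    return np.mean([np.asarray(p, dtype=float) for p in points], axis=0)


def distance(x, y) -> float:
    return float(np.linalg.norm(np.asarray(x, dtype=float) - np.asarray(y, dtype=float)))


def distance_projected(x, y, plane: Plane) -> float:
    """Euclidean distance between the projections of two points onto a plane."""
    return distance(project_point(plane, x), project_point(plane, y))


def angle_at_vertex_projected(a, b, c, plane: Plane) -> float:
    """Angle (degrees, [0, 180]) at ``b`` between rays to ``a`` and ``c``,
    after projecting all three points onto ``plane``."""
    pa, pb, pc = (project_point(plane, x) for x in (a, b, c))
    v1 = pa - pb
    v2 = pc - pb
    if np.linalg.norm(v1) < _DEGENERATE_TOL or np.linalg.norm(v2) < _DEGENERATE_TOL:
        raise DegenerateAngleError("projected vertex coincides with an endpoint")
    ang = np.arctan2(np.linalg.norm(np.cross(v1, v2)), np.dot(v1, v2))
    return float(np.degrees(ang))


def _as_direction(obj, plane: Plane) -> np.ndarray:
    """Direction vector of a line-like argument, in 3-D (not yet projected).

    Accepts a :class:`Line3`, a pair of points, or a :class:`Plane` (replaced
    by its intersection line with the projection plane).
    """
    if isinstance(obj, Plane):
        d = np.cross(obj.normal, plane.normal)
        if np.linalg.norm(d) < _DEGENERATE_TOL:
            raise NoIntersectionError(
                f"plane {obj.label!r} is parallel to the projection plane")
        return d
    if isinstance(obj, Line3):
        return obj.direction
    a, b = obj
    return np.asarray(b, dtype=float) - np.asarray(a, dtype=float)


def plane_intersection_line(p1: Plane, p2: Plane) -> Line3:
    """Intersection line of two non-parallel planes."""
    d = np.cross(p1.normal, p2.normal)
    if np.linalg.norm(d) < _DEGENERATE_TOL:
        raise NoIntersectionError("planes are parallel")
    # Solve for a point on both planes (and on the plane through origin normal to d)
    A = np.vstack([p1.normal, p2.normal, d])
    b = np.array([np.dot(p1.normal, p1.origin), np.dot(p2.normal, p2.origin), 0.0])
    origin = np.linalg.solve(A, b)
    return Line3(origin, d)


def angle_between_lines_projected(l1, l2, plane: Plane) -> float:
    """Acute-or-right angle (degrees, [0, 90]) between two undirected lines
    after projecting their directions into ``plane``.

    Either argument may be a point pair, a :class:`Line3`, or a
    :class:`Plane` (its intersection line with ``plane`` is used).  Signed
    canting/yaw conventions live in the parameter layer, not here.
    """
    dirs = []
    for obj in (l1, l2):
        d = _as_direction(obj, plane)
        d = d - np.dot(d, plane.normal) * plane.normal
        if np.linalg.norm(d) < _DEGENERATE_TOL:
            raise DegenerateAngleError("projected line direction has zero length")
        dirs.append(d / np.linalg.norm(d))
    # atan2 form: full precision near 0 and 90 degrees
    cross = np.linalg.norm(np.cross(dirs[0], dirs[1]))
    dot = abs(float(np.dot(dirs[0], dirs[1])))
    return float(np.degrees(np.arctan2(cross, dot)))


@dataclass(frozen=True)
class ReferencePlaneSet:
    """The seven landmark-derived reference planes.

    FH is fitted to the four orbitale/porion points; SP passes through
    nasion and basion perpendicular to FH; HP through nasion parallel to FH;
    CP through nasion perpendicular to both; MP through gnathion and both
    gonions; OP is the occlusal plane (see ``op_mode``); TVL passes through
    subnasale perpendicular to FH and SP.
    """

    fh: Plane
    sp: Plane
    hp: Plane
    cp: Plane
    mp: Plane
    op: Plane
    tvl: Plane

    def __getitem__(self, label: str) -> Plane:
        return getattr(self, label.lower())

    # Orthonormal head axes used for signed angle conventions.
    @property
    def axis_left(self) -> np.ndarray:
        return self.sp.normal

    @property
    def axis_superior(self) -> np.ndarray:
        return self.fh.normal

    @property
    def axis_anterior(self) -> np.ndarray:
        return self.cp.normal


REFERENCE_PLANE_LANDMARKS = (
    "or_L", "or_R", "po_L", "po_R", "n", "ba", "gn", "go_L", "go_R",
    "u1d_L", "u1d_R", "u1m_L", "u1m_R", "u6_L", "u6_R", "sn'",
)


def build_reference_planes(lset: LandmarkSet, op_mode: str = "midpoint3") -> ReferencePlaneSet:
    """Construct all seven reference planes from one landmark session.

    ``op_mode`` selects the occlusal-plane reading: ``midpoint3`` (default)
    takes the exact plane through the incisal-edge midpoint and the two
    first-molar cusps; ``ols6`` least-squares-fits the six incisor-edge and
    molar points.
    """
    missing = lset.missing(REFERENCE_PLANE_LANDMARKS)
    if missing:
        raise MissingLandmarkError(missing)

    fh = fit_plane_ols([lset["or_L"], lset["or_R"], lset["po_L"], lset["po_R"]],
                       label="FH")
    n_pt, ba = lset["n"], lset["ba"]
    # orientation conventions are anatomical (frame-independent): the FH/HP
    # normal points superior (nasion side, away from gnathion), the SP
    # normal toward the anatomical left (the _L porion), the CP/TVL normal
    # anterior (nasion is anterior of basion)
    fh_normal = fh.normal
    if np.dot(fh_normal, n_pt - lset["gn"]) < 0:
        fh_normal = -fh_normal
    fh = Plane(fh.origin, fh_normal, "FH")

    sp_normal = np.cross(ba - n_pt, fh.normal)
    if np.linalg.norm(sp_normal) < _DEGENERATE_TOL:
        raise SingularFitError("nasion-basion direction is parallel to the FH normal")
    sp_normal = sp_normal / np.linalg.norm(sp_normal)
    if np.dot(sp_normal, lset["po_L"] - lset["po_R"]) < 0:
        sp_normal = -sp_normal
    sp = Plane(n_pt, sp_normal, "SP")

    hp = Plane(n_pt, fh.normal, "HP")

    cp_normal = np.cross(fh.normal, sp.normal)
    cp_normal = cp_normal / np.linalg.norm(cp_normal)
    if np.dot(cp_normal, n_pt - ba) < 0:
        cp_normal = -cp_normal
    cp = Plane(n_pt, cp_normal, "CP")

    mp = Plane.from_points(lset["gn"], lset["go_L"], lset["go_R"], "MP",
                           orient=fh.normal)

    incisal_mid = midpoint(lset["u1d_L"], lset["u1d_R"], lset["u1m_L"], lset["u1m_R"])
    if op_mode == "midpoint3":
        op = Plane.from_points(incisal_mid, lset["u6_L"], lset["u6_R"], "OP",
                               orient=fh.normal)
    elif op_mode == "ols6":
        op = fit_plane_ols([lset["u1d_L"], lset["u1d_R"], lset["u1m_L"],
                            lset["u1m_R"], lset["u6_L"], lset["u6_R"]], label="OP")
    else:
        raise ValueError(f"unknown op_mode {op_mode!r}")

    tvl = Plane(lset["sn'"], cp.normal, "TVL")
    return ReferencePlaneSet(fh=fh, sp=sp, hp=hp, cp=cp, mp=mp, op=op, tvl=tvl)


def signed_canting_deg(left_pt, right_pt, planes: ReferencePlaneSet) -> float:
    """Coronal tilt of the left-to-right line of a bilateral pair (degrees).

    Both points are projected on CP; positive when the left point ends up
    superior.  A mirror-symmetric head gives exactly zero.
    """
    d = np.asarray(left_pt, dtype=float) - np.asarray(right_pt, dtype=float)
    dl = float(np.dot(d, planes.axis_left))
    ds = float(np.dot(d, planes.axis_superior))
    if abs(dl) < _DEGENERATE_TOL and abs(ds) < _DEGENERATE_TOL:
        raise DegenerateAngleError("bilateral points coincide after projection on CP")
    return float(np.degrees(np.arctan2(ds, dl)))


def signed_yaw_deg(anterior_pt, posterior_pt, planes: ReferencePlaneSet) -> float:
    """Axial deviation of a midline anteroposterior line from SP (degrees).

    Projected on HP; positive when the anterior end deviates to the left.
    """
    d = np.asarray(anterior_pt, dtype=float) - np.asarray(posterior_pt, dtype=float)
    dl = float(np.dot(d, planes.axis_left))
    da = float(np.dot(d, planes.axis_anterior))
    if abs(dl) < _DEGENERATE_TOL and abs(da) < _DEGENERATE_TOL:
        raise DegenerateAngleError("line endpoints coincide after projection on HP")
    return float(np.degrees(np.arctan2(dl, da)))


def signed_condyle_yaw_deg(lateral_pt, medial_pt, side: str,
                           planes: ReferencePlaneSet) -> float:
    """Axial rotation of one condylar medio-lateral axis (degrees).

    Projected on HP and measured from the pure lateral direction of the
    given side; positive when the lateral pole sits anterior to the medial
    pole.  On a mirror-symmetric head the left and right values are equal.
    """
    d = np.asarray(lateral_pt, dtype=float) - np.asarray(medial_pt, dtype=float)
    lat = planes.axis_left if side == "left" else -planes.axis_left
    dl = float(np.dot(d, lat))
    da = float(np.dot(d, planes.axis_anterior))
    if abs(dl) < _DEGENERATE_TOL and abs(da) < _DEGENERATE_TOL:
        raise DegenerateAngleError("condylar poles coincide after projection on HP")
    return float(np.degrees(np.arctan2(da, dl)))


def rigid_motion(rng: np.random.Generator | None = None,
                 seed: int | None = None):
    """A uniformly random proper rotation and a translation, for testing
    frame invariance.  Returns ``(R, t)``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    # QR of a Gaussian matrix gives a Haar-distributed orthogonal matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-100.0, 100.0, size=3)
    return q, t
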