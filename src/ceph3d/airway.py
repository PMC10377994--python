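"""Upper-airway cross-sections and volumes from a closed surface mesh.

The pharyngeal airway is bounded by planes parallel to the Frankfort
horizontal through the posterior nasal spine (top), the uvula tip (the
velopharynx/glossopharynx boundary) and the anterior-inferior C3 point
(bottom).  Cross-sectional areas are taken on a 1 mm grid anchored at the
top plane; areas of multiple disjoint intersection loops are summed, since
the airway lumen may be non-convex or bifid at a slice.

Volumes are exact volumes of the mesh clipped between two parallel planes,
evaluated by the divergence theorem with a vector field chosen parallel to
the clipping planes: the planar caps then carry zero flux, so only the
(clipped) lateral surface has to be integrated and no cap triangulation is
needed.  Slice-profile integration is retained in the test suite as an
independent oracle, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .config import RunConfig
from .errors import (MissingLandmarkError, NotWatertightError,
                     OpenContourError, PlaneOrderingError)
from .geometry import Plane, ReferencePlaneSet, signed_distance
from .landmarks import LandmarkSet

AirwayMesh = trimesh.Trimesh


def load_mesh(path, ras_to_lps: bool = False) -> AirwayMesh:
    """Load a triangulated surface (STL/PLY/OBJ), optionally flipping RAS->LPS."""
    mesh = trimesh.load_mesh(path)
    if isinstance(mesh, trimesh.Scene):
        mesh = mesh.to_mesh()
    if ras_to_lps:
        mesh = mesh.copy()
        mesh.apply_transform(np.diag([-1.0, -1.0, 1.0, 1.0]))
        mesh.invert()  # reflection flips orientation
    return mesh


def section_area(mesh: AirwayMesh, plane: Plane) -> float:
    """Total enclosed area (mm^2) of all closed mesh/plane intersection loops.

    Returns 0 when the plane misses the mesh; raises
    :class:`OpenContourError` when any intersection contour fails to close
    (mesh boundary crosses the plane).
    """
    path3d = mesh.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if path3d is None or len(path3d.entities) == 0:
        return 0.0
    if not path3d.is_closed:
        raise OpenContourError(
            "mesh/plane intersection contains an open contour "
            "(mesh boundary crosses the section plane)")
    # in-plane orthonormal basis for the 2-D shoelace formula
    n = plane.normal
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    total = 0.0
    for loop in path3d.discrete:
        if not np.allclose(loop[0], loop[-1], atol=1e-8):
            raise OpenContourError(
                "mesh/plane intersection contains an open contour "
                "(mesh boundary crosses the section plane)")
        x = (loop - plane.origin) @ e1
        y = (loop - plane.origin) @ e2
        total += 0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    return float(total)


@dataclass
class SliceProfile:
    """Area-vs-depth profile between two bounding planes.

    ``heights`` are offsets (mm) below the top plane, strictly increasing,
    with both endpoints included (the last entry is the exact plane-to-plane
    gap even when it is not a step multiple).
    """

    heights: np.ndarray
    areas: np.ndarray

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(np.diff(self.heights) <= 0):
            raise ValueError("profile heights must be strictly increasing")
        if np.any(self.areas < -1e-9):
            raise ValueError("negative section area")

    @property
    def mean(self) -> float:
        return float(self.areas.mean())

    @property
    def min(self) -> float:
        return float(self.areas.min())


def _grid(gap: float, step: float) -> np.ndarray:
    """Offsets 0, step, 2*step, ... plus the exact bottom plane."""
    if gap <= 0:
        raise PlaneOrderingError("top plane must lie strictly above the bottom plane")
    offsets = list(np.arange(0.0, gap, step))
    if gap - offsets[-1] < 1e-9 * max(1.0, gap):
        offsets[-1] = gap
    else:
        offsets.append(gap)
    return np.array(offsets)


def slice_profile(mesh: AirwayMesh, top: Plane, bottom: Plane,
                  step: float = 1.0) -> SliceProfile:
    """Section the mesh on a regular grid between two parallel planes.

    The grid is anchored at the top plane and includes both endpoints.
    """
    n = top.normal
    if np.linalg.norm(np.cross(n, bottom.normal)) > 1e-9:
        raise PlaneOrderingError("bounding planes are not parallel")
    gap = signed_distance(top, bottom.origin)  # along the top normal
    down = -n
    if gap > 0:  # bottom is on the +normal side; flip the descent direction
        down = n
    gap = abs(gap)
    offsets = _grid(gap, step)
    areas = [section_area(mesh, Plane(top.origin + off * down, n)) for off in offsets]
    return SliceProfile(offsets, np.array(areas))


# ------------------------------------------------------------------ volume

def _clip_polygon(poly: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clip of a planar polygon to the half-space
    ``dot(x - origin, normal) <= 0``."""
    sd = (poly - origin) @ normal
    out = []
    m = len(poly)
    for i in range(m):
        j = (i + 1) % m
        inside_i, inside_j = sd[i] <= 0, sd[j] <= 0
        if inside_i:
            out.append(poly[i])
        if inside_i != inside_j:
            t = sd[i] / (sd[i] - sd[j])
            out.append(poly[i] + t * (poly[j] - poly[i]))
    return np.array(out) if out else np.empty((0, 3))


def clipped_volume(mesh: AirwayMesh, top: Plane, bottom: Plane) -> float:
    """Volume (mm^3) of the region of a watertight mesh between two parallel
    planes, with exact planar caps.

    Implementation: each surface triangle is clipped to the slab, and the
    flux of the field ``F = (x . u) u`` (``div F = 1``) with ``u`` a unit
    vector parallel to both clipping planes is summed over the clipped
    lateral surface.  The caps have normals perpendicular to ``u`` and
    contribute nothing, so the result equals the capped-solid volume.
    """
    if not mesh.is_watertight:
        raise NotWatertightError(
            "mesh has open edges; repair it (e.g. fill holes / merge duplicate "
            "vertices) before requesting volumes")
    n = top.normal
    if np.linalg.norm(np.cross(n, bottom.normal)) > 1e-9:
        raise PlaneOrderingError("bounding planes are not parallel")
    # u: any unit vector orthogonal to the slab normal
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)

    # orient half-spaces so the slab is the intersection of both "inside"s
    def halfspace(plane: Plane, interior_point: np.ndarray):
        nn = plane.normal
        if np.dot(interior_point - plane.origin, nn) > 0:
            nn = -nn
        return plane.origin, nn

    mid = 0.5 * (top.origin + project_along(bottom, top.origin))
    hs = [halfspace(top, mid), halfspace(bottom, mid)]

    tris = mesh.triangles  # (m, 3, 3)
    face_normals = mesh.face_normals
    if mesh.volume < 0:  # inverted winding; flip outwardness
        face_normals = -face_normals
    volume = 0.0
    for tri, fn in zip(tris, face_normals):
        poly = tri
        for origin, nn in hs:
            if len(poly) == 0:
                break
            poly = _clip_polygon(poly, origin, nn)
        if len(poly) < 3:
            continue
        nu = float(np.dot(fn, u))
        if nu == 0.0:
            continue
        # fan triangulation; integrand (x.u) is linear, so use centroids
        for k in range(1, len(poly) - 1):
            a, b, c = poly[0], poly[k], poly[k + 1]
            area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
            centroid_u = float(np.dot(a + b + c, u)) / 3.0
            volume += nu * area * centroid_u
    return float(volume)


def project_along(plane: Plane, x: np.ndarray) -> np.ndarray:
    """Foot of the perpendicular from ``x`` onto ``plane``."""
    x = np.asarray(x, dtype=float)
    return x - np.dot(x - plane.origin, plane.normal) * plane.normal


def airway_parameters(mesh: AirwayMesh, lset: LandmarkSet,
                      planes: ReferencePlaneSet,
                      config: RunConfig | None = None) -> dict:
    """The nine airway parameters as a name -> value mapping.

    Mean areas are means of the ``step_mm`` slice profile over the
    respective segment (``mean_mode='volume_over_height'`` divides the
    clipped volume by the segment height instead); the minimum area is the
    grid minimum over the full pharynx.  ``H-MP`` is the unsigned distance
    from the hyoid to the mandibular plane; ``H-C`` the distance from the
    hyoid to the C2/C3 midpoint.
    """
    config = config or RunConfig()
    required = ("alv(PNS)", "u", "h", "c2", "c3")
    missing = lset.missing(required)
    if missing:
        raise MissingLandmarkError(missing)

    n = planes.fh.normal
    top = Plane(lset["alv(PNS)"], n, "FH")
    mid = Plane(lset["u"], n, "FH")
    bottom = Plane(lset["c3"], n, "FH")

    # superior-to-inferior ordering along the FH normal
    s_top = 0.0
    s_mid = signed_distance(top, mid.origin)
    s_bot = signed_distance(top, bottom.origin)
    if not (min(s_top, s_bot) < s_mid < max(s_top, s_bot)):
        raise PlaneOrderingError(
            "uvula plane does not lie between the alv(PNS) and c3 planes")

    step = config.step_mm
    full = slice_profile(mesh, top, bottom, step)
    velo = slice_profile(mesh, top, mid, step)
    glosso = slice_profile(mesh, mid, bottom, step)

    vol_velo = clipped_volume(mesh, top, mid)
    vol_glosso = clipped_volume(mesh, mid, bottom)
    vol_full = clipped_volume(mesh, top, bottom)

    if config.mean_mode == "volume_over_height":
        means = (vol_full / abs(s_bot), vol_velo / abs(s_mid),
                 vol_glosso / abs(s_bot - s_mid))
    else:
        means = (full.mean, velo.mean, glosso.mean)

    h = lset["h"]
    return {
        "H-MP|^d": abs(signed_distance(planes.mp, h)),
        "H-C|^d": float(np.linalg.norm(h - 0.5 * (lset["c2"] + lset["c3"]))),
        "Airway, Mean|^a": means[0],
        "Velopharynx, Mean|^a": means[1],
        "Glossopharynx, Mean|^a": means[2],
        "Airway, Min|^a": full.min,
        "Airway|^v": vol_full,
        "Velopharynx|^v": vol_velo,
        "Glossopharynx|^v": vol_glosso,
    }
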