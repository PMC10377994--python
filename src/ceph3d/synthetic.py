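"""Deterministic synthetic data: head templates, rater sessions, phantoms.

The head template is a complete 126-landmark set with hard-coded plausible
adult proportions (bizygomatic breadth ~130 mm, anterior facial height
~100 mm).  It makes no claim of normative anatomy; its job is to exercise
every measurement without degeneracies.  By construction the template is
exactly mirror symmetric about its own midsagittal plane, so every signed
canting/yaw parameter and every midline-to-sagittal distance is exactly
zero -- the null the symmetry tests rely on.  Per-seed shape variation is
applied mirror-symmetrically (median points move within the midline plane,
bilateral pairs move as mirror images), which also keeps the four
Frankfort-horizontal fit points exactly coplanar, making the whole
parameter set exactly rigid-motion invariant (see the methods note).

The study simulator reproduces the 2-examiner x 2-session design: subject
anatomy = one study base template + isotropic per-landmark subject offsets
(SD ``sigma_subject``); each examiner carries a systematic per-landmark
bias field (SD ``sigma_examiner``) shared across their sessions; each
session adds independent labeling noise (SD ``sigma_session``).  For any
single coordinate this is the classic two-way random-effects decomposition,
so the intra-examiner ICC has expectation
sigma_subject^2 / (sigma_subject^2 + sigma_session^2).

Airway phantoms are generalized cylinders aligned with the template's
vertical axis, with closed-form area profiles and volumes used as oracles
for the areal/voluminal parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .landmarks import LandmarkSet, build_registry

# Base template coordinates, LPS mm.  Median points at l = 0; bilateral
# entries give the LEFT point, the right one is its mirror image.
# Nasion at the origin; Frankfort horizontal at s = -28 by construction
# (orbitale and porion share that height).
_MEDIAN = {
    "s": (0.0, 65.0, -5.0),
    "ba": (0.0, 85.0, -35.0),
    "n": (0.0, 0.0, 0.0),
    "a(ANS)": (0.0, -3.0, -50.0),
    "ss(A)": (0.0, 1.0, -55.0),
    "alv(PNS)": (0.0, 42.0, -52.0),
    "ale": (0.0, -2.0, -60.0),
    "ol": (0.0, 5.0, -60.0),
    "id": (0.0, 2.0, -68.0),
    "li": (0.0, 8.0, -70.0),
    "sm(B)": (0.0, 6.0, -78.0),
    "pg": (0.0, 4.0, -92.0),
    "gn": (0.0, 6.0, -97.0),
    "me": (0.0, 8.0, -100.0),
    "ge": (0.0, 14.0, -88.0),
    "g'": (0.0, -8.0, 8.0),
    "n'": (0.0, -7.0, 0.0),
    "se'": (0.0, -9.0, -6.0),
    "pn'": (0.0, -22.0, -30.0),
    "sn'": (0.0, -14.0, -38.0),
    "c'": (0.0, -20.0, -32.0),
    "ls'": (0.0, -13.0, -52.0),
    "mp'": (0.0, -13.5, -45.0),
    "sto'": (0.0, -12.0, -57.0),
    "li'": (0.0, -13.0, -63.0),
    "sm'": (0.0, -10.0, -72.0),
    "me'": (0.0, -4.0, -102.0),
    "pg'": (0.0, -9.0, -90.0),
    "gn'": (0.0, -6.5, -96.0),
    "u": (0.0, 48.0, -68.0),
    "h": (0.0, 38.0, -108.0),
    "c3": (0.0, 74.0, -110.0),
    "c2": (0.0, 72.0, -90.0),
    "epi": (0.0, 52.0, -102.0),
}
_BILATERAL_LEFT = {
    "po": (58.0, 75.0, -28.0),
    "ms": (52.0, 72.0, -45.0),
    "or": (32.0, 12.0, -28.0),
    "al": (12.0, -2.0, -48.0),
    "zm": (42.0, 25.0, -40.0),
    "ju": (55.0, 48.0, -30.0),
    "zy": (65.0, 55.0, -25.0),
    "ecm_u6": (30.0, 25.0, -58.0),
    "ecm_u7": (32.0, 35.0, -57.0),
    "enm_u7": (20.0, 35.0, -57.0),
    "col": (50.0, 70.0, -25.0),
    "cdl": (58.0, 70.0, -28.0),
    "cdm": (42.0, 70.0, -28.0),
    "go": (48.0, 65.0, -78.0),
    "ag": (44.0, 55.0, -85.0),
    "ecm_l6": (28.0, 28.0, -65.0),
    "ml": (24.0, 18.0, -82.0),
    "lg": (44.0, 62.0, -48.0),
    "enm_l6": (18.0, 28.0, -65.0),
    "u1d": (4.5, -8.0, -65.0),
    "u1m": (0.8, -8.5, -65.3),
    "apu1": (2.6, 0.0, -50.0),
    "u3": (18.0, 2.0, -61.0),
    "u6": (26.0, 26.0, -60.0),
    "l1d": (4.2, -5.0, -63.0),
    "l1m": (0.8, -5.5, -63.3),
    "apl1": (2.5, 2.0, -78.0),
    "l3": (17.0, 4.0, -62.0),
    "l6": (25.0, 28.0, -62.0),
    "al'": (16.0, -6.0, -44.0),
    "ma'": (14.0, -10.0, -40.0),
    "ac'": (17.0, -2.0, -42.0),
    "sbal'": (8.0, -9.0, -44.0),
    "mc'": (4.0, -16.0, -36.0),
    "cs'": (6.0, -14.0, -38.0),
    "vs'": (5.0, -12.0, -51.0),
    "ch'": (24.0, -6.0, -56.0),
    "vi'": (8.0, -11.0, -62.0),
    "obs'": (62.0, 70.0, -10.0),
    "t'": (60.0, 72.0, -22.0),
    "it'": (60.0, 70.0, -30.0),
    "obi'": (58.0, 72.0, -38.0),
    "ps'": (28.0, 2.0, -20.0),
    "en'": (16.0, 4.0, -22.0),
    "ex'": (44.0, 6.0, -24.0),
    "zy'": (68.0, 55.0, -25.0),
}


def make_template(subject_seed: int = 0, variation_mm: float = 1.5,
                  scale_sd: float = 0.03, subject_id: str = "") -> LandmarkSet:
    """A complete, exactly mirror-symmetric 126-landmark head.

    ``variation_mm`` controls seeded per-landmark shape offsets: median
    points are displaced only within the midline plane, bilateral pairs are
    displaced as exact mirror images, and the whole head gets a mild global
    scale factor (SD ``scale_sd``).  ``variation_mm=0`` returns the fixed
    base template.  Identical seeds reproduce identical sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([subject_seed, 0x5EAD]))
    scale = 1.0 + scale_sd * float(rng.standard_normal()) if variation_mm > 0 else 1.0
    scale = float(np.clip(scale, 0.85, 1.15))
    points = {}
    for name, (l, p, s) in _MEDIAN.items():
        dp, ds = (variation_mm * rng.standard_normal(2)) if variation_mm > 0 else (0.0, 0.0)
        points[name] = scale * np.array([l, p + dp, s + ds])
    for code, (l, p, s) in _BILATERAL_LEFT.items():
        if variation_mm > 0:
            dl, dp, ds = variation_mm * rng.standard_normal(3)
        else:
            dl = dp = ds = 0.0
        left = scale * np.array([l + dl, p + dp, s + ds])
        right = left * np.array([-1.0, 1.0, 1.0])
        points[code + "_L"] = left
        points[code + "_R"] = right
    assert set(points) == set(build_registry().names)
    return LandmarkSet(points, subject_id=subject_id or f"synthetic-{subject_seed}")


def perturb(lset: LandmarkSet, sigma_mm: float, seed: int,
            keep_fh_coplanar: bool = False) -> LandmarkSet:
    """Add isotropic Gaussian noise to every landmark (asymmetric).

    With ``keep_fh_coplanar`` the offsets of the four Frankfort-horizontal
    fit points (orbitale and porion, both sides) are projected into the
    plane currently spanned by them, keeping that quadruple exactly
    coplanar.  Geometric property tests use this to retain exact
    plane-fit equivariance on an otherwise asymmetric head.
    """
    rng = np.random.default_rng(seed)
    fh_names = ("or_L", "or_R", "po_L", "po_R")
    normal = None
    if keep_fh_coplanar:
        pts = np.array([lset[nm] for nm in fh_names])
        # the quadruple is coplanar in any mirror-symmetric template
        u, v = pts[1] - pts[0], pts[2] - pts[0]
        normal = np.cross(u, v)
        normal /= np.linalg.norm(normal)
    points = {}
    for name, pt in lset.points.items():
        offset = sigma_mm * rng.standard_normal(3)
        if normal is not None and name in fh_names:
            offset = offset - np.dot(offset, normal) * normal
        points[name] = pt + offset
    return LandmarkSet(points, subject_id=lset.subject_id,
                       examiner_id=lset.examiner_id, session_id=lset.session_id)


@dataclass(frozen=True)
class NoiseModel:
    """Variance components of the simulated labeling process (mm)."""

    sigma_subject: float = 2.0
    sigma_examiner: float = 0.5
    sigma_session: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_subject", "sigma_examiner", "sigma_session"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_study(n_subjects: int, noise: NoiseModel,
                   examiners=("1", "2"), sessions=("1", "2")) -> dict:
    """Simulate a complete reliability study.

    Returns a manifest ``(subject, examiner, session) -> LandmarkSet`` with
    ``len(examiners) * len(sessions) * n_subjects`` entries.  One base
    anatomy is drawn per study; subject truths add isotropic per-landmark
    offsets of SD ``sigma_subject``, each examiner adds a bias field of SD
    ``sigma_examiner`` shared across their sessions, and each session adds
    independent noise of SD ``sigma_session``.  Fully deterministic in
    ``noise.seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    root = np.random.SeedSequence([noise.seed, 0x57CD])
    base_seed, offsets_seed = root.spawn(2)
    base = make_template(int(base_seed.generate_state(1)[0] % (2**31)),
                         variation_mm=1.5)
    names = list(base.points)
    m = len(names)
    rng = np.random.default_rng(offsets_seed)

    subject_off = noise.sigma_subject * rng.standard_normal((n_subjects, m, 3))
    examiner_off = noise.sigma_examiner * rng.standard_normal((len(examiners), m, 3))

    manifest = {}
    for si in range(n_subjects):
        subject = f"S{si + 1:03d}"
        truth = {nm: base[nm] + subject_off[si, j] for j, nm in enumerate(names)}
        for ei, examiner in enumerate(examiners):
            for session in sessions:
                sess_noise = noise.sigma_session * rng.standard_normal((m, 3))
                pts = {nm: truth[nm] + examiner_off[ei, j] + sess_noise[j]
                       for j, nm in enumerate(names)}
                manifest[(subject, examiner, session)] = LandmarkSet(
                    pts, subject_id=subject, examiner_id=examiner,
                    session_id=session)
    return manifest


# ----------------------------------------------------------------- phantoms

PROFILES = ("constant", "step", "taper", "two_lobe")


@dataclass(frozen=True)
class PhantomSpec:
    """A generalized-cylinder airway phantom with closed-form answers.

    ``profile`` shapes the radius along the axis: ``constant`` (radius_top
    everywhere), ``step`` (radius_top above mid-height, radius_bottom
    below), ``taper`` (linear radius_top -> radius_bottom) or ``two_lobe``
    (two disjoint parallel constant tubes, radii radius_top and
    radius_bottom, 3.5 radii apart).  The axis is vertical (the template's
    FH normal); ``top_s`` is the superior end, the tube extends ``height``
    mm downward.
    """

    profile: str = "constant"
    radius_top: float = 10.0
    radius_bottom: float = 5.0
    height: float = 40.0
    facet_count: int = 360
    top_s: float = 0.0
    center_lp: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.facet_count < 16:
            raise ValueError("facet_count must be >= 16")
        if self.height <= 0 or self.radius_top <= 0 or self.radius_bottom <= 0:
            raise ValueError("height and radii must be positive")

    # -- closed-form answers for the continuous surface --------------------
    def radius_at(self, depth: float) -> float:
        """Radius at ``depth`` mm below the top (constant/step/taper only)."""
        if self.profile == "constant":
            return self.radius_top
        if self.profile == "step":
            return self.radius_top if depth < self.height / 2 else self.radius_bottom
        if self.profile == "taper":
            t = depth / self.height
            return (1 - t) * self.radius_top + t * self.radius_bottom
        raise ValueError("no single radius for a two-lobe phantom")

    def area_at(self, depth: float) -> float:
        if self.profile == "two_lobe":
            return np.pi * (self.radius_top**2 + self.radius_bottom**2)
        return np.pi * self.radius_at(depth) ** 2

    @property
    def analytic_volume(self) -> float:
        h, r1, r2 = self.height, self.radius_top, self.radius_bottom
        if self.profile == "constant":
            return np.pi * r1**2 * h
        if self.profile == "step":
            return np.pi * (r1**2 + r2**2) * h / 2.0
        if self.profile == "taper":  # conical frustum
            return np.pi * h * (r1**2 + r1 * r2 + r2**2) / 3.0
        return np.pi * (r1**2 + r2**2) * h

    @property
    def analytic_min_area(self) -> float:
        if self.profile == "two_lobe":
            return self.area_at(0.0)
        return np.pi * min(self.radius_top, self.radius_bottom) ** 2 \
            if self.profile != "constant" else np.pi * self.radius_top**2

    @property
    def analytic_mean_area(self) -> float:
        """Height-averaged cross-sectional area."""
        return self.analytic_volume / self.height


def _tube(center_lp, rings, facets) -> tuple:
    """Vertices and faces of one closed tube; ``rings`` is a list of
    (s-height, radius), superior first."""
    cl, cp = center_lp
    theta = np.linspace(0.0, 2.0 * np.pi, facets, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    verts = []
    for s, r in rings:
        ring = np.column_stack([cl + r * cos_t, cp + r * sin_t,
                                np.full(facets, s)])
        verts.append(ring)
    top_center = np.array([[cl, cp, rings[0][0]]])
    bot_center = np.array([[cl, cp, rings[-1][0]]])
    verts = np.vstack(verts + [top_center, bot_center])
    n_rings = len(rings)
    i_top, i_bot = n_rings * facets, n_rings * facets + 1
    faces = []
    for ridx in range(n_rings - 1):
        a0, b0 = ridx * facets, (ridx + 1) * facets
        for j in range(facets):
            jn = (j + 1) % facets
            faces.append([a0 + j, b0 + j, b0 + jn])
            faces.append([a0 + j, b0 + jn, a0 + jn])
    for j in range(facets):  # caps
        jn = (j + 1) % facets
        faces.append([i_top, jn, j])  # top cap faces up (+s outward)
        base = (n_rings - 1) * facets
        faces.append([i_bot, base + j, base + jn])
    return verts, np.array(faces)


def make_phantom(spec: PhantomSpec) -> trimesh.Trimesh:
    """Build the watertight phantom mesh for a spec (LPS mm, vertical axis)."""
    s0, h = spec.top_s, spec.height
    if spec.profile == "two_lobe":
        sep = 3.5 * max(spec.radius_top, spec.radius_bottom)
        cl, cp = spec.center_lp
        va, fa = _tube((cl - sep / 2, cp), [(s0, spec.radius_top),
                                            (s0 - h, spec.radius_top)],
                       spec.facet_count)
        vb, fb = _tube((cl + sep / 2, cp), [(s0, spec.radius_bottom),
                                            (s0 - h, spec.radius_bottom)],
                       spec.facet_count)
        verts = np.vstack([va, vb])
        faces = np.vstack([fa, fb + len(va)])
    else:
        if spec.profile == "constant":
            rings = [(s0, spec.radius_top), (s0 - h, spec.radius_top)]
        elif spec.profile == "taper":
            rings = [(s0, spec.radius_top), (s0 - h, spec.radius_bottom)]
        else:  # step: duplicate ring at the jump forms the annular shelf
            rings = [(s0, spec.radius_top), (s0 - h / 2, spec.radius_top),
                     (s0 - h / 2, spec.radius_bottom), (s0 - h, spec.radius_bottom)]
        verts, faces = _tube(spec.center_lp, rings, spec.facet_count)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.fix_normals()
    if not mesh.is_watertight:
        raise RuntimeError("phantom construction produced a non-watertight mesh")
    return mesh


def airway_phantom_for(lset: LandmarkSet, radius: float = 12.0,
                       facet_count: int = 180) -> trimesh.Trimesh:
    """A constant tube spanning the subject's alv(PNS)..c3 slab with margin,
    positioned behind the ramus -- a stand-in airway for pipeline tests."""
    top = float(lset["alv(PNS)"][2]) + 5.0
    bottom = float(lset["c3"][2]) - 5.0
    cp = float((lset["alv(PNS)"][1] + lset["c3"][1]) / 2.0)
    spec = PhantomSpec(profile="constant", radius_top=radius,
                       height=top - bottom, facet_count=facet_count,
                       top_s=top, center_lp=(0.0, cp))
    return make_phantom(spec)
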