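"""The 126-landmark registry and the in-memory landmark session container.

Landmarks are named 3-D points in millimetres in the LPS
(left-posterior-superior) frame.  The registry groups them into five
anatomical regions -- cranial, mandibular, teeth, soft tissue and airway --
with bilateral entries expanded into ``_L``/``_R`` pairs.  One point,
``alv(PNS)`` (the posterior nasal spine), belongs to both the cranial and
the airway region, so the region counts 28 + 25 + 20 + 48 + 6 sum to 127
while the registry holds 126 unique names.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

REGIONS = ("cranial", "mandibular", "teeth", "soft_tissue", "airway")

Point3 = np.ndarray  # shape (3,), float64, LPS millimetres


def point(l: float, p: float, s: float) -> Point3:
    """Build an LPS point; raises on non-finite coordinates."""
    arr = np.array([l, p, s], dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite coordinates: {arr}")
    return arr


@dataclass(frozen=True)
class LandmarkDef:
    """One registry entry: a named anatomical point.

    ``laterality`` is ``median`` for midline points; bilateral table entries
    are stored as two defs with ``_L``/``_R`` suffixes and laterality
    ``left``/``right``.  ``shared_regions`` is non-empty only for
    ``alv(PNS)``, which the schema counts in both the cranial and airway
    sets.
    """

    name: str
    long_name: str
    region: str
    laterality: str
    definition_text: str
    shared_regions: frozenset = field(default_factory=frozenset)

    @property
    def regions(self) -> frozenset:
        return frozenset({self.region}) | self.shared_regions


# (code, long name, definition) per region; bilateral rows expand to _L/_R.
_CRANIAL_MEDIAN = [
    ("s", "Sella", "The central point of the sella turcica"),
    ("ba", "Basion", "The most inferior median point on the foramen magnum's anterior rim"),
    ("n", "Nasion", "Intersection of the nasofrontal sutures in the median plane"),
    ("a(ANS)", "Acanthion (ANS)",
     "Most anterior tip of the anterior nasal spine; also known as anterior nasal spine (ANS)"),
    ("ss(A)", "Subspinale",
     "The deepest point seen in the profile view below the anterior nasal spine; also known as orthodontic point A"),
    ("alv(PNS)", "Alveolon (PNS)",
     "Median point, at the rear of the hard palate, of a line joining the posteriormost alveolar margins; "
     "also known as posterior nasal spine (PNS)"),
    ("ale", "Alveolare",
     "Median point at the inferior tip of the bony septum between the upper central incisors"),
    ("ol", "Orale", "Median most inferior point of the maxillary symphysis; on the lingual surface"),
]
_CRANIAL_BILATERAL = [
    ("po", "Porion", "Most superior point on the upper margin of the external auditory meatus"),
    ("ms", "Mastoidale", "The inferiormost projecting point of the tip of the mastoid process"),
    ("or", "Orbitale",
     "Most inferior point on the inferior orbital rim; usually falls along the lateral half of the orbital margin"),
    ("al", "Alare",
     "Instrumentally determined as the most lateral point on the nasal aperture in a transverse plane"),
    ("zm", "Zygomaxillare", "Most inferior point on the zygomaticomaxillary suture"),
    ("ju", "Jugale",
     "Vertex of the posterior zygomatic angle; between the vertical edge and horizontal part of the zygomatic arch"),
    ("zy", "Zygion", "Instrumentally determined as the most lateral point on the zygomatic arch"),
    ("ecm_u6", "Ectomolare U6",
     "Most lateral point on the buccal alveolar margin; at the mesial buccal edge of the first molar position"),
    ("ecm_u7", "Ectomolare",
     "Most lateral point on the buccal alveolar margin; at the center of the second molar position"),
    ("enm_u7", "Ectomolare",
     "Most lateral point on the lingual alveolar margin; at the center of the second molar position"),
]
_MANDIBULAR_MEDIAN = [
    ("id", "Infradentale",
     "Median point at the superior tip of the septum between the mandibular central incisors"),
    ("li", "Linguale", "Median most superior point of the mandibular symphysis; on the lingual surface"),
    ("sm(B)", "Supramentale",
     "Deepest median point in the groove superior to the mental eminence; also known as orthodontic point B"),
    ("pg", "Pogonion", "Most anterior median point on the mental eminence of the mandible"),
    ("gn", "Gnathion", "Median point halfway between pg and me"),
    ("me", "Menton",
     "Most inferior median point of the mental symphysis (may not be the inferior point on the mandible "
     "as the chin is often clefted on the inferior margin)"),
    ("ge", "Genion", "Most projecting tip of the internal mental spine on the lingual surface of the mandible"),
]
_MANDIBULAR_BILATERAL = [
    ("col", "Condyle", "The most superior point of the mandibular condyle"),
    ("cdl", "Condylion laterale", "Most lateral point on the mandibular condyle"),
    ("cdm", "Condylion mediale", "Most medial point on the mandibular condyle"),
    ("go", "Gonion",
     "Point on the rounded margin of the angle of the mandible, bisecting two lines, one following vertical "
     "margin of ramus and one following horizontal margin of corpus of mandible"),
    ("ag", "Antegonion", "Apex of the antegonial notch"),
    ("ecm_l6", "Ectomolare L6",
     "Buccal alveolar margin; at the mesial buccal edge of the lower first molar position"),
    ("ml", "Mentale", "Most inferior point on the margin of the mandibular mental foramen"),
    ("lg", "Lingulare", "Superiormost point of the lingula of the mandible"),
    ("enm_l6", "Endomolare L6",
     "Lingual alveolar margin; at the mesial buccal edge of the lower first molar position."),
]
_TEETH_BILATERAL = [
    ("u1d", "Upper incisor distal", "The distal point of the incisal edge of the upper central incisor"),
    ("u1m", "Upper incisor mesial", "The mesial point of the incisal edge of the upper central incisor"),
    ("apu1", "Apex of U1", "The apex of the upper central incisor"),
    ("u3", "U3", "The cusp tip of upper canine"),
    ("u6", "U6", "The mesiobuccal cusp tip of the upper first molar"),
    ("l1d", "Lower incisor distal", "The distal point of the incisal edge of the lower central incisor"),
    ("l1m", "Lower incisor mesial", "The mesial point of the incisal edge of the lower central incisor"),
    ("apl1", "Apex of L1", "The apex of the lower central incisor"),
    ("l3", "L3", "The cusp tip of lower canine"),
    ("l6", "L6", "The mesiobuccal cusp tip of the lower first molar"),
]
_SOFT_MEDIAN = [
    ("g'", "Glabella",
     "Most anterior midline point on the forehead; in the region of the superciliary ridges"),
    ("n'", "Nasion", "Point directly anterior to the nasofrontal suture, in the midline, overlying n"),
    ("se'", "Sellion", "Deepest midline point of the nasofronal angle"),
    ("pn'", "Pronasale",
     "The most anteriorly protruded point of the apex nasi; in the case of a bifid nose, the more "
     "protruding tip is chosen"),
    ("sn'", "Subnasale",
     "Median point at the junction between the lower border of the nasal septum and the philtrum area"),
    ("c'", "Columella", "Midpoint of the nasal columella crest intersecting a line between the two cs' points"),
    ("ls'", "Labiale superius", "Midpoint of the vermilion border of the upper lip"),
    ("mp'", "Mid-philtrum", "Point midway between sn' and ls'; in the median plane"),
    ("sto'", "Stomion",
     "Midline point of the labial fissure when the lips are closed naturally with teeth shut in the "
     "natural position"),
    ("li'", "Labiale inferius", "Midpoint of the vermilion border of the lower lip"),
    ("sm'", "Supramentale", "Deepest midline point of the mentolabial sulcus"),
    ("me'", "Menton", "Most inferior median point of the chin"),
    ("pg'", "Pogonion",
     "Most anterior midpoint of the chin; located on the skin surface anterior to the identical bony "
     "landmark of the mandible"),
    ("gn'", "Gnathion", "Median point halfway between pg' and me'"),
]
# The printed definition of sbal' ("most inferior point of the earlobe")
# contradicts its anatomical name (Subalare, at the nasal alar base); the
# registry stores the schema text verbatim and the discrepancy is flagged in
# the documentation.  It has no computational impact: sbal' feeds no
# measurement parameter.
_SOFT_BILATERAL = [
    ("al'", "Alare", "The most lateral point on the nasal ala"),
    ("ma'", "Mid-alare", "Midpoint on the nasal alar where the ala thickness (not width) is measured"),
    ("ac'", "Alar curvature point",
     "The most posterolateral point of the curvature of the base line of each nasal ala"),
    ("sbal'", "Subalare", "Most inferior point of the earlobe"),
    ("mc'", "Mid-columella",
     "Midpoint of the nasal columella crest on either side where the columella thickness is measured"),
    ("cs'", "Columella superius",
     "Most superior point on each columella crest of the nose; level with the top of the corresponding nostril"),
    ("vs'", "Vermilion superius",
     "Most superior point of the vermilion border of the upper lip at its apex on either side"),
    ("ch'", "Cheilion",
     "Outer corners of the mouth where the outer edges of the upper and lower vermilions meet"),
    ("vi'", "Vermilion inferius",
     "Most inferolateral point of the vermilion border of the lower lip at the maximum curve change on either side"),
    ("obs'", "Otobasion superius",
     "Most superior point of attachment of the ear helix to the temporal region of the head"),
    ("t'", "Tragion",
     "Located at the notch above the tragus of the ear (the cartilaginous projection anterior to the external "
     "auditory canal) where the upper edge of the cartilage disappears into the skin of the face"),
    ("it'", "Intertragion", "Apex of groove between the tragus and antitragus"),
    ("obi'", "Otobasion inferius", "Most inferior point of attachment of the ear lobe with the cheek"),
    ("ps'", "Palpebrale superius", "Most superior point on the margin of the upper eyelid"),
    ("en'", "Endocanthion",
     "Most medial point of the palpebral fissure; at the inner commissure of the eye; best seen when "
     "subject is gazing upward"),
    ("ex'", "Exocanthion",
     "Most lateral point of the palpebral fissure; at the outer commissure of the eye; best seen when "
     "subject is gazing upward"),
    ("zy'", "Zygion",
     "Most lateral point overlying each zygomatic arch; identified as the point of maximum bizygomatic "
     "breadth of the face"),
]
_AIRWAY_MEDIAN = [
    # alv(PNS) is defined in the cranial block and shared into this region.
    ("u", "Uvula", "The tip of uvula"),
    ("h", "Hyoid", "The superior anterior median point of hyoid"),
    ("c3", "C3 anterius inferius", "The inferior anterior median point of the third cervix"),
    ("c2", "C2 anterius inferius", "The inferior anterior median point of the second cervix"),
    ("epi", "Epiglottis", "Most inferior point of epiglottic vallecula"),
]


@dataclass(frozen=True)
class LandmarkRegistry:
    """Ordered, immutable collection of landmark definitions."""

    defs: tuple

    def __post_init__(self):
        names = [d.name for d in self.defs]
        if len(names) != len(set(names)):
            raise ValueError("registry names are not unique")

    def __len__(self) -> int:
        return len(self.defs)

    def __iter__(self):
        return iter(self.defs)

    def __contains__(self, name: str) -> bool:
        return name in self.by_name()

    def by_name(self) -> dict:
        return {d.name: d for d in self.defs}

    @property
    def names(self) -> tuple:
        return tuple(d.name for d in self.defs)

    def region(self, region: str) -> tuple:
        """All defs counted in ``region``, including shared membership."""
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return tuple(d for d in self.defs if region in d.regions)

    def region_counts(self) -> dict:
        return {r: len(self.region(r)) for r in REGIONS}


def _expand(rows, region, laterality, shared=()):
    out = []
    for code, long_name, text in rows:
        if laterality == "median":
            out.append(LandmarkDef(code, long_name, region, "median", text,
                                   frozenset(shared)))
        else:
            for suffix, side in (("_L", "left"), ("_R", "right")):
                out.append(LandmarkDef(code + suffix, long_name, region, side, text))
    return out


def build_registry() -> LandmarkRegistry:
    """Construct the full 126-landmark registry.

    Ordering is deterministic: region blocks in anatomical order, median
    points before bilateral ones, and ``_L`` before ``_R`` within a pair.
    """
    defs = []
    for code, long_name, text in _CRANIAL_MEDIAN:
        shared = ("airway",) if code == "alv(PNS)" else ()
        defs.append(LandmarkDef(code, long_name, "cranial", "median", text, frozenset(shared)))
    defs += _expand(_CRANIAL_BILATERAL, "cranial", "bilateral")
    defs += _expand(_MANDIBULAR_MEDIAN, "mandibular", "median")
    defs += _expand(_MANDIBULAR_BILATERAL, "mandibular", "bilateral")
    defs += _expand(_TEETH_BILATERAL, "teeth", "bilateral")
    defs += _expand(_SOFT_MEDIAN, "soft_tissue", "median")
    defs += _expand(_SOFT_BILATERAL, "soft_tissue", "bilateral")
    defs += _expand(_AIRWAY_MEDIAN, "airway", "median")
    return LandmarkRegistry(tuple(defs))


@dataclass
class LandmarkSet:
    """One labeling session: landmark name -> LPS point (mm).

    A session may be incomplete; consumers declare the landmarks they need
    and handle absences explicitly.  ``extras`` holds points whose names are
    not in the registry (kept for round-tripping, never measured).
    """

    points: dict
    subject_id: str = ""
    examiner_id: str = ""
    session_id: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r}: invalid point {p!r}")
            self.points[name] = arr

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> Point3:
        return self.points[name]

    def __len__(self) -> int:
        return len(self.points)

    def get(self, name: str, default=None):
        return self.points.get(name, default)

    def missing(self, required: Iterable[str]) -> list:
        return sorted(set(required) - set(self.points))

    def coordinates(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else list(self.points)
        return np.array([self.points[n] for n in names])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "LandmarkSet":
        """Return a copy with ``x -> scale * R x + t`` applied to every point."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        pts = {k: scale * (R @ v) + t for k, v in self.points.items()}
        return replace(self, points=pts, extras=dict(self.extras))

    def mirrored(self, plane_origin: np.ndarray, plane_normal: np.ndarray) -> "LandmarkSet":
        """Reflect every point through a plane and swap ``_L``/``_R`` names."""
        o = np.asarray(plane_origin, dtype=float)
        nrm = np.asarray(plane_normal, dtype=float)
        nrm = nrm / np.linalg.norm(nrm)

        def refl(x):
            return x - 2.0 * np.dot(x - o, nrm) * nrm

        def swap(name):
            if name.endswith("_L"):
                return name[:-2] + "_R"
            if name.endswith("_R"):
                return name[:-2] + "_L"
            return name

        pts = {swap(k): refl(v) for k, v in self.points.items()}
        return replace(self, points=pts, extras=dict(self.extras))


def swap_lr_name(name: str) -> str:
    if name.endswith("_L"):
        return name[:-2] + "_R"
    if name.endswith("_R"):
        return name[:-2] + "_L"
    return name
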