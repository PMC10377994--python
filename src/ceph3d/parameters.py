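"""The measurement-parameter registry and its evaluator.

78 parameters in three sets: 42 skeletal (23 angular, 19 linear), 27 soft
tissue (9 angular, 18 linear) and 9 upper-airway (2 linear, 4 areal, 3
voluminal).  The registry is data-driven -- each row declares its required
landmarks, the planes it uses and a small formula closure over the
geometric kernel -- so invariance suites can iterate the whole table
generically and each definition stays auditable in one place.

Conventions (printed in every report header):

* "Distance to plane" midline offsets (Pg-SP, U1-SP, L1-SP, pg'-SP) are
  absolute values; profile distances to TVL are signed, anterior positive.
* "Difference in distance" rows are signed differences of signed plane
  distances: positive Overbite means the upper incisal edge is inferior to
  the lower (vertical overlap); positive Overjet means it is anterior.
* Canting angles are signed, positive when the left point of the pair is
  superior; Maxillary Yawing is signed, positive when the anterior end
  deviates to the left; Condyle Yaw is signed, positive when the lateral
  condylar pole is anterior to the medial pole.
* Incisor axes run from the incisal-edge midpoint (u1 / l1, the centroid of
  the four edge points) to the root-apex midpoint.
* Three-point angles lie in [0, 180] degrees; line-line angles in [0, 90]
  unless a signed convention above applies; g'-sn'-pg' reports the
  supplementary angle whenever the raw angle is obtuse, so it is acute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geo
from .config import RunConfig
from .errors import Ceph3dError
from .geometry import ReferencePlaneSet
from .landmarks import LandmarkSet, build_registry

PARAMETER_SETS = ("skeletal", "soft_tissue", "airway")
SUBTYPES = ("angular", "linear", "areal", "voluminal")
_UNITS = {"angular": "deg", "linear": "mm", "areal": "mm^2", "voluminal": "mm^3"}


@dataclass(frozen=True)
class ParameterDefinition:
    name: str
    set: str
    subtype: str
    required_landmarks: tuple
    required_planes: tuple
    fn: object = None  # callable(EvalContext) -> float; None for airway rows
    units: str = ""

    def __post_init__(self):
        if not self.units:
            object.__setattr__(self, "units", _UNITS[self.subtype])


@dataclass
class MeasurementValue:
    parameter: str
    value: float | None
    units: str
    set: str
    subtype: str
    subject_id: str = ""
    examiner_id: str = ""
    session_id: str = ""
    missing_reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.value is None


class EvalContext:
    """Bundles one session, its reference planes and the run configuration."""

    def __init__(self, lset: LandmarkSet, planes: ReferencePlaneSet,
                 config: RunConfig | None = None):
        self.lset = lset
        self.planes = planes
        self.cfg = config or RunConfig()

    def p(self, name):
        return self.lset[name]

    def mid(self, *names):
        return geo.midpoint(*(self.lset[n] for n in names))

    # footnote midpoints: incisal edges and root apices, upper and lower
    def u1(self):
        return self.mid("u1d_L", "u1d_R", "u1m_L", "u1m_R")

    def apu(self):
        return self.mid("apu1_L", "apu1_R")

    def l1(self):
        return self.mid("l1d_L", "l1d_R", "l1m_L", "l1m_R")

    def apl(self):
        return self.mid("apl1_L", "apl1_R")


# ---------------------------------------------------------------- formulas

def _ang3(a, b, c):
    return lambda ctx: geo.angle_at_vertex_projected(
        ctx.p(a), ctx.p(b), ctx.p(c), ctx.planes.sp)


def _line_line_sp(pair1, pair2):
    return lambda ctx: geo.angle_between_lines_projected(
        (ctx.p(pair1[0]), ctx.p(pair1[1])),
        (ctx.p(pair2[0]), ctx.p(pair2[1])), ctx.planes.sp)


def _line_plane_sp(pair, plane_label):
    return lambda ctx: geo.angle_between_lines_projected(
        (ctx.p(pair[0]), ctx.p(pair[1])), ctx.planes[plane_label], ctx.planes.sp)


def _plane_plane_sp(label1, label2):
    return lambda ctx: geo.angle_between_lines_projected(
        ctx.planes[label1], ctx.planes[label2], ctx.planes.sp)


def _canting(code):
    return lambda ctx: geo.signed_canting_deg(
        ctx.p(f"{code}_L"), ctx.p(f"{code}_R"), ctx.planes)


def _dist(a, b):
    return lambda ctx: geo.distance(ctx.p(a), ctx.p(b))


def _dist_sp_proj(a, b):
    return lambda ctx: geo.distance_projected(ctx.p(a), ctx.p(b), ctx.planes.sp)


def _abs_dist_sp(name):
    return lambda ctx: abs(geo.signed_distance(ctx.planes.sp, ctx.p(name)))


def _tvl(name):
    # signed: the TVL normal points anterior, so protrusion is positive
    return lambda ctx: geo.signed_distance(ctx.planes.tvl, ctx.p(name))


def _height_diff(upper, lower):
    """Signed difference of superior plane distances: positive when the
    first point is superior to the second."""
    def fn(ctx):
        a = upper(ctx) if callable(upper) else ctx.p(upper)
        b = lower(ctx) if callable(lower) else ctx.p(lower)
        return geo.signed_distance(ctx.planes.hp, a) - geo.signed_distance(ctx.planes.hp, b)
    return fn


def _anb(ctx):
    if ctx.cfg.anb_signed:
        sna = geo.angle_at_vertex_projected(ctx.p("s"), ctx.p("n"), ctx.p("ss(A)"), ctx.planes.sp)
        snb = geo.angle_at_vertex_projected(ctx.p("s"), ctx.p("n"), ctx.p("sm(B)"), ctx.planes.sp)
        return sna - snb
    return geo.angle_at_vertex_projected(ctx.p("ss(A)"), ctx.p("n"), ctx.p("sm(B)"), ctx.planes.sp)


def _interincisal(ctx):
    return geo.angle_between_lines_projected(
        (ctx.u1(), ctx.apu()), (ctx.l1(), ctx.apl()), ctx.planes.sp)


def _u1_sn(ctx):
    return geo.angle_between_lines_projected(
        (ctx.p("s"), ctx.p("n")), (ctx.u1(), ctx.apu()), ctx.planes.sp)


def _l1_apg(ctx):
    return geo.angle_between_lines_projected(
        (ctx.p("ss(A)"), ctx.p("pg")), (ctx.l1(), ctx.apl()), ctx.planes.sp)


def _l1_mp(ctx):
    return geo.angle_between_lines_projected(
        (ctx.l1(), ctx.apl()), ctx.planes.mp, ctx.planes.sp)


def _maxillary_yaw(ctx):
    return geo.signed_yaw_deg(ctx.p("a(ANS)"), ctx.p("alv(PNS)"), ctx.planes)


def _condyle_yaw(side):
    suffix = "_L" if side == "left" else "_R"
    return lambda ctx: geo.signed_condyle_yaw_deg(
        ctx.p("cdl" + suffix), ctx.p("cdm" + suffix), side, ctx.planes)


def _arch_height(ctx):
    plane = geo.Plane.from_points(ctx.p("ale"), ctx.p("ecm_u6_L"), ctx.p("ecm_u6_R"))
    return abs(geo.signed_distance(plane, ctx.mid("a(ANS)", "alv(PNS)")))


def _arch_length(ctx):
    return geo.distance(ctx.p("ale"), ctx.mid("ecm_u6_L", "ecm_u6_R"))


def _g_sn_pg(ctx):
    ang = geo.angle_at_vertex_projected(ctx.p("g'"), ctx.p("sn'"), ctx.p("pg'"), ctx.planes.sp)
    return 180.0 - ang if ang > 90.0 else ang


def _eye_canting(ctx):
    left = ctx.mid("en'_L", "ex'_L")
    right = ctx.mid("en'_R", "ex'_R")
    return geo.signed_canting_deg(left, right, ctx.planes)


def _t_mid_angle(apex2):
    def fn(ctx):
        tmid = ctx.mid("t'_L", "t'_R")
        return geo.angle_at_vertex_projected(tmid, ctx.p("n'"), ctx.p(apex2), ctx.planes.sp)
    return fn


_UPPER_AXIS_PTS = ("u1d_L", "u1d_R", "u1m_L", "u1m_R", "apu1_L", "apu1_R")
_LOWER_AXIS_PTS = ("l1d_L", "l1d_R", "l1m_L", "l1m_R", "apl1_L", "apl1_R")
_U1_PTS = ("u1d_L", "u1d_R", "u1m_L", "u1m_R")
_L1_PTS = ("l1d_L", "l1d_R", "l1m_L", "l1m_R")

AIRWAY_PARAMETER_NAMES = (
    "H-MP|^d", "H-C|^d",
    "Airway, Mean|^a", "Velopharynx, Mean|^a", "Glossopharynx, Mean|^a",
    "Airway, Min|^a",
    "Airway|^v", "Velopharynx|^v", "Glossopharynx|^v",
)


def build_parameter_registry() -> tuple:
    """All 78 parameter definitions in table order."""
    rows = []

    def add(name, pset, subtype, landmarks, planes, fn):
        rows.append(ParameterDefinition(name, pset, subtype, tuple(landmarks),
                                        tuple(planes), fn))

    # ---- skeletal, angular (23)
    add("SNA|°", "skeletal", "angular", ("s", "n", "ss(A)"), ("SP",), _ang3("s", "n", "ss(A)"))
    add("SNB|°", "skeletal", "angular", ("s", "n", "sm(B)"), ("SP",), _ang3("s", "n", "sm(B)"))
    add("ANB|°", "skeletal", "angular", ("s", "n", "ss(A)", "sm(B)"), ("SP",), _anb)
    add("NAPg|°", "skeletal", "angular", ("n", "ss(A)", "pg"), ("SP",), _ang3("n", "ss(A)", "pg"))
    add("NSBa|°", "skeletal", "angular", ("n", "s", "ba"), ("SP",), _ang3("n", "s", "ba"))
    add("SN-ANSPNS|°", "skeletal", "angular", ("s", "n", "a(ANS)", "alv(PNS)"), ("SP",),
        _line_line_sp(("s", "n"), ("a(ANS)", "alv(PNS)")))
    add("FMA|°", "skeletal", "angular", ("gn", "go_L", "go_R"), ("FH", "MP", "SP"),
        _plane_plane_sp("FH", "MP"))
    add("Interincisal Angle|°", "skeletal", "angular", _UPPER_AXIS_PTS + _LOWER_AXIS_PTS,
        ("SP",), _interincisal)
    add("AB-NPg|°", "skeletal", "angular", ("ss(A)", "sm(B)", "n", "pg"), ("SP",),
        _line_line_sp(("ss(A)", "sm(B)"), ("n", "pg")))
    add("U1-SN|°", "skeletal", "angular", ("s", "n") + _UPPER_AXIS_PTS, ("SP",), _u1_sn)
    add("L1-APg|°", "skeletal", "angular", ("ss(A)", "pg") + _LOWER_AXIS_PTS, ("SP",), _l1_apg)
    add("Maxillary Yawing|°", "skeletal", "angular", ("a(ANS)", "alv(PNS)"), ("SP", "HP"),
        _maxillary_yaw)
    add("Mastoideus Canting|°", "skeletal", "angular", ("ms_L", "ms_R"), ("HP", "CP"),
        _canting("ms"))
    add("U6 Canting|°", "skeletal", "angular", ("u6_L", "u6_R"), ("HP", "CP"), _canting("u6"))
    add("U3 Canting|°", "skeletal", "angular", ("u3_L", "u3_R"), ("HP", "CP"), _canting("u3"))
    add("Go Canting|°", "skeletal", "angular", ("go_L", "go_R"), ("HP", "CP"), _canting("go"))
    add("Y-axis|°", "skeletal", "angular", ("gn", "s"), ("FH", "SP"),
        _line_plane_sp(("gn", "s"), "FH"))
    add("OP Tipping|°", "skeletal", "angular",
        ("u1d_L", "u1d_R", "u1m_L", "u1m_R", "u6_L", "u6_R"), ("OP", "HP", "SP"),
        _plane_plane_sp("OP", "HP"))
    add("Facial Angle|°", "skeletal", "angular", ("n", "pg"), ("FH", "SP"),
        _line_plane_sp(("n", "pg"), "FH"))
    add("SN-MP|°", "skeletal", "angular", ("s", "n", "gn", "go_L", "go_R"), ("MP", "SP"),
        _line_plane_sp(("s", "n"), "MP"))
    add("L1-MP|°", "skeletal", "angular", ("gn", "go_L", "go_R") + _LOWER_AXIS_PTS,
        ("MP", "SP"), _l1_mp)
    add("Condyle Yaw L|°", "skeletal", "angular", ("cdl_L", "cdm_L"), ("SP", "HP"),
        _condyle_yaw("left"))
    add("Condyle Yaw R|°", "skeletal", "angular", ("cdl_R", "cdm_R"), ("SP", "HP"),
        _condyle_yaw("right"))

    # ---- skeletal, linear (19)
    add("Pg-SP|^d", "skeletal", "linear", ("pg",), ("SP",), _abs_dist_sp("pg"))
    add("U1-SP|^d", "skeletal", "linear", _U1_PTS, ("SP",),
        lambda ctx: abs(geo.signed_distance(ctx.planes.sp, ctx.u1())))
    add("L1-SP|^d", "skeletal", "linear", _L1_PTS, ("SP",),
        lambda ctx: abs(geo.signed_distance(ctx.planes.sp, ctx.l1())))
    add("Dental Arch Width ex6, Upper|^d", "skeletal", "linear", ("ecm_u6_L", "ecm_u6_R"),
        (), _dist("ecm_u6_L", "ecm_u6_R"))
    add("Dental Arch Length ex6, Upper|^d", "skeletal", "linear",
        ("ale", "ecm_u6_L", "ecm_u6_R"), (), _arch_length)
    add("Dental Arch Height ex6, Upper|^d", "skeletal", "linear",
        ("a(ANS)", "alv(PNS)", "ale", "ecm_u6_L", "ecm_u6_R"), (), _arch_height)
    add("Mandibular Body Length L|^d", "skeletal", "linear", ("ml_L", "lg_L"), (),
        _dist("ml_L", "lg_L"))
    add("Mandibular Body Length R|^d", "skeletal", "linear", ("ml_R", "lg_R"), (),
        _dist("ml_R", "lg_R"))
    add("AgL-AgR|^d", "skeletal", "linear", ("ag_L", "ag_R"), (), _dist("ag_L", "ag_R"))
    add("GoL-GoR|^d", "skeletal", "linear", ("go_L", "go_R"), (), _dist("go_L", "go_R"))
    add("JuL-JuR|^d", "skeletal", "linear", ("ju_L", "ju_R"), (), _dist("ju_L", "ju_R"))
    add("ZmL-ZmR|^d", "skeletal", "linear", ("zm_L", "zm_R"), (), _dist("zm_L", "zm_R"))
    add("ZyL-ZyR|^d", "skeletal", "linear", ("zy_L", "zy_R"), (), _dist("zy_L", "zy_R"))
    add("Piriform Apertura Width|^d", "skeletal", "linear", ("al_L", "al_R"), (),
        _dist("al_L", "al_R"))
    add("Overbite|^d", "skeletal", "linear", _U1_PTS + _L1_PTS, ("HP",),
        _height_diff(lambda ctx: ctx.l1(), lambda ctx: ctx.u1()))
    add("Overjet|^d", "skeletal", "linear", _U1_PTS + _L1_PTS, ("CP",),
        lambda ctx: geo.signed_distance(ctx.planes.cp, ctx.u1())
        - geo.signed_distance(ctx.planes.cp, ctx.l1()))
    add("N-Me|^d", "skeletal", "linear", ("n", "me"), ("SP",), _dist_sp_proj("n", "me"))
    add("Gn-A|^d", "skeletal", "linear", ("gn", "ss(A)"), ("SP",), _dist_sp_proj("gn", "ss(A)"))
    add("N-ANS|^d", "skeletal", "linear", ("n", "a(ANS)"), ("SP",), _dist_sp_proj("n", "a(ANS)"))

    # ---- soft tissue, angular (9)
    add("t'-n'-mp'|°", "soft_tissue", "angular", ("t'_L", "t'_R", "n'", "mp'"), ("SP",),
        _t_mid_angle("mp'"))
    add("t'-n'-sm'|°", "soft_tissue", "angular", ("t'_L", "t'_R", "n'", "sm'"), ("SP",),
        _t_mid_angle("sm'"))
    add("Mouth Canting|°", "soft_tissue", "angular", ("ch'_L", "ch'_R"), ("HP", "CP"),
        _canting("ch'"))
    add("Nasolabial Angle|°", "soft_tissue", "angular", ("c'", "sn'", "ls'"), ("SP",),
        _ang3("c'", "sn'", "ls'"))
    add("Upper Lip Angle|°", "soft_tissue", "angular", ("ls'", "sn'"), ("CP", "SP"),
        _line_plane_sp(("ls'", "sn'"), "CP"))
    add("g'-sn'-pg'|°", "soft_tissue", "angular", ("g'", "sn'", "pg'"), ("SP",), _g_sn_pg)
    add("g'-se'-pn'|°", "soft_tissue", "angular", ("g'", "se'", "pn'"), ("SP",),
        _ang3("g'", "se'", "pn'"))
    add("Eyelid Canting|°", "soft_tissue", "angular", ("ps'_L", "ps'_R"), ("HP", "CP"),
        _canting("ps'"))
    add("Eye Canting|°", "soft_tissue", "angular", ("en'_L", "en'_R", "ex'_L", "ex'_R"),
        ("HP", "CP"), _eye_canting)

    # ---- soft tissue, linear (18)
    add("n'-mp'|^d", "soft_tissue", "linear", ("n'", "mp'"), ("SP",), _dist_sp_proj("n'", "mp'"))
    add("n'-sm'|^d", "soft_tissue", "linear", ("n'", "sm'"), ("SP",), _dist_sp_proj("n'", "sm'"))
    add("mp'-sm'|^d", "soft_tissue", "linear", ("mp'", "sm'"), ("SP",), _dist_sp_proj("mp'", "sm'"))
    add("pn'-sn'|^d", "soft_tissue", "linear", ("pn'", "sn'"), ("SP",), _dist_sp_proj("pn'", "sn'"))
    add("Upper Lip Length|^d", "soft_tissue", "linear", ("sn'", "sto'"), ("SP",),
        _dist_sp_proj("sn'", "sto'"))
    add("Upper Vermilion Width|^d", "soft_tissue", "linear", ("ls'", "sto'"), ("SP",),
        _dist_sp_proj("ls'", "sto'"))
    add("pg'-SP|^d", "soft_tissue", "linear", ("pg'",), ("SP",), _abs_dist_sp("pg'"))
    add("U1 exposure|^d", "soft_tissue", "linear", _U1_PTS + ("sto'",), ("HP",),
        _height_diff("sto'", lambda ctx: ctx.u1()))
    add("Lower 1/3 Height|^d", "soft_tissue", "linear", ("sn'", "me'"), ("HP",),
        _height_diff("sn'", "me'"))
    add("Facial Height_n'|^d", "soft_tissue", "linear", ("n'", "me'"), ("HP",),
        _height_diff("n'", "me'"))
    add("Inner Canthic Diameter|^d", "soft_tissue", "linear", ("en'_L", "en'_R"), (),
        _dist("en'_L", "en'_R"))
    for code in ("g'", "pn'", "mp'", "li'", "sm'", "pg'", "gn'"):
        add(f"{code}-TVL|^d", "soft_tissue", "linear", (code, "sn'"), ("TVL",), _tvl(code))

    # ---- airway (9): evaluated in one pass by the airway module
    add("H-MP|^d", "airway", "linear", ("h", "gn", "go_L", "go_R"), ("MP",), None)
    add("H-C|^d", "airway", "linear", ("h", "c2", "c3"), (), None)
    for name in ("Airway, Mean|^a", "Velopharynx, Mean|^a", "Glossopharynx, Mean|^a",
                 "Airway, Min|^a"):
        add(name, "airway", "areal", ("alv(PNS)", "u", "c3"), ("FH",), None)
    for name in ("Airway|^v", "Velopharynx|^v", "Glossopharynx|^v"):
        add(name, "airway", "voluminal", ("alv(PNS)", "u", "c3"), ("FH",), None)

    return tuple(rows)


def registry_closure_check(param_registry=None) -> None:
    """Assert every required landmark name exists in the landmark registry."""
    lm_names = set(build_registry().names)
    for defn in param_registry or build_parameter_registry():
        unknown = set(defn.required_landmarks) - lm_names
        if unknown:
            raise ValueError(f"{defn.name}: unknown landmarks {sorted(unknown)}")


def evaluate(defn: ParameterDefinition, lset: LandmarkSet,
             planes: ReferencePlaneSet, airway_mesh=None,
             config: RunConfig | None = None,
             _airway_values: dict | None = None) -> MeasurementValue:
    """Evaluate one parameter; absences and degeneracies become missing
    markers with a reason, never exceptions."""
    config = config or RunConfig()
    base = dict(parameter=defn.name, units=defn.units, set=defn.set,
                subtype=defn.subtype, subject_id=lset.subject_id,
                examiner_id=lset.examiner_id, session_id=lset.session_id)
    missing = lset.missing(defn.required_landmarks)
    if missing:
        return MeasurementValue(value=None, missing_reason=f"{', '.join(missing)} absent",
                                **base)
    if defn.set == "airway":
        if _airway_values is not None and defn.name in _airway_values:
            return MeasurementValue(value=float(_airway_values[defn.name]), **base)
        if airway_mesh is None:
            return MeasurementValue(value=None, missing_reason="airway mesh absent", **base)
        from .airway import airway_parameters
        try:
            values = airway_parameters(airway_mesh, lset, planes, config=config)
        except Ceph3dError as exc:
            return MeasurementValue(value=None, missing_reason=str(exc), **base)
        return MeasurementValue(value=float(values[defn.name]), **base)
    try:
        value = float(defn.fn(EvalContext(lset, planes, config)))
    except Ceph3dError as exc:
        return MeasurementValue(value=None, missing_reason=str(exc), **base)
    if not np.isfinite(value):
        return MeasurementValue(value=None, missing_reason="non-finite result", **base)
    return MeasurementValue(value=value, **base)


def evaluate_all(lset: LandmarkSet, planes: ReferencePlaneSet,
                 airway_mesh=None, config: RunConfig | None = None,
                 registry=None) -> list:
    """One MeasurementValue per registry row, in stable table order.

    Per-parameter failures are recorded as missing markers; the batch never
    aborts.  The nine airway rows are computed in a single mesh pass.
    """
    config = config or RunConfig()
    registry = registry or build_parameter_registry()
    airway_values = None
    if airway_mesh is not None:
        needed = ("alv(PNS)", "u", "h", "c2", "c3", "gn", "go_L", "go_R")
        if not lset.missing(needed):
            from .airway import airway_parameters
            try:
                airway_values = airway_parameters(airway_mesh, lset, planes, config=config)
            except Ceph3dError:
                airway_values = None
    return [evaluate(defn, lset, planes, airway_mesh=airway_mesh, config=config,
                     _airway_values=airway_values) for defn in registry]


def measurements_to_frame(values) -> pd.DataFrame:
    """Long-format table of measurement values."""
    return pd.DataFrame([{
        "subject": v.subject_id, "examiner": v.examiner_id, "session": v.session_id,
        "parameter": v.parameter, "set": v.set, "subtype": v.subtype,
        "value": v.value, "units": v.units, "missing_reason": v.missing_reason,
    } for v in values])


def registry_to_frame(registry=None) -> pd.DataFrame:
    """Dump the parameter registry for audit."""
    return pd.DataFrame([{
        "parameter": d.name, "set": d.set, "subtype": d.subtype, "units": d.units,
        "required_landmarks": ";".join(d.required_landmarks),
        "required_planes": ";".join(d.required_planes),
    } for d in (registry or build_parameter_registry())])
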