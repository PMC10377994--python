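"""Rater-reliability analysis: ICC(A,1) with 95% CI, classification, flags.

The agreement statistic is the single-measurement, absolute-agreement,
two-way random-effects intraclass correlation -- ICC(2,1) in the
Shrout-Fleiss numbering, ICC(A,1) in McGraw-Wong.  With ``n`` subjects and
``k`` raters and the two-way ANOVA mean squares MSR (subjects), MSC
(raters) and MSE (residual),

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

and the 95% confidence interval uses the F-based construction with
Satterthwaite degrees of freedom for the rater term.  Estimates can be
negative and are reported as computed, never truncated.

Classification bands: ICC < 0.5 poor, 0.5-0.75 (inclusive) moderate,
(0.75, 0.9] good, > 0.9 excellent.  Two flagging conditions mark
potentially unreliable quantities: condition 1 -- the ICC itself is below
0.75; condition 2 -- the ICC is at least 0.75 but the lower 95% bound falls
below 0.50.  The two are mutually exclusive by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .config import RunConfig
from .errors import UndefinedICCError
from .geometry import build_reference_planes
from .landmarks import LandmarkSet, build_registry
from .parameters import build_parameter_registry, evaluate_all

log = logging.getLogger(__name__)

CLASSIFICATIONS = ("poor", "moderate", "good", "excellent")
FLAG_ICC_BELOW = "condition1_icc_below_0.75"
FLAG_CI_BELOW = "condition2_lower_ci_below_0.50"


@dataclass
class RatingsMatrix:
    """``n`` subjects x ``k`` raters of one quantity, complete cases only."""

    quantity: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D subjects x raters array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >=2 subjects and >=2 raters, got {n}x{k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings contain non-finite entries")


@dataclass
class ICCResult:
    quantity: str
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    ms_rows: float
    ms_cols: float
    ms_err: float
    classification: str = ""
    flags: frozenset = field(default_factory=frozenset)
    ci_note: str = ""

    def __post_init__(self):
        if not self.classification:
            self.classification = classify_icc(self.icc)
        if not self.flags:
            self.flags = flag_result(self)


def _mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(matrix: RatingsMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) point estimate with a 100(1-alpha)% confidence interval.

    Raises :class:`UndefinedICCError` when the ratings carry no variance at
    all (the ratio is then 0/0 and carries no information).
    """
    x = matrix.values
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    scale = max(1.0, float(np.abs(x).max()) ** 2)
    if msr + msc + mse < 1e-14 * scale:
        raise UndefinedICCError(
            f"{matrix.quantity}: all ratings identical; ICC undefined "
            "(zero between-subject and zero within-subject variance)")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-14 * scale:
        raise UndefinedICCError(f"{matrix.quantity}: degenerate variance structure")
    icc = (msr - mse) / denom

    if mse < 1e-14 * scale and msc < 1e-14 * scale:
        # perfect agreement: every rater reproduces every subject exactly
        return ICCResult(matrix.quantity, 1.0, 1.0, 1.0, n, k, msr, msc, mse)

    # F-based interval with Satterthwaite df for the combined rater/error
    # term (the standard absolute-agreement, single-score construction)
    r = icc
    if mse < 1e-14 * scale:
        v = k - 1.0  # limit of the Satterthwaite df as MSE -> 0
    else:
        fj = msc / mse
        with np.errstate(all="ignore"):
            vn = (n - 1) * (k - 1) * (k * r * fj + n * (1 + (k - 1) * r) - k * r) ** 2
            vd = (n - 1) * k**2 * r**2 * fj**2 + (n * (1 + (k - 1) * r) - k * r) ** 2
            v = vn / vd
        # v may be fractional, even below 1 for negative estimates; 0/0 or
        # inf/inf arise only in degenerate layouts, where the residual df
        # is the natural fallback
        if not np.isfinite(v) or v <= 0:
            v = (n - 1.0) * (k - 1.0)
    f_l = f_dist.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = f_dist.ppf(1.0 - alpha / 2.0, v, n - 1)
    with np.errstate(all="ignore"):
        lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse)
                                        + n * msr)
        upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse
                                         + n * f_u * msr)
    if not np.isfinite(lower):  # limit of the expression as f_l -> inf
        lower = -n * mse / (k * msc + (k * n - k - n) * mse)
    if not np.isfinite(upper):  # limit as f_u -> inf
        upper = 1.0

    # the approximation can cross the point estimate at the edges
    note = ""
    if lower > icc or upper < icc:
        note = "ci clipped to contain the point estimate"
        lower, upper = min(lower, icc), max(upper, icc)
    upper = min(upper, 1.0)
    return ICCResult(matrix.quantity, float(icc), float(lower), float(upper),
                     n, k, float(msr), float(msc), float(mse), ci_note=note)


def classify_icc(icc: float) -> str:
    """Four-band reliability label; boundaries 0.5 and 0.75 fall in the
    moderate band, 0.9 in good, per the inclusive reading of the bands."""
    if icc < 0.5:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def flag_result(r: ICCResult) -> frozenset:
    """The two-condition marking of potentially unreliable quantities."""
    if r.icc < 0.75:
        return frozenset({FLAG_ICC_BELOW})
    if r.ci_low < 0.50:
        return frozenset({FLAG_CI_BELOW})
    return frozenset()


# ----------------------------------------------------------------- study

AXES = ("L", "P", "S")


@dataclass
class ReliabilityReport:
    """Per-landmark-axis and per-parameter ICC tables.

    ``landmark_table`` has one row per (region-block landmark, axis,
    condition) -- the shared posterior-nasal-spine point appears in both its
    cranial and airway blocks, giving 127 landmark rows per axis.
    ``parameter_table`` has one row per (parameter, condition).  Conditions
    are ``inter`` plus one ``examiner:<id>`` per examiner.
    """

    landmark_table: pd.DataFrame
    parameter_table: pd.DataFrame
    n_subjects_used: int = 0
    n_subjects_dropped: int = 0


def _result_row(base: dict, values_by_subject: dict, quantity: str) -> dict:
    """Complete-case ICC over a subject -> list-of-rater-values mapping."""
    rows = [v for v in values_by_subject.values()
            if all(x is not None and np.isfinite(x) for x in v)]
    base = dict(base)
    base.update(icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                n=len(rows), k=0, classification="", flags="", note="")
    if len(rows) < 2:
        base["note"] = "fewer than 2 complete subjects"
        return base
    matrix = np.array(rows, dtype=float)
    base["k"] = matrix.shape[1]
    try:
        res = icc_a1(RatingsMatrix(quantity, matrix))
    except UndefinedICCError:
        base["note"] = "undefined (zero variance)"
        return base
    base.update(icc=res.icc, ci_low=res.ci_low, ci_high=res.ci_high,
                classification=res.classification, flags=";".join(sorted(res.flags)))
    return base


def reliability_study(manifest: dict, meshes: dict | None = None,
                      config: RunConfig | None = None,
                      include_parameters: bool = True,
                      landmark_filter=None) -> ReliabilityReport:
    """Run the full two-examiner, two-session reliability analysis.

    Parameters
    ----------
    manifest
        Mapping ``(subject, examiner, session) -> LandmarkSet``.  Subjects
        missing any (examiner, session) cell are dropped (complete-case)
        with a logged count.  Two examiners and two sessions are the
        expected design; more raters are handled generically.
    meshes
        Optional ``subject -> AirwayMesh`` for the airway parameters.
    include_parameters
        Skip parameter evaluation (landmark coordinates only) when False.
    landmark_filter
        Optional collection of landmark names to restrict the landmark
        table to (used for large simulation studies).

    Intra-examiner ICC treats one examiner's sessions as raters; the
    inter-examiner ICC treats examiners as raters, each represented by the
    mean of their sessions (``config.inter_mode`` selects the alternative
    literal readings ``first_sessions`` and ``all_four``).
    """
    config = config or RunConfig()
    meshes = meshes or {}
    subjects = sorted({key[0] for key in manifest})
    examiners = sorted({key[1] for key in manifest})
    sessions = sorted({key[2] for key in manifest})
    complete = [s for s in subjects
                if all((s, e, ses) in manifest for e in examiners for ses in sessions)]
    dropped = len(subjects) - len(complete)
    if dropped:
        log.info("dropped %d subject(s) with incomplete sessions", dropped)
    if len(complete) < 2:
        raise ValueError("need at least 2 complete subjects")

    registry = build_registry()
    lm_names = [d.name for d in registry]
    if landmark_filter is not None:
        keep = set(landmark_filter)
        lm_names = [nm for nm in lm_names if nm in keep]

    param_registry = build_parameter_registry() if include_parameters else ()
    param_values = {}
    if include_parameters:
        for key, lset in manifest.items():
            if key[0] not in complete:
                continue
            planes = build_reference_planes(lset, op_mode=config.op_mode)
            mesh = meshes.get(key[0])
            for mv in evaluate_all(lset, planes, airway_mesh=mesh, config=config,
                                   registry=param_registry):
                param_values[(key, mv.parameter)] = mv.value

    def cell_values(quantity_of_session, condition_examiner=None):
        """subject -> rater-value list under one condition."""
        out = {}
        for subj in complete:
            if condition_examiner is None:  # inter-examiner
                vals = []
                for e in examiners:
                    per_session = [quantity_of_session((subj, e, ses)) for ses in sessions]
                    if config.inter_mode == "first_sessions":
                        vals.append(per_session[0])
                    elif config.inter_mode == "all_four":
                        vals.extend(per_session)
                    else:  # session_means
                        if any(v is None for v in per_session):
                            vals.append(None)
                        else:
                            vals.append(float(np.mean(per_session)))
            else:  # intra: this examiner's sessions are the raters
                vals = [quantity_of_session((subj, condition_examiner, ses))
                        for ses in sessions]
            out[subj] = vals
        return out

    conditions = [("inter", None)] + [(f"examiner:{e}", e) for e in examiners]

    landmark_rows = []
    region_blocks = [(d, region) for region in
                     ("cranial", "mandibular", "teeth", "soft_tissue", "airway")
                     for d in registry.region(region)]
    for d, region in region_blocks:
        if d.name not in lm_names:
            continue
        for ax_idx, axis in enumerate(AXES):
            def getter(key, _name=d.name, _i=ax_idx):
                lset = manifest[key]
                pt = lset.get(_name)
                return None if pt is None else float(pt[_i])
            for cond_name, cond_ex in conditions:
                base = {"region": region, "landmark": d.name, "axis": axis,
                        "condition": cond_name}
                landmark_rows.append(_result_row(
                    base, cell_values(getter, cond_ex), f"{d.name}[{axis}]"))

    parameter_rows = []
    for defn in param_registry:
        def getter(key, _name=defn.name):
            return param_values.get((key, _name))
        for cond_name, cond_ex in conditions:
            base = {"set": defn.set, "subtype": defn.subtype,
                    "parameter": defn.name, "condition": cond_name}
            parameter_rows.append(_result_row(
                base, cell_values(getter, cond_ex), defn.name))

    return ReliabilityReport(
        landmark_table=pd.DataFrame(landmark_rows),
        parameter_table=pd.DataFrame(parameter_rows),
        n_subjects_used=len(complete), n_subjects_dropped=dropped)
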