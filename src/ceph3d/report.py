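"""Human-readable rendering of reliability reports.

Rendering is a pure function of the report: CSV files keep full precision
for machine use; the markdown tables round to 2 decimals in the
``icc [low,high]`` style of clinical reliability tables.  Flag columns
encode the two marking conditions; flag logic always operates on the
unrounded values, so a cell printing "0.75" may still carry the
below-0.75 flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .reliability import ReliabilityReport


def _fmt_cell(row) -> str:
    if not np.isfinite(row["icc"]):
        return "--"
    return f"{row['icc']:.2f} [{row['ci_low']:.2f},{row['ci_high']:.2f}]"


def _pivot_markdown(table: pd.DataFrame, index_cols: list) -> str:
    df = table.copy()
    df["cell"] = df.apply(_fmt_cell, axis=1)
    wide = df.pivot_table(index=index_cols, columns="condition", values="cell",
                          aggfunc="first", sort=False)
    wide = wide.reset_index()
    lines = ["| " + " | ".join(str(c) for c in wide.columns) + " |",
             "|" + "---|" * len(wide.columns)]
    for _, row in wide.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.values) + " |")
    return "\n".join(lines)


_HEADER_NOTE = """\
Conventions: midline-to-sagittal distances are absolute; distances to the
true vertical line are signed (anterior positive); canting is positive when
the left point is superior; yawing is positive when the anterior end
deviates to the left; positive overbite/overjet mean inferior/anterior
position of the upper incisal edge relative to the lower.
Flags: condition1 = ICC < 0.75; condition2 = ICC >= 0.75 with lower 95%
bound < 0.50.  Flags are computed on unrounded values.
"""


def render_reports(report: ReliabilityReport, config: RunConfig | None = None,
                   out_dir=None) -> dict:
    """Write landmark_icc.csv, parameter_icc.csv, flags.csv and markdown
    tables; returns the paths written."""
    config = config or RunConfig()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    lm, par = report.landmark_table, report.parameter_table
    paths["landmark_icc"] = out / "landmark_icc.csv"
    lm.to_csv(paths["landmark_icc"], index=False)
    paths["parameter_icc"] = out / "parameter_icc.csv"
    par.to_csv(paths["parameter_icc"], index=False)

    pieces = [tab[tab["flags"] != ""].assign(table=label)
              for tab, label in ((lm, "landmark"), (par, "parameter"))
              if len(tab)]
    flagged = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    paths["flags"] = out / "flags.csv"
    flagged.to_csv(paths["flags"], index=False)

    md = ["# Reliability report", "", _HEADER_NOTE, "",
          f"Subjects used: {report.n_subjects_used}; "
          f"dropped (incomplete): {report.n_subjects_dropped}", ""]
    if len(lm):
        md += ["## Landmark coordinates (per axis, L/P/S)", "",
               _pivot_markdown(lm, ["region", "landmark", "axis"]), ""]
    if len(par):
        md += ["## Measurement parameters", "",
               _pivot_markdown(par, ["set", "subtype", "parameter"]), ""]
    paths["markdown"] = out / "reliability.md"
    paths["markdown"].write_text("\n".join(md))
    return paths
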