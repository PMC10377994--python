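"""Run configuration with documented defaults.

The config round-trips through a plain ``key=value`` text file so that a
study run is reproducible from its logged configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    """Tunable choices exposed across the library.

    op_mode
        Occlusal-plane construction: ``midpoint3`` (plane through the
        incisal-edge midpoint and both first-molar cusps, default) or
        ``ols6`` (least-squares fit of the six tooth points).
    mean_mode
        Airway "mean area": ``slice_mean`` (mean of the 1 mm slice profile,
        default) or ``volume_over_height``.
    inter_mode
        Ratings fed to the inter-examiner ICC: ``session_means`` (default),
        ``first_sessions`` or ``all_four`` (each session a rater).
    anb_signed
        If true, report ANB as SNA - SNB instead of the unsigned three-point
        angle.
    step_mm
        Slice spacing of the airway area profile (mm).
    outlier_threshold_mm
        Centroid-distance threshold for flagging gross landmark outliers.
    """

    op_mode: str = "midpoint3"
    mean_mode: str = "slice_mean"
    inter_mode: str = "session_means"
    anb_signed: bool = False
    step_mm: float = 1.0
    outlier_threshold_mm: float = 300.0
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self):
        if self.op_mode not in ("midpoint3", "ols6"):
            raise ValueError(f"op_mode {self.op_mode!r}")
        if self.mean_mode not in ("slice_mean", "volume_over_height"):
            raise ValueError(f"mean_mode {self.mean_mode!r}")
        if self.inter_mode not in ("session_means", "first_sessions", "all_four"):
            raise ValueError(f"inter_mode {self.inter_mode!r}")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")

    def to_file(self, path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            ftype = types[key]
            if ftype in ("bool", bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif ftype in ("int", int):
                kwargs[key] = int(value)
            elif ftype in ("float", float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
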