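"""File formats and run configuration.

CSV conventions (header required, UTF-8, '.' decimal):

* tracks — long format, one row per cell per frame:
  ``cell_id,t_min,x_um,y_um,z_um,diameter_um`` (last two optional);
* concentration observations — ``y_mm,t_s,c_norm`` (or ``gray_level``
  plus a calibration file);
* concentration field — long format ``y_mm,t_s,c_norm``;
* calibration points — ``concentration,gray_level``.

:class:`RunConfig` merges the diffusion, experiment and walk settings
of a full pipeline run; it is validated up front and unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import CalibrationCurve, ConcentrationField
from .motility import DEFAULT_DIAMETER_UM, Trajectory, TrackSet

logger = logging.getLogger(__name__)

__all__ = [
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "read_field",
    "write_field",
    "read_observations",
    "read_calibration_points",
    "load_calibration",
    "save_calibration",
    "RunConfig",
]


class TrackFormatError(ValueError):
    """Raised for malformed trajectory tables (message carries row numbers)."""


_TRACK_REQUIRED = ["cell_id", "t_min", "x_um", "y_um"]


def tracks_to_frame(tracks: TrackSet) -> pd.DataFrame:
    rows = []
    for traj in tracks:
        for t, (x, y, z) in zip(traj.t_min, traj.xyz):
            rows.append((traj.cell_id, t, x, y, z, traj.diameter_um))
    return pd.DataFrame(
        rows, columns=["cell_id", "t_min", "x_um", "y_um", "z_um", "diameter_um"]
    )


def frame_to_tracks(df: pd.DataFrame, *, t_stimulus_min: float = 30.0,
                    gradient_dir=(0.0, -1.0, 0.0),
                    frame_interval_min: float = 1.0,
                    default_diameter_um: float = DEFAULT_DIAMETER_UM) -> TrackSet:
    missing = [c for c in _TRACK_REQUIRED if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        warnings.warn("track table is empty; returning an empty TrackSet",
                      stacklevel=2)
        return TrackSet([], t_stimulus_min=t_stimulus_min,
                        gradient_dir=gradient_dir,
                        frame_interval_min=frame_interval_min)
    if "z_um" not in df.columns:
        df = df.assign(z_um=0.0)
    if "diameter_um" not in df.columns:
        df = df.assign(diameter_um=default_diameter_um)
    df = df.copy()
    df["_row"] = np.arange(2, len(df) + 2)  # file line numbers (1 = header)

    dup = df.duplicated(subset=["cell_id", "t_min"], keep=False)
    if dup.any():
        lines = df.loc[dup, "_row"].tolist()[:10]
        raise TrackFormatError(
            f"duplicate (cell_id, t_min) pairs at line(s) {lines}"
        )

    trajectories = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        t = grp["t_min"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = int(grp["_row"].iloc[bad[0] + 1])
            raise TrackFormatError(
                f"cell {cell_id}: time not strictly increasing at line {line}"
            )
        diam = grp["diameter_um"].to_numpy(dtype=float)
        diam_val = float(diam[0]) if np.isfinite(diam[0]) else default_diameter_um
        trajectories.append(Trajectory(
            cell_id=str(cell_id), t_min=t,
            xyz=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            diameter_um=diam_val,
        ))
    return TrackSet(trajectories, t_stimulus_min=t_stimulus_min,
                    gradient_dir=gradient_dir,
                    frame_interval_min=frame_interval_min)


def read_tracks(path, **metadata) -> TrackSet:
    """Read a trajectory CSV; metadata kwargs are passed to the TrackSet."""
    df = pd.read_csv(path)
    return frame_to_tracks(df, **metadata)


def write_tracks(tracks: TrackSet, path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def write_field(field: ConcentrationField, path) -> None:
    """Write a concentration field as long-format CSV (y_mm, t_s, c_norm)."""
    Y, T = np.meshgrid(field.y_mm, field.t_s, indexing="ij")
    pd.DataFrame({"y_mm": Y.ravel(), "t_s": T.ravel(),
                  "c_norm": field.c_norm.ravel()}).to_csv(path, index=False)


def read_field(path) -> ConcentrationField:
    df = pd.read_csv(path)
    for col in ("y_mm", "t_s", "c_norm"):
        if col not in df.columns:
            raise ValueError(f"field CSV missing column {col!r}")
    y = np.unique(df["y_mm"].to_numpy(dtype=float))
    t = np.unique(df["t_s"].to_numpy(dtype=float))
    c = (df.pivot_table(index="y_mm", columns="t_s", values="c_norm")
         .reindex(index=y, columns=t).to_numpy())
    if np.isnan(c).any():
        raise ValueError("field CSV is not a complete (y, t) grid")
    return ConcentrationField(y, t, c)


def read_observations(path, calibration: CalibrationCurve | None = None,
                      C0: float = 1.0) -> np.ndarray:
    """Read concentration observations as an (n, 3) array (y_mm, t_s, c_norm).

    Accepts either a ``c_norm`` column or a ``gray_level`` column plus a
    calibration curve (gray levels are then converted and normalized by
    ``C0``).
    """
    df = pd.read_csv(path)
    for col in ("y_mm", "t_s"):
        if col not in df.columns:
            raise ValueError(f"observations CSV missing column {col!r}")
    if "c_norm" in df.columns:
        c = df["c_norm"].to_numpy(dtype=float)
    elif "gray_level" in df.columns:
        if calibration is None:
            raise ValueError("gray_level observations require a calibration curve")
        from .diffusion import gray_to_concentration

        c = np.asarray(gray_to_concentration(
            calibration, df["gray_level"].to_numpy(dtype=float))) / C0
    else:
        raise ValueError("observations CSV needs a c_norm or gray_level column")
    return np.column_stack([df["y_mm"].to_numpy(dtype=float),
                            df["t_s"].to_numpy(dtype=float), c])


def read_calibration_points(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("concentration", "gray_level"):
        if col not in df.columns:
            raise ValueError(f"calibration CSV missing column {col!r}")
    return df[["concentration", "gray_level"]].to_numpy(dtype=float)


def save_calibration(curve: CalibrationCurve, path) -> None:
    Path(path).write_text(json.dumps({
        "slope": curve.slope, "intercept": curve.intercept,
        "valid_range": list(curve.valid_range), "r_squared": curve.r_squared,
    }, indent=2))


def load_calibration(path) -> CalibrationCurve:
    d = json.loads(Path(path).read_text())
    return CalibrationCurve(slope=d["slope"], intercept=d["intercept"],
                            valid_range=tuple(d["valid_range"]),
                            r_squared=d.get("r_squared", 1.0))


@dataclass
class RunConfig:
    """Merged configuration of a full pipeline run.

    Groups the diffusion solve (D, chamber geometry, discretization),
    the experiment metadata (stimulus time, gradient direction, binning,
    projection, test level) and the synthetic-walk parameters. Loaded
    from JSON or YAML; unknown keys are rejected.
    """

    # diffusion
    D_cm2_s: float = 2e-6
    C0: float = 1.0
    L_reservoir_mm: float = 20.0
    L_membrane_mm: float = 0.15
    L_gel_mm: float = 5.0
    D_factor_membrane: float = 1.0
    dy_mm: float = 0.05
    dt_s: float = 10.0
    t_end_s: float = 4800.0
    # experiment / analysis
    t_stimulus_min: float = 30.0
    gradient_dir: tuple[float, float, float] = (0.0, -1.0, 0.0)
    frame_interval_min: float = 1.0
    projection: str = "xy"
    bin_min: float = 5.0
    motile_window_min: float = 10.0
    alpha: float = 0.05
    # synthetic walk (None -> analyze user-supplied tracks)
    simulate: bool = True
    walk_profile: str = "donorA-like"
    walk_overrides: dict = dc_field(default_factory=dict)
    tracks_csv: str | None = None
    # run plumbing
    out_dir: str = "report"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.projection not in ("xy", "xyz"):
            raise ValueError("projection must be 'xy' or 'xyz'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("bin_min", "motile_window_min", "frame_interval_min",
                     "dy_mm", "dt_s", "t_end_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        self.gradient_dir = tuple(float(v) for v in self.gradient_dir)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(unknown)}; "
                f"valid keys are {', '.join(sorted(known))}"
            )
        return cls(**raw)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gradient_dir"] = list(d["gradient_dir"])
        return d

    def log_defaults(self) -> None:
        """Log every field left at its default (audit trail of the run)."""
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            default = (f.default if f.default is not dataclasses.MISSING
                       else f.default_factory())
            if val == default:
                logger.info("config: %s defaulted to %r", f.name, val)
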