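"""Cell-trajectory motility statistics.

Implements the standard read-outs of a time-lapse chemotaxis assay:

* cumulative chemotactic index I — net displacement along the gradient
  divided by curvilinear path length, per cell, population value
  weighted by each cell's path length;
* motile fraction — cells whose net displacement in a time window
  exceeds their own diameter;
* binned velocity statistics — per-frame backward-difference velocities
  averaged in 5-min bins (components and modulus);
* per-cell mean speeds over the pre- and post-stimulus periods;
* biased-cell fraction — per bin, the percentage of cells whose
  velocity sample rejects a zero-mean one-sample t-test at p < alpha.

Trajectories are 3-D positions in µm sampled at (nominally) 1-min
frames; headline statistics use the XY projection by default since the
z axis of a confocal/widefield stack is sampled far more coarsely than
the in-plane coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "TrackSet",
    "MotilityReport",
    "SpeedDistribution",
    "curvilinear_length",
    "chemotactic_index_cell",
    "chemotactic_index_population",
    "chemotactic_index_series",
    "motile_fraction",
    "velocity_series",
    "per_cell_mean_speed",
    "biased_fraction_ttest",
    "build_motility_report",
]

DEFAULT_DIAMETER_UM = 10.0  # typical neutrophil


def _proj_slice(projection: str) -> slice:
    if projection == "xy":
        return slice(0, 2)
    if projection == "xyz":
        return slice(0, 3)
    raise ValueError(f"projection must be 'xy' or 'xyz', got {projection!r}")


@dataclass
class Trajectory:
    """One cell's time-stamped positions.

    ``t_min`` strictly increasing, positions in µm; ``xyz`` has shape
    (n, 3) (z filled with 0 when absent). ``diameter_um`` is used by the
    motile criterion.
    """

    cell_id: str
    t_min: np.ndarray
    xyz: np.ndarray
    diameter_um: float = DEFAULT_DIAMETER_UM

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.size == 0:
            self.xyz = self.xyz.reshape(0, 3)
        if self.xyz.shape[1] == 2:
            self.xyz = np.column_stack([self.xyz, np.zeros(len(self.xyz))])
        if self.xyz.shape[0] != self.t_min.size or self.xyz.shape[1] != 3:
            raise ValueError(
                f"cell {self.cell_id}: positions shape {self.xyz.shape} "
                f"inconsistent with {self.t_min.size} time points"
            )
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError(f"cell {self.cell_id}: time must be strictly increasing")
        if not self.diameter_um > 0:
            raise ValueError(f"cell {self.cell_id}: diameter must be positive")

    def __len__(self) -> int:
        return self.t_min.size

    def window(self, t_from: float, t_to: float) -> np.ndarray:
        """Boolean mask of samples with t_from <= t <= t_to."""
        return (self.t_min >= t_from) & (self.t_min <= t_to)

    def velocities(self, projection: str = "xy", max_gap_factor: float = 2.0,
                   frame_interval_min: float | None = None):
        """Backward-difference velocities (µm/min), one per frame after the first.

        Returns ``(t_mid, v)`` where ``t_mid`` are the timestamps the
        velocities are assigned to (the right endpoint of each step) and
        ``v`` has one column per projected axis. Gaps longer than
        ``max_gap_factor`` frame intervals are still differenced over the
        actual elapsed time but logged.
        """
        sl = _proj_slice(projection)
        dt = np.diff(self.t_min)
        if frame_interval_min is not None and np.any(dt > max_gap_factor * frame_interval_min):
            logger.warning(
                "cell %s: %d frame gap(s) longer than %gx the frame interval",
                self.cell_id, int(np.sum(dt > max_gap_factor * frame_interval_min)),
                max_gap_factor,
            )
        v = np.diff(self.xyz[:, sl], axis=0) / dt[:, None]
        return self.t_min[1:], v


@dataclass
class TrackSet:
    """A tracked cell population plus the experiment metadata.

    ``t_stimulus_min`` is when the chemoattractant was added to the
    reservoir; ``gradient_dir`` is the unit vector pointing toward the
    chemoattractant source (default (0, −1, 0): the membrane sits at
    lower y than the imaging volume).
    """

    trajectories: list[Trajectory] = dc_field(default_factory=list)
    t_stimulus_min: float = 30.0
    gradient_dir: tuple[float, float, float] = (0.0, -1.0, 0.0)
    frame_interval_min: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gradient_dir, dtype=float)
        norm = np.linalg.norm(g)
        if not norm > 0:
            raise ValueError("gradient_dir must be non-zero")
        self.gradient_dir = tuple(g / norm)
        if self.t_stimulus_min < 0:
            raise ValueError("t_stimulus_min must be >= 0")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def t_max_min(self) -> float:
        return max((tr.t_min[-1] for tr in self.trajectories), default=0.0)

    def gradient_vector(self, projection: str = "xy") -> np.ndarray:
        g = np.asarray(self.gradient_dir)[_proj_slice(projection)]
        n = np.linalg.norm(g)
        if not n > 0:
            raise ValueError("gradient_dir has zero projection on the chosen axes")
        return g / n


def curvilinear_length(traj: Trajectory, t_from: float, t_to: float,
                       projection: str = "xy") -> float:
    """Total curvilinear path length (µm) inside [t_from, t_to].

    Sum of successive inter-sample Euclidean distances; a window holding
    fewer than 2 samples contributes length 0 (logged).
    """
    sl = _proj_slice(projection)
    m = traj.window(t_from, t_to)
    if m.sum() < 2:
        logger.debug("cell %s: <2 samples in [%g, %g]; length 0",
                     traj.cell_id, t_from, t_to)
        return 0.0
    pts = traj.xyz[m][:, sl]
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def chemotactic_index_cell(traj: Trajectory, t_from: float, t_to: float,
                           gradient_dir, projection: str = "xy"):
    """Per-cell chemotactic index on a window, with its weighting length.

    I = (net displacement · gradient direction) / curvilinear length;
    +1 for a straight run toward the source, −1 straight away, ~0 for
    unbiased motion. Returns ``(I, L)``; a cell with zero path length in
    the window gets ``(nan, 0.0)`` — excluded from population averages
    by its zero weight rather than raising.
    """
    sl = _proj_slice(projection)
    g = np.asarray(gradient_dir, dtype=float)[sl]
    gn = np.linalg.norm(g)
    if not gn > 0:
        raise ValueError("gradient_dir has zero projection")
    g = g / gn
    L = curvilinear_length(traj, t_from, t_to, projection)
    if L == 0.0:
        return float("nan"), 0.0
    m = traj.window(t_from, t_to)
    pts = traj.xyz[m][:, sl]
    net = pts[-1] - pts[0]
    return float(np.dot(net, g) / L), L


def chemotactic_index_population(tracks: TrackSet, t_eval: float,
                                 t_origin: float = 0.0,
                                 projection: str = "xy") -> float:
    """Cumulative population chemotactic index at ``t_eval``.

    Length-weighted mean of per-cell indices computed on
    [t_origin, t_eval]: I = Σ Iᵢ·Lᵢ / Σ Lᵢ. Returns nan when every cell
    is stationary on the window.
    """
    if not t_eval > t_origin:
        raise ValueError("t_eval must exceed t_origin")
    num = 0.0
    den = 0.0
    for traj in tracks:
        I, L = chemotactic_index_cell(traj, t_origin, t_eval,
                                      tracks.gradient_dir, projection)
        if L > 0:
            num += I * L
            den += L
    if den == 0.0:
        return float("nan")
    return num / den


def chemotactic_index_series(tracks: TrackSet, step_min: float = 5.0,
                             t_origin: float = 0.0,
                             projection: str = "xy") -> pd.DataFrame:
    """Cumulative I evaluated at regular steps from the experiment start."""
    t_end = tracks.t_max_min
    t_evals = np.arange(t_origin + step_min, t_end + step_min / 2, step_min)
    rows = [
        {"t_min": t, "chemotactic_index":
            chemotactic_index_population(tracks, t, t_origin, projection)}
        for t in t_evals
    ]
    return pd.DataFrame(rows)


def motile_fraction(tracks: TrackSet, window_min: float = 10.0,
                    projection: str = "xy") -> pd.DataFrame:
    """Fraction of cells whose net displacement per window exceeds their diameter.

    Windows are half-open [k·w, (k+1)·w) tiling the record from t = 0.
    The displacement is between a cell's first and last sample inside
    the window; a cell with fewer than 2 samples there is excluded from
    that window's denominator. The criterion is strict ( > diameter).
    """
    sl = _proj_slice(projection)
    t_end = tracks.t_max_min
    edges = np.arange(0.0, t_end + window_min, window_min)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = 0
        n_motile = 0
        for traj in tracks:
            m = (traj.t_min >= lo) & (traj.t_min < hi)
            if m.sum() < 2:
                continue
            pts = traj.xyz[m][:, sl]
            disp = float(np.linalg.norm(pts[-1] - pts[0]))
            n += 1
            if disp > traj.diameter_um:
                n_motile += 1
        rows.append({
            "t_start_min": lo, "t_end_min": hi,
            "motile_fraction": (n_motile / n) if n else float("nan"),
            "n_cells": n,
        })
    return pd.DataFrame(rows)


def _binned_cell_velocities(tracks: TrackSet, bin_min: float,
                            projection: str = "xy"):
    """Yield (bin_start, cell, v) with v the cell's velocity samples in the bin."""
    t_end = tracks.t_max_min
    edges = np.arange(0.0, t_end + bin_min, bin_min)
    per_cell = [
        traj.velocities(projection, frame_interval_min=tracks.frame_interval_min)
        for traj in tracks
    ]
    for lo, hi in zip(edges[:-1], edges[1:]):
        for traj, (tv, v) in zip(tracks, per_cell):
            m = (tv >= lo) & (tv < hi)
            if m.any():
                yield lo, hi, traj, v[m]


def velocity_series(tracks: TrackSet, bin_min: float = 5.0,
                    projection: str = "xy") -> pd.DataFrame:
    """Population-mean velocity components and modulus per time bin.

    Per-frame backward-difference velocities are pooled over all cells
    within half-open bins [k·b, (k+1)·b); the modulus is computed per
    frame and then averaged (not the norm of the mean — an isotropic
    population has zero mean components but positive mean modulus).
    """
    acc: dict[float, list[np.ndarray]] = {}
    spans: dict[float, float] = {}
    for lo, hi, _traj, v in _binned_cell_velocities(tracks, bin_min, projection):
        acc.setdefault(lo, []).append(v)
        spans[lo] = hi
    rows = []
    for lo in sorted(acc):
        v = np.vstack(acc[lo])
        row = {"t_start_min": lo, "t_end_min": spans[lo],
               "v_x_um_min": float(v[:, 0].mean()),
               "v_y_um_min": float(v[:, 1].mean()),
               "v_mod_um_min": float(np.linalg.norm(v, axis=1).mean()),
               "n_samples": int(v.shape[0])}
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SpeedDistribution:
    """Per-cell mean speeds over a period plus population summaries."""

    period: str
    per_cell: pd.Series  # index cell_id, values µm/min
    mean: float
    sd: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray  # 1 µm/min bins from 0


def per_cell_mean_speed(tracks: TrackSet, period: str = "pre",
                        projection: str = "xy",
                        hist_bin_um_min: float = 1.0) -> SpeedDistribution:
    """Average velocity modulus per cell over the pre- or post-stimulus period.

    The stimulus time splits the record; a cell tracked in only one
    period simply has no entry for the other. The histogram uses
    1 µm/min bins starting at 0.
    """
    if period not in ("pre", "post"):
        raise ValueError("period must be 'pre' or 'post'")
    values = {}
    for traj in tracks:
        tv, v = traj.velocities(projection,
                                frame_interval_min=tracks.frame_interval_min)
        m = tv <= tracks.t_stimulus_min if period == "pre" else tv > tracks.t_stimulus_min
        if m.any():
            values[traj.cell_id] = float(np.linalg.norm(v[m], axis=1).mean())
    per_cell = pd.Series(values, name=f"mean_speed_{period}", dtype=float)
    if per_cell.empty:
        return SpeedDistribution(period, per_cell, float("nan"), float("nan"),
                                 np.array([]), np.array([0.0]))
    top = max(hist_bin_um_min, np.ceil(per_cell.max() / hist_bin_um_min)
              * hist_bin_um_min)
    edges = np.arange(0.0, top + hist_bin_um_min / 2, hist_bin_um_min)
    counts, edges = np.histogram(per_cell.values, bins=edges)
    return SpeedDistribution(period, per_cell, float(per_cell.mean()),
                             float(per_cell.std(ddof=1)) if len(per_cell) > 1 else 0.0,
                             counts, edges)


def _ttest_reject(samples: np.ndarray, popmean: float, alpha: float) -> np.ndarray:
    """Vectorized two-sided one-sample t-test over rows of ``samples``.

    Returns a boolean rejection flag per row. Degenerate zero-variance
    rows are rejected iff their common value differs from the null mean
    (the t statistic diverges there).
    """
    samples = np.atleast_2d(samples)
    n = samples.shape[1]
    mean = samples.mean(axis=1)
    sd = samples.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - popmean) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    reject = p < alpha
    reject[degenerate] = ~np.isclose(mean[degenerate], popmean)
    return reject


def biased_fraction_ttest(tracks: TrackSet, bin_min: float = 5.0,
                          alpha: float = 0.05, min_samples: int = 3,
                          projection: str = "xy") -> pd.DataFrame:
    """Percentage of cells per bin with a biased (non-random) velocity sample.

    For each 5-min bin and each cell holding >= ``min_samples`` velocity
    samples, a two-sided one-sample t-test against mean 0 is run on the
    x and y velocity components; the returned percentages count cells
    rejecting at p < alpha. The modulus is strictly positive under any
    null, so for it the test is run against the bin's population-mean
    modulus (null: this cell's speed does not differ from the
    population's in this bin) — reported alongside but interpreted
    differently from the component tests.
    """
    bins: dict[float, dict[str, list]] = {}
    spans: dict[float, float] = {}
    for lo, hi, traj, v in _binned_cell_velocities(tracks, bin_min, projection):
        d = bins.setdefault(lo, {"cells": []})
        d["cells"].append(v)
        spans[lo] = hi
    rows = []
    for lo in sorted(bins):
        cells = [v for v in bins[lo]["cells"] if v.shape[0] >= min_samples]
        n_skipped = len(bins[lo]["cells"]) - len(cells)
        if n_skipped:
            logger.debug("bin %g: skipped %d cell(s) with <%d samples",
                         lo, n_skipped, min_samples)
        if not cells:
            continue
        all_mod = np.concatenate([np.linalg.norm(v, axis=1) for v in cells])
        pop_mod = float(all_mod.mean())
        n = len(cells)
        # vectorize over cells sharing a sample count (the common case:
        # every cell contributes a full bin of frames)
        rej_x = rej_y = rej_m = 0
        counts = {v.shape[0] for v in cells}
        for cnt in counts:
            group = [v for v in cells if v.shape[0] == cnt]
            vx = np.stack([v[:, 0] for v in group])
            vy = np.stack([v[:, 1] for v in group])
            vm = np.stack([np.linalg.norm(v, axis=1) for v in group])
            rej_x += int(_ttest_reject(vx, 0.0, alpha).sum())
            rej_y += int(_ttest_reject(vy, 0.0, alpha).sum())
            rej_m += int(_ttest_reject(vm, pop_mod, alpha).sum())
        rows.append({"t_start_min": lo, "t_end_min": spans[lo],
                     "pct_biased_vx": 100.0 * rej_x / n,
                     "pct_biased_vy": 100.0 * rej_y / n,
                     "pct_biased_mod": 100.0 * rej_m / n,
                     "n_cells": n})
    return pd.DataFrame(rows)


@dataclass
class MotilityReport:
    """Bundle of the assay's motility read-outs (tidy frames)."""

    motile_fraction: pd.DataFrame
    velocity: pd.DataFrame
    chemotactic_index: pd.DataFrame
    biased_fraction: pd.DataFrame
    speed_pre: SpeedDistribution
    speed_post: SpeedDistribution

    def to_tidy(self) -> pd.DataFrame:
        """Long-format report: one row per (bin_start, metric, value, n)."""
        rows = []
        for _, r in self.motile_fraction.iterrows():
            rows.append((r.t_start_min, "motile_fraction", r.motile_fraction,
                         r.n_cells))
        for _, r in self.velocity.iterrows():
            for k in ("v_x_um_min", "v_y_um_min", "v_mod_um_min"):
                rows.append((r.t_start_min, k, r[k], r.n_samples))
        for _, r in self.chemotactic_index.iterrows():
            rows.append((r.t_min, "chemotactic_index", r.chemotactic_index,
                         np.nan))
        for _, r in self.biased_fraction.iterrows():
            for k in ("pct_biased_vx", "pct_biased_vy", "pct_biased_mod"):
                rows.append((r.t_start_min, k, r[k], r.n_cells))
        for dist in (self.speed_pre, self.speed_post):
            if not np.isnan(dist.mean):
                rows.append((np.nan, f"mean_speed_{dist.period}", dist.mean,
                             len(dist.per_cell)))
                rows.append((np.nan, f"sd_speed_{dist.period}", dist.sd,
                             len(dist.per_cell)))
        return pd.DataFrame(rows, columns=["bin_start", "metric", "value", "n"])


def build_motility_report(tracks: TrackSet, *, bin_min: float = 5.0,
                          motile_window_min: float = 10.0, alpha: float = 0.05,
                          projection: str = "xy",
                          ci_from_stimulus: bool = False) -> MotilityReport:
    """Compute every motility read-out for a tracked population."""
    t_origin = tracks.t_stimulus_min if ci_from_stimulus else 0.0
    return MotilityReport(
        motile_fraction=motile_fraction(tracks, motile_window_min, projection),
        velocity=velocity_series(tracks, bin_min, projection),
        chemotactic_index=chemotactic_index_series(tracks, bin_min, t_origin,
                                                   projection),
        biased_fraction=biased_fraction_ttest(tracks, bin_min, alpha,
                                              projection=projection),
        speed_pre=per_cell_mean_speed(tracks, "pre", projection),
        speed_post=per_cell_mean_speed(tracks, "post", projection),
    )
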