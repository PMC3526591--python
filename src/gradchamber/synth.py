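"""Synthetic chemotaxis experiments.

The generator emulates the statistical structure of the neutrophil/IL-8
assay the analysis code is built for: ~70 cells imaged once per minute
for 110 min, chemoattractant added at t = 30 min to a reservoir below
the imaging volume (gradient direction (0, −1, 0)), a motile
subpopulation with speeds of order 0.5–7 µm/min, and a directed
response that follows the arrival of the diffusing chemoattractant
front.

Cells follow a biased persistent random walk: a mover's velocity is an
AR(1) process

    v(t+Δt) = α·v(t) + (1−α)·(drift(t)·ĝ + s·η),   η ~ N(0, I₃)

where α is the direction-memory (persistence) coefficient, s the speed
scale of the current period, ĝ the gradient direction and drift(t) =
χ·|∂(C/C0)/∂y| evaluated from a concentration field at the cell's
current position — zero until the chemoattractant front reaches the
cell. Non-movers only jitter about their anchor point. Every sample
path is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from ._units import MM_PER_UM, S_PER_MIN, UM_PER_MM
from .diffusion import (
    CalibrationCurve,
    ConcentrationField,
    DiffusionParams,
    closed_form_field,
    concentration_to_gray,
)
from .motility import Trajectory, TrackSet

__all__ = [
    "WalkParams",
    "SyntheticExperiment",
    "simulate_tracks",
    "simulate_gray_series",
    "make_fixture_experiment",
    "FIXTURE_PROFILES",
]


@dataclass(frozen=True)
class WalkParams:
    """Generative parameters of the biased persistent random walk.

    Defaults mirror the emulated experiment: 70 cells, 110 one-minute
    frames, stimulus at 30 min. ``chemotactic_coupling`` (χ) converts
    the local normalized gradient (1/mm) into a drift speed (µm/min);
    ``envelope_tau_min`` optionally decays χ exponentially after the
    stimulus, a phenomenological stand-in for the transient (adaptive)
    chemotactic response; ``baseline_drift_um_min`` is a constant
    pre-existing drift along the gradient (some donors show a non-zero
    baseline orientation bias). Cells start uniformly in an imaging
    volume of ``box_um`` centred ``y0_center_mm`` from the membrane.
    """

    n_cells: int = 70
    duration_min: float = 110.0
    frame_interval_min: float = 1.0
    t_stimulus_min: float = 30.0
    motile_fraction_pre: float = 0.3
    motile_fraction_post: float = 0.8
    speed_scale_pre_um_min: float = 1.0
    speed_scale_post_um_min: float = 3.0
    persistence: float = 0.5
    chemotactic_coupling: float = 25.0
    envelope_tau_min: float | None = None
    baseline_drift_um_min: float = 0.0
    jitter_sd_um: float = 0.3
    cell_diameter_um: float = 10.0
    y0_center_mm: float = 2.0
    box_um: tuple[float, float, float] = (1000.0, 1000.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("motile_fraction_pre", "motile_fraction_post"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("speed_scale_pre_um_min", "speed_scale_post_um_min",
                     "chemotactic_coupling", "jitter_sd_um",
                     "baseline_drift_um_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        if not self.duration_min > self.t_stimulus_min:
            raise ValueError("duration must exceed t_stimulus")
        if self.n_cells < 1 or self.frame_interval_min <= 0:
            raise ValueError("need n_cells >= 1 and a positive frame interval")


@dataclass
class SyntheticExperiment:
    """Generated tracks plus the ground truth they were built from."""

    tracks: TrackSet
    field: ConcentrationField | None
    params: WalkParams
    ground_truth: dict


def _drift_speed(params: WalkParams, field, t_min: float,
                 y_mm: np.ndarray) -> np.ndarray:
    """Imposed drift speed (µm/min) per cell at time t (min since start)."""
    drift = np.full(y_mm.shape, params.baseline_drift_um_min)
    if t_min < params.t_stimulus_min or field is None:
        return drift
    t_since = t_min - params.t_stimulus_min
    if isinstance(field, ConcentrationField):
        grad = np.abs(field.gradient_y(y_mm, t_since * S_PER_MIN))
    else:  # fixed normalized gradient, 1/mm
        grad = np.full(y_mm.shape, abs(float(field)))
    chi = params.chemotactic_coupling
    if params.envelope_tau_min is not None:
        chi = chi * np.exp(-t_since / params.envelope_tau_min)
    return drift + chi * grad


def simulate_tracks(params: WalkParams, field=None,
                    gradient_dir=(0.0, -1.0, 0.0)) -> SyntheticExperiment:
    """Simulate a tracked population coupled to a concentration field.

    ``field`` is a :class:`ConcentrationField` whose time axis starts at
    chemoattractant addition (as produced by the diffusion module), a
    plain number taken as a fixed normalized gradient (1/mm) switched on
    at the stimulus, or None for no stimulus coupling. Cells must start
    inside the field's y range.
    """
    g = np.asarray(gradient_dir, dtype=float)
    g = g / np.linalg.norm(g)
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    dt = params.frame_interval_min
    times = np.arange(0.0, params.duration_min + dt / 2, dt)
    n_frames = times.size

    box = np.asarray(params.box_um, dtype=float)
    origin = np.array([-box[0] / 2,
                       params.y0_center_mm * UM_PER_MM - box[1] / 2,
                       0.0])
    pos0 = origin + rng.random((n, 3)) * box
    if isinstance(field, ConcentrationField):
        y0_mm = pos0[:, 1] * MM_PER_UM
        if np.any(y0_mm < field.y_mm.min()) or np.any(y0_mm > field.y_mm.max()):
            raise ValueError(
                "cells initialized outside the concentration field's y range"
            )

    mover_pre = rng.random(n) < params.motile_fraction_pre
    mover_post = rng.random(n) < params.motile_fraction_post

    pos = np.empty((n_frames, n, 3))
    pos[0] = pos0
    anchor = pos0.copy()
    v = np.zeros((n, 3))
    alpha = params.persistence
    drift_series = np.zeros(n_frames)

    prev_movers = mover_pre
    for k in range(1, n_frames):
        t = times[k - 1]
        post = t >= params.t_stimulus_min
        movers = mover_post if post else mover_pre
        stopped = prev_movers & ~movers
        if stopped.any():  # re-anchor cells that stop at the stimulus
            anchor[stopped] = pos[k - 1, stopped]
        prev_movers = movers
        s = params.speed_scale_post_um_min if post else params.speed_scale_pre_um_min
        y_mm = pos[k - 1, :, 1] * MM_PER_UM
        drift = _drift_speed(params, field, t, y_mm)
        drift_series[k] = float(drift[movers].mean()) if movers.any() else 0.0
        eta = rng.standard_normal((n, 3))
        v = alpha * v + (1 - alpha) * (drift[:, None] * g[None, :] + s * eta)
        jitter = rng.normal(0.0, params.jitter_sd_um, (n, 3))
        pos[k] = np.where(movers[:, None], pos[k - 1] + v * dt, anchor + jitter)

    trajectories = [
        Trajectory(cell_id=f"cell{i:03d}", t_min=times, xyz=pos[:, i, :],
                   diameter_um=params.cell_diameter_um)
        for i in range(n)
    ]
    tracks = TrackSet(trajectories, t_stimulus_min=params.t_stimulus_min,
                      gradient_dir=tuple(g),
                      frame_interval_min=params.frame_interval_min)
    speeds = np.linalg.norm(np.diff(pos[:, :, :2], axis=0), axis=2) / dt
    ground_truth = {
        "mover_pre": mover_pre,
        "mover_post": mover_post,
        "mean_speed_um_min": speeds.mean(axis=0),
        "imposed_drift_um_min": drift_series,
    }
    return SyntheticExperiment(
        tracks=tracks,
        field=field if isinstance(field, ConcentrationField) else None,
        params=params, ground_truth=ground_truth,
    )


def simulate_gray_series(curve: CalibrationCurve, field: ConcentrationField,
                         positions_mm=(2.0, 3.0, 4.0, 5.0),
                         noise_sd: float = 0.0, seed: int = 0,
                         t_s=None, C0: float = 1.0):
    """Noisy mean-gray-level time series at fixed distances from the membrane.

    gray(y, t) = slope·C(y, t) + intercept + N(0, noise_sd²); the series
    emulates epifluorescence monitoring of the tracer front and is
    invertible through the calibration up to noise. Returns a DataFrame
    with columns ``y_mm, t_s, gray_level``.
    """
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    positions = np.asarray(positions_mm, dtype=float)
    # cell-centred solver grids stop half a spacing short of the wall;
    # allow positions within one spacing of the edge (clipped by at())
    tol = float(np.diff(field.y_mm).max()) if field.y_mm.size > 1 else 0.0
    if (np.any(positions < field.y_mm.min() - tol)
            or np.any(positions > field.y_mm.max() + tol)):
        raise ValueError("positions outside the field's y range")
    if t_s is None:
        t_s = field.t_s
    t_s = np.asarray(t_s, dtype=float)
    rng = np.random.default_rng(seed)
    Y, T = np.meshgrid(positions, t_s, indexing="ij")
    conc = field.at(Y.ravel(), T.ravel()) * C0
    gray = concentration_to_gray(curve, conc)
    gray = gray + rng.normal(0.0, noise_sd, gray.shape) if noise_sd else gray
    return pd.DataFrame({"y_mm": Y.ravel(), "t_s": T.ravel(),
                         "gray_level": gray})


# Fixture profiles emulating the qualitative population behaviours seen in
# the assay: a low-baseline donor whose index rises and plateaus after the
# stimulus, a high-baseline donor with a pre-existing orientation bias whose
# response peaks and decays, and a no-stimulus isotropic control.
FIXTURE_PROFILES: dict[str, WalkParams] = {
    "donorA-like": WalkParams(
        motile_fraction_pre=0.25, motile_fraction_post=0.8,
        speed_scale_pre_um_min=0.7, speed_scale_post_um_min=3.0,
        chemotactic_coupling=12.0, envelope_tau_min=None,
    ),
    "donorB-like": WalkParams(
        motile_fraction_pre=0.5, motile_fraction_post=0.85,
        speed_scale_pre_um_min=1.7, speed_scale_post_um_min=3.5,
        chemotactic_coupling=600.0, envelope_tau_min=12.0,
        baseline_drift_um_min=0.4,
    ),
    "isotropic": WalkParams(
        motile_fraction_pre=0.4, motile_fraction_post=0.4,
        speed_scale_pre_um_min=1.5, speed_scale_post_um_min=1.5,
        chemotactic_coupling=0.0,
    ),
}


def make_fixture_experiment(profile: str, seed: int = 0) -> SyntheticExperiment:
    """Deterministic packaged experiment for one of the named profiles.

    The gradient field is the closed-form solution with D = 2e-6 cm²/s
    over the post-stimulus window; the "isotropic" profile has zero
    chemotactic coupling and no post-stimulus change.
    """
    if profile not in FIXTURE_PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {sorted(FIXTURE_PROFILES)}"
        )
    params = replace(FIXTURE_PROFILES[profile], seed=seed)
    t_post_s = (params.duration_min - params.t_stimulus_min) * S_PER_MIN
    field = closed_form_field(DiffusionParams(D_cm2_s=2e-6),
                              t_end_s=t_post_s, dt_s=60.0)
    if profile == "isotropic":
        field = None
    return simulate_tracks(params, field)
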