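"""Chemoattractant transport in the gradient chamber.

The chamber is a closed 1-D axis: chemoattractant reservoir | porous
membrane | collagen gel. Two models of the normalized concentration
C/C0 are provided:

* a closed-form semi-infinite-slab solution of Fick's second law with a
  fixed half-concentration boundary at the membrane–gel interface,
  C(y, t)/C0 = ½·erfc( y / (2·√(D·t)) );
* a conservative finite-difference solve of the full three-section
  chamber with no-flux walls, which drops the semi-infinite
  approximation and lets the interface concentration evolve.

On top of the forward models sit a single-parameter least-squares fit of
the diffusion coefficient D to concentration observations, and the
linear fluorescence calibration that maps epifluorescence mean gray
level to tracer concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special, stats

from ._units import CM_PER_MM, MM2_PER_CM2

__all__ = [
    "DiffusionParams",
    "ChamberGeometry1D",
    "ConcentrationField",
    "CalibrationCurve",
    "DiffusionFit",
    "StabilityError",
    "FitError",
    "ExtrapolationWarning",
    "closed_form_profile",
    "closed_form_field",
    "solve_chamber_1d",
    "fit_diffusion_coefficient",
    "fit_calibration",
    "gray_to_concentration",
    "concentration_to_gray",
]


class StabilityError(RuntimeError):
    """Raised when an explicit scheme violates its stability criterion."""


class FitError(ValueError):
    """Raised when a least-squares fit is ill-posed."""


class ExtrapolationWarning(UserWarning):
    """Emitted when a calibration curve is evaluated outside its fitted range."""


@dataclass(frozen=True)
class DiffusionParams:
    """Transport parameters of the tracer/chemoattractant.

    Parameters
    ----------
    D_cm2_s:
        Diffusion coefficient in cm²/s. For a 10 kDa FITC-dextran tracer
        in collagen the fitted value is of order 2e-6 cm²/s.
    C0:
        Initial reservoir concentration in arbitrary concentration units.
        All field outputs are normalized C/C0, so C0 only matters when
        converting to absolute concentrations.
    """

    D_cm2_s: float = 2e-6
    C0: float = 1.0

    def __post_init__(self) -> None:
        if not self.D_cm2_s > 0:
            raise ValueError(f"D must be positive, got {self.D_cm2_s}")
        if not self.C0 > 0:
            raise ValueError(f"C0 must be positive, got {self.C0}")

    @property
    def D_mm2_s(self) -> float:
        return self.D_cm2_s * MM2_PER_CM2


@dataclass(frozen=True)
class ChamberGeometry1D:
    """Three-section chamber axis: reservoir | membrane | gel.

    y = 0 is the membrane–gel interface; y grows into the gel. Lengths
    in mm. ``D_factor_membrane`` scales the diffusivity inside the
    membrane section (1.0 = membrane does not hinder transport, the
    default: 0.22 µm pores are far larger than a 10 kDa tracer).
    """

    L_reservoir_mm: float = 20.0
    L_membrane_mm: float = 0.15
    L_gel_mm: float = 5.0
    D_factor_membrane: float = 1.0

    def __post_init__(self) -> None:
        for name in ("L_reservoir_mm", "L_membrane_mm", "L_gel_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.D_factor_membrane <= 1:
            raise ValueError("D_factor_membrane must be in (0, 1]")

    @property
    def y_min_mm(self) -> float:
        return -(self.L_reservoir_mm + self.L_membrane_mm)

    @property
    def y_max_mm(self) -> float:
        return self.L_gel_mm


@dataclass
class ConcentrationField:
    """Normalized concentration C/C0 on a (y, t) grid.

    ``y_mm`` are positions along the chamber axis (membrane–gel interface
    at y = 0, positive into the gel; solver outputs include negative y
    for the membrane and reservoir sections). ``t_s`` are times since
    chemoattractant addition. ``c_norm`` has shape (len(y_mm), len(t_s)).
    """

    y_mm: np.ndarray
    t_s: np.ndarray
    c_norm: np.ndarray

    def __post_init__(self) -> None:
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.c_norm = np.asarray(self.c_norm, dtype=float)
        if self.c_norm.shape != (self.y_mm.size, self.t_s.size):
            raise ValueError(
                f"c_norm shape {self.c_norm.shape} does not match grid "
                f"({self.y_mm.size}, {self.t_s.size})"
            )

    def at(self, y_mm, t_s):
        """Bilinear interpolation of C/C0 at (y, t); clips to grid edges."""
        y = np.clip(np.asarray(y_mm, dtype=float), self.y_mm[0], self.y_mm[-1])
        t = np.clip(np.asarray(t_s, dtype=float), self.t_s[0], self.t_s[-1])
        if self.y_mm.size > 1:
            iy = np.clip(np.searchsorted(self.y_mm, y) - 1, 0, self.y_mm.size - 2)
            wy = (y - self.y_mm[iy]) / (self.y_mm[iy + 1] - self.y_mm[iy])
            iy1 = iy + 1
        else:
            iy = iy1 = np.zeros_like(y, dtype=int)
            wy = np.zeros_like(y)
        if self.t_s.size > 1:
            it = np.clip(np.searchsorted(self.t_s, t) - 1, 0, self.t_s.size - 2)
            wt = (t - self.t_s[it]) / (self.t_s[it + 1] - self.t_s[it])
            it1 = it + 1
        else:
            it = it1 = np.zeros_like(t, dtype=int)
            wt = np.zeros_like(t)
        c00 = self.c_norm[iy, it]
        c01 = self.c_norm[iy, it1]
        c10 = self.c_norm[iy1, it]
        c11 = self.c_norm[iy1, it1]
        return (
            c00 * (1 - wy) * (1 - wt)
            + c01 * (1 - wy) * wt
            + c10 * wy * (1 - wt)
            + c11 * wy * wt
        )

    def gradient_y(self, y_mm, t_s, dy_mm: float = 0.05):
        """∂(C/C0)/∂y in 1/mm by central difference on the interpolant."""
        y = np.asarray(y_mm, dtype=float)
        return (self.at(y + dy_mm / 2, t_s) - self.at(y - dy_mm / 2, t_s)) / dy_mm

    def gel_section(self) -> "ConcentrationField":
        """Restrict the field to the gel (y >= 0)."""
        mask = self.y_mm >= 0
        return ConcentrationField(self.y_mm[mask], self.t_s, self.c_norm[mask])

    def total_mass(self) -> np.ndarray:
        """∫ C/C0 dy at each time; conserved under no-flux walls.

        On a uniform grid (the solver's cell-centred grid) the discrete
        measure sum(C)·dy is used — the quantity the conservative scheme
        preserves identically; otherwise the trapezoid rule.
        """
        dy = np.diff(self.y_mm)
        if dy.size and np.allclose(dy, dy[0]):
            return self.c_norm.sum(axis=0) * dy[0]
        return np.trapezoid(self.c_norm, self.y_mm, axis=0)


def closed_form_profile(y_mm, t_s, params: DiffusionParams):
    """Semi-infinite-slab concentration C/C0 at distance y from the membrane.

    Solves Fick's second law with C = C0/2 held at the interface (y = 0),
    C → 0 as y → ∞ and C = 0 initially, giving
    ``0.5 * erfc(y / (2 sqrt(D t)))``. y in mm, t in s since
    chemoattractant addition. Vectorized in y and t. At the singular
    corner y = 0, t = 0 the boundary value 0.5 is returned (right limit
    in t).
    """

    y = np.asarray(y_mm, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be >= 0 (distance into the gel)")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    y_cm = y * CM_PER_MM
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = y_cm / (2.0 * np.sqrt(params.D_cm2_s * t))
    # t = 0: arg is inf for y > 0 (C = 0) and nan for y = 0 (boundary, C = 1/2)
    arg = np.where(np.isnan(arg), 0.0, arg)
    out = 0.5 * special.erfc(arg)
    return out if out.ndim else float(out)


def closed_form_field(
    params: DiffusionParams,
    y_mm=None,
    t_s=None,
    *,
    L_gel_mm: float = 5.0,
    t_end_s: float = 7200.0,
    dy_mm: float = 0.05,
    dt_s: float = 60.0,
) -> ConcentrationField:
    """Tabulate the closed-form profile on a regular gel grid."""
    if y_mm is None:
        y_mm = np.arange(0.0, L_gel_mm + dy_mm / 2, dy_mm)
    if t_s is None:
        t_s = np.arange(0.0, t_end_s + dt_s / 2, dt_s)
    y_mm = np.asarray(y_mm, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    c = closed_form_profile(y_mm[:, None], t_s[None, :], params)
    return ConcentrationField(y_mm, t_s, c)


def _banded_matrices(D_face_mm2_s: np.ndarray, dy_mm: float, dt_s: float, theta: float):
    """Crank–Nicolson banded LHS/RHS for the conservative 1-D diffusion stencil.

    ``D_face`` holds face diffusivities between adjacent cells (length
    n-1). No-flux outer walls follow from omitting the boundary faces,
    which also makes column sums of the update operator zero — discrete
    mass is conserved identically.
    """
    n = D_face_mm2_s.size + 1
    r = dt_s / dy_mm**2
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    lower[1:] = r * D_face_mm2_s  # A[i, i-1] = r*D_face[i-1]
    upper[:-1] = r * D_face_mm2_s  # A[i, i+1] = r*D_face[i]
    diag[:-1] -= r * D_face_mm2_s
    diag[1:] -= r * D_face_mm2_s
    # LHS = I - theta*A, RHS = I + (1-theta)*A, banded (ab) format for LHS
    ab = np.zeros((3, n))
    ab[0, 1:] = -theta * upper[:-1]
    ab[1, :] = 1.0 - theta * diag
    ab[2, :-1] = -theta * lower[1:]
    return ab, (lower, diag, upper)


def _apply_rhs(bands, c, theta: float):
    lower, diag, upper = bands
    out = (1.0 + (1 - theta) * diag) * c
    out[1:] += (1 - theta) * lower[1:] * c[:-1]
    out[:-1] += (1 - theta) * upper[:-1] * c[1:]
    return out


def solve_chamber_1d(
    geom: ChamberGeometry1D,
    params: DiffusionParams,
    t_grid_s,
    dy_mm: float = 0.05,
    dt_s: float = 10.0,
    scheme: str = "crank-nicolson",
    membrane_prefilled: bool = True,
) -> ConcentrationField:
    """Finite-difference solve of the closed three-section chamber.

    Cell-centred conservative discretization with no-flux walls at both
    ends. The initial condition is C/C0 = 1 throughout the reservoir and
    0 in the gel; the thin membrane starts at C/C0 = 1 by default
    (``membrane_prefilled=True``: adding the chemoattractant solution
    wets the membrane pores on contact, placing the initial step exactly
    at the membrane–gel interface, which is what holds that interface at
    C0/2 at early and intermediate times). Set ``membrane_prefilled=False``
    for a dry membrane. Diffusivity is D inside reservoir and gel and
    D·D_factor_membrane inside the membrane, harmonically averaged at
    cell faces. Time stepping is Crank–Nicolson by default;
    ``scheme="explicit"`` is accepted only when the CFL criterion
    ``max(D)·dt/dy² <= 0.5`` holds, otherwise :class:`StabilityError`.

    Returns the field on the full axis (reservoir at y < 0); snapshots
    are taken exactly at the requested ``t_grid_s`` (a shortened final
    sub-step is used when a requested time is not a multiple of dt).
    """

    if dy_mm <= 0 or dt_s <= 0:
        raise ValueError("dy_mm and dt_s must be positive")
    t_grid = np.atleast_1d(np.asarray(t_grid_s, dtype=float))
    if np.any(t_grid < 0) or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid_s must be non-negative and strictly increasing")

    n = int(round((geom.y_max_mm - geom.y_min_mm) / dy_mm))
    y_centers = geom.y_min_mm + (np.arange(n) + 0.5) * dy_mm
    D_cell = np.full(n, params.D_mm2_s)
    in_membrane = (y_centers > -geom.L_membrane_mm) & (y_centers < 0)
    D_cell[in_membrane] *= geom.D_factor_membrane
    D_face = 2.0 * D_cell[:-1] * D_cell[1:] / (D_cell[:-1] + D_cell[1:])

    if scheme == "crank-nicolson":
        theta = 0.5
    elif scheme == "explicit":
        theta = 0.0
        cfl = D_cell.max() * dt_s / dy_mm**2
        if cfl > 0.5:
            raise StabilityError(
                f"explicit scheme unstable: D*dt/dy^2 = {cfl:.3g} > 0.5; "
                f"reduce dt below {0.5 * dy_mm**2 / D_cell.max():.3g} s "
                "or use scheme='crank-nicolson'"
            )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    ab, bands = _banded_matrices(D_face, dy_mm, dt_s, theta)

    fill_to = 0.0 if membrane_prefilled else -geom.L_membrane_mm
    c = np.where(y_centers < fill_to, 1.0, 0.0)
    snapshots = np.empty((n, t_grid.size))
    t_now = 0.0
    for j, t_target in enumerate(t_grid):
        while t_now < t_target - 1e-9:
            step = min(dt_s, t_target - t_now)
            if abs(step - dt_s) < 1e-12:
                ab_step, bands_step = ab, bands
            else:
                ab_step, bands_step = _banded_matrices(D_face, dy_mm, step, theta)
            rhs = _apply_rhs(bands_step, c, theta)
            if theta > 0:
                c = linalg.solve_banded((1, 1), ab_step, rhs)
            else:
                c = rhs
            t_now += step
        snapshots[:, j] = c

    return ConcentrationField(y_centers, t_grid, snapshots)


@dataclass(frozen=True)
class DiffusionFit:
    """Result of a diffusion-coefficient fit."""

    D_cm2_s: float
    residual_norm: float
    n_obs: int
    model: str

    def to_dict(self) -> dict:
        return {
            "D_cm2_s": self.D_cm2_s,
            "residual_norm": self.residual_norm,
            "n_obs": self.n_obs,
            "model": self.model,
        }


def _as_observations(observations) -> np.ndarray:
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observations must be (n, 3): columns y_mm, t_s, c_norm")
    return obs


def fit_diffusion_coefficient(
    observations,
    model: str = "closed_form",
    geom: ChamberGeometry1D | None = None,
    *,
    D_bounds_cm2_s: tuple[float, float] = (1e-8, 1e-4),
    dy_mm: float = 0.05,
    dt_s: float = 30.0,
) -> DiffusionFit:
    """Least-squares estimate of D from (y, t, C/C0) observations.

    Minimizes Σ(C_obs − C_model(y, t; D))² over log10(D) on the bounded
    interval ``D_bounds_cm2_s`` with a bounded scalar minimizer; the log
    scale conditions the one-dimensional search. ``model="closed_form"``
    uses the erfc profile; ``model="numeric"`` re-solves the chamber at
    every candidate D and interpolates (``geom`` defaults to the standard
    chamber).
    """

    obs = _as_observations(observations)
    if obs.shape[0] < 3:
        raise FitError("need at least 3 observations")
    if np.unique(obs[:, 1]).size < 2:
        raise FitError("observations must span at least 2 distinct times")
    if np.allclose(obs[:, 2], 0.0):
        raise FitError("all-zero concentrations: D is unidentifiable")
    if model not in ("closed_form", "numeric"):
        raise ValueError(f"unknown model {model!r}")
    if model == "numeric" and geom is None:
        geom = ChamberGeometry1D()

    y, t, c_obs = obs.T
    t_unique = np.unique(t)

    def predict(D: float) -> np.ndarray:
        params = DiffusionParams(D_cm2_s=D)
        if model == "closed_form":
            return closed_form_profile(y, t, params)
        fld = solve_chamber_1d(geom, params, t_unique, dy_mm=dy_mm, dt_s=dt_s)
        return fld.at(y, t)

    from scipy.optimize import minimize_scalar

    def objective(log10_D: float) -> float:
        resid = c_obs - predict(10.0**log10_D)
        return float(resid @ resid)

    lo, hi = np.log10(D_bounds_cm2_s)
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    D_hat = float(10.0**res.x)
    return DiffusionFit(
        D_cm2_s=D_hat,
        residual_norm=float(np.sqrt(res.fun)),
        n_obs=obs.shape[0],
        model=model,
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map between mean gray level and tracer concentration.

    ``gray = slope * concentration + intercept`` within ``valid_range``
    (the concentration span of the calibration points).
    """

    slope: float
    intercept: float
    valid_range: tuple[float, float]
    r_squared: float = field(default=1.0)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")
        if not self.valid_range[0] < self.valid_range[1]:
            raise ValueError("valid_range must satisfy min < max")


def fit_calibration(points) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, gray level) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): columns concentration, gray_level")
    conc, gray = pts.T
    if np.unique(conc).size < 2:
        raise FitError("need at least 2 distinct concentrations")
    res = stats.linregress(conc, gray)
    if res.slope <= 0:
        raise FitError(f"fitted slope {res.slope:.3g} is not positive")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        valid_range=(float(conc.min()), float(conc.max())),
        r_squared=float(res.rvalue**2),
    )


def gray_to_concentration(curve: CalibrationCurve, gray):
    """Invert the calibration line; warns (never rejects) on extrapolation."""
    gray = np.asarray(gray, dtype=float)
    conc = (gray - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    n_out = int(np.count_nonzero((conc < lo) | (conc > hi)))
    if n_out:
        warnings.warn(
            f"{n_out} value(s) outside the calibrated range [{lo:g}, {hi:g}]; "
            "extrapolated",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return conc if conc.ndim else float(conc)


def concentration_to_gray(curve: CalibrationCurve, concentration):
    """Forward calibration map (used when synthesizing gray-level series)."""
    conc = np.asarray(concentration, dtype=float)
    gray = curve.slope * conc + curve.intercept
    return gray if gray.ndim else float(gray)
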