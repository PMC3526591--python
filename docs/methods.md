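# Methods

## Gradient model

The chamber is reduced to one spatial axis y: chemoattractant reservoir
(y < −L_mem), porous membrane (−L_mem < y < 0), collagen gel (0 < y <
L_gel). The reduction is justified by the transport physics: the membrane
spans the full chamber cross-section, so the concentration field depends
on the distance from the membrane only, except within a short distance of
the membrane-frame windows, which the package does not model.

**Closed form.** Treating the gel as a semi-infinite slab with the
interface held at C₀/2 (the symmetric split between two half-spaces of
equal diffusivity), C = 0 far away and C = 0 initially, the unique
solution of Fick's second law is C(y,t)/C₀ = ½·erfc(y/(2√(Dt))). The
singular corner (y = 0, t = 0) returns the boundary value 0.5, i.e. the
right-limit in t.

**Finite-difference solver.** A cell-centred conservative discretization
with no-flux at both outer walls, harmonic-mean face diffusivities (the
membrane section can carry a diffusivity factor ≤ 1), and Crank–Nicolson
stepping (an explicit scheme is accepted only when D·dt/dy² ≤ 0.5,
otherwise it refuses with a diagnostic). Because boundary faces are simply
omitted from the flux stencil, the column sums of the update operator
vanish and the discrete mass Σ C·dy is conserved to linear-solver
round-off at every step — the suite checks 10⁻⁶ relative over 2 h.
Requested output times that are not multiples of dt are landed on exactly
with one shortened sub-step.

*Initial condition.* By default the membrane section starts at C/C₀ = 1
along with the reservoir (`membrane_prefilled=True`): physically, adding
the chemoattractant solution wets the membrane pores on contact, and this
places the initial concentration step exactly at the membrane–gel
interface. This is what holds the interface at C₀/2 through the 2 h
window (measured: 0.500 ± 10⁻⁸ on the default geometry) and keeps the gel
profile within 0.2% of C₀ of the closed form at y ∈ {2, 3, 5} mm. With a
dry membrane (`membrane_prefilled=False`) the step sits at y = −L_mem and
the interface reads ~0.38–0.46 over the same window; the option exists
for sensitivity studies.

*Comparing solver and closed form.* Pointwise relative discrepancy is not
meaningful everywhere: before the front arrives both solutions are ~0, and
at the far gel wall the no-flux boundary doubles a ~10⁻³·C₀ tail relative
to the semi-infinite solution (an image-term effect). Agreement is
therefore stated as: |ΔC| ≤ 2% of C₀ everywhere on the observation
positions, and ≤ 2% pointwise wherever C/C₀ > 0.01.

**Defaults** (all configurable): L_reservoir = 20 mm (the reservoir must
dwarf the gel for the interface condition to hold ~2 h), L_membrane =
0.15 mm with diffusivity factor 1.0 (0.22 µm pores do not hinder a 10 kDa
tracer), L_gel = 5 mm, dy = 0.05 mm, dt = 10 s, D = 2·10⁻⁶ cm²/s.
Lengths are mm, times s, D cm²/s; all conversions live in one constants
table (`_units.py`); concentrations are carried normalized (C/C₀)
end-to-end.

**D estimation** minimizes Σ(C_obs − C_model)² over log₁₀D on the bounded
interval [10⁻⁸, 10⁻⁴] cm²/s with a deterministic bounded scalar
minimizer; the log scale conditions the search and the objective is
unimodal in practice. The `numeric` variant re-solves the chamber per
candidate D on a dy = 0.05 mm / dt = 30 s grid; coarser grids were found
to bias D̂ by several percent through the half-cell offset of the
interface, so the fit grid matches the solver default in space. The fit
refuses fewer than 3 observations, a single distinct time, or all-zero
concentrations (D is unidentifiable).

**Calibration** is ordinary least squares of mean gray level on
concentration (the assay's fluorescence response is linear across
0.2–120 µM). Inversion outside the fitted concentration range warns
(`ExtrapolationWarning`) but returns the value — pre-front noise
legitimately dips just below the range and must not be rejected.

## Motility statistics

All headline statistics use the XY projection by default: the z axis of a
stack is sampled an order of magnitude more coarsely than the in-plane
positions, so including z mostly adds quantization noise. `projection="xyz"`
is available throughout.

* **Curvilinear length** is the sum of inter-sample Euclidean distances in
  a window; a window with < 2 samples contributes 0. Coarser temporal
  sampling can only shorten a jagged path — a documented caveat (tested as
  an inequality), meaning path lengths are comparable only at equal frame
  rates.
* **Chemotactic index.** Per cell, I = (net displacement · ĝ)/L over
  [t_origin, t]; population value Σ IᵢLᵢ/Σ Lᵢ. Cells with L = 0 drop out
  through their zero weight (not as I = 0, which would bias the mean
  toward zero). The cumulative series is evaluated every 5 min from t = 0
  by default; an option computes it from the stimulus instead.
* **Motile fraction.** Per half-open 10-min window, the fraction of cells
  (≥ 2 samples in the window) whose net displacement strictly exceeds
  their diameter — "exceeds" is read as strict, so the boundary case is
  non-motile. Missing diameters default to 10 µm (typical neutrophil).
* **Velocities** are backward differences assigned to the right endpoint
  of each step, pooled per half-open 5-min bin. The modulus is averaged
  per frame, not taken of the mean — an isotropic population must show
  zero mean components with a positive mean modulus. Frame gaps are
  differenced over the actual elapsed time and logged when > 2× the
  nominal interval.
* **Biased-cell fraction.** Per bin and cell (≥ 3 velocity samples), a
  two-sided one-sample t-test of each velocity component against zero;
  the reported percentage counts rejections at p < 0.05, with no
  multiple-testing correction — the statistic is a per-cell tally, not an
  inference on any single cell. The modulus is strictly positive under
  any null, so a zero-mean test would be meaningless for it; instead the
  modulus sample is tested against the bin's population-mean modulus
  (null: this cell's speed matches the population's). Both are reported;
  they answer different questions. Zero-variance samples (degenerate t)
  reject iff their value differs from the null mean. The t statistic and
  p-value are computed vectorized across cells; this matches
  `scipy.stats.ttest_1samp` exactly and is two orders of magnitude faster
  at 1000 cells.

  The 5% type-I calibration of these tests holds for serially independent
  velocity samples. Persistent walks are AR(1)-correlated within a bin
  (variance of the 5-sample mean inflated ~2.2× at persistence 0.5), so
  the nominal-level check in the suite runs on persistence-0 walks; on
  persistent walks the same test over-rejects by construction, which is a
  property of the t-test, not of the implementation.

## Synthetic experiments

The generator is the package's test bed: a biased persistent random walk
whose movers update v(t+Δt) = α·v(t) + (1−α)·(drift·ĝ + s·η) with η
standard normal per axis, α the persistence, s the speed scale of the
current period, and drift = χ·|∂(C/C₀)/∂y| evaluated from a simulated
concentration field at the cell's position — so the directed response
switches on only when the diffusing front actually reaches the cell.
Non-movers jitter (σ = 0.3 µm) about an anchor; mover status re-draws at
the stimulus (reproducing the observed rise in motile fraction), and a
cell that stops re-anchors at its current position. All randomness flows
from one `numpy` Generator seeded by `seed`; identical seeds give
byte-identical tracks.

Defaults mirror the emulated experiment: 70 cells, 110 min at 1
frame/min, stimulus at 30 min, cells seeded in a 1 × 1 mm × 100 µm volume
centred 2 mm from the membrane, gradient toward (0, −1, 0). Speed scales
(0.5–3.5 µm/min across profiles) sit in the observed neutrophil range.
The optional exponential envelope on χ (`envelope_tau_min`) phenomenologically
reproduces the transient, adapting response; no receptor-level mechanism
is claimed. The fixture profiles encode the two qualitative donor
behaviours: `donorA-like` (low baseline motility, index ~0 pre-stimulus,
rising to a ~0.25 plateau; χ = 12), `donorB-like` (higher baseline, a
pre-existing orientation bias modelled as a constant 0.4 µm/min baseline
drift giving pre-stimulus I ≈ 0.25 — an explicit modelling choice, the
biological origin of such baselines being unknown — with a strong decaying
coupling, χ = 600, τ = 12 min, so the cumulative index peaks near 0.5 and
decays), and `isotropic` (no coupling, no stimulus change). Because the
cumulative index averages over the whole history, its post-peak decay is
intrinsically slower than that of any instantaneous read-out.

What the generator does *not* emulate: segmentation/tracking errors and
track fragmentation, cell–cell interactions and collisions, gel
remodelling or contact guidance, chemoattractant consumption by cells,
and z-anisotropic motility. Passing recovery tests therefore demonstrates
correctness of the estimators under the model's assumptions, not
robustness to those real-data artefacts.

## Problem sizes and determinism

The suite simulates 70–1000 cells × 110 frames and solves the chamber on
~500 nodes × 720 steps, sizes at which every statistic is
sampling-error-limited rather than discretization-limited; estimator
recovery is asserted within 2 standard errors across 10 seeds.
`scripts/acceptance.py` derives all randomness from its `--seed` and
recomputes its outputs from scratch on every run. Pipeline runs with the
same seed produce byte-identical CSV/JSON artifacts (checked by checksum).

## Known limitations

* 1-D transport only; frame-window (x-direction) effects near the
  membrane are out of scope.
* No convection, degradation or cell consumption of chemoattractant.
* The biased fraction for the velocity modulus is an interpretation (see
  above); the component tests are the exact classical procedure.
* Trajectories are taken as given; detection, linking and gap-closing
  belong to upstream tracking software.
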