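# Methods

## Transport model

The mother cell is an ellipsoid of revolution (full major axis ℓx along
x, full minor axis ℓy on both transverse axes) centred in a rectangular
domain (default 10.5 × 6.6 × 6.6 µm). A voxel belongs to the interior
when its centre satisfies the ellipsoid inequality; the stair-step
boundary this produces converges under refinement (volume error < 2% at
64×40×40, < 0.5% at 200×120×120) and is checked by refinement tests.
The default desk-scale grid is 64×40×40; the full-fidelity 200×120×120
grid used for reference runs is available through configuration.

Vesicle concentration obeys

    dCv/dt = kgen − kon · Cv · Σ_n γn Φn + Dv ∇²Cv,

with Φn(x) = exp(−‖x − xn‖/β) evaluated at interior voxel centres
(3-D Euclidean distance to the bud neck; buds themselves are not
meshed) and γn = 1/(Σ Φn · voxel volume), so the normalisation
γn ∫ Φn dV = 1 holds exactly in the same quadrature the solver uses.
The per-bud placement of γn inside the sink term follows from the
normalisation condition and the per-bud recruitment integral; the model
is linear in Cv throughout.

**Boundary condition.** Zero diffusive flux is realised ghost-cell-free:
the discrete Laplacian exchanges fluxes only between pairs of interior
voxels, so a missing neighbour simply contributes no flux. Summing the
discrete equation over the cell then telescopes all internal fluxes and
gives exact mass balance: at steady state Σ rates = kgen·Vcell to the
linear-solver tolerance.

**Solvers.** (i) Explicit Euler with the reference default step
dt = 1e-4 s, guarded by dt ≤ min(h)²/(6 Dv); the stepper refuses to run
otherwise. Steadiness is declared when the largest relative per-bud
rate change per simulated second drops below `steady_tol` (default
1e-6). The initial condition is Cv = 0 (any initial condition converges
to the same steady state by linearity; a uniform closed-form guess is a
useful warm start). (ii) The steady state solves the SPD sparse system
(kon·S − Dv·L) Cv = kgen over interior voxels by Jacobi-preconditioned
conjugate gradients (rtol 1e-12, sparse-direct fallback). The two
solvers agree on per-bud rates to < 0.5% at 64×40×40.

**Units.** Lengths µm, times s in the model (minutes in imaging series),
volumes µm³, concentrations vesicles·µm⁻³. CVs throughout the package
use the sample (n−1) standard deviation.

## Behaviour of the delivery CV

With symmetric placements the CV vanishes identically (mirror-symmetric
grids give bitwise-equal fields). For the adjacent-pair geometry the CV

- increases with kon (more cables → stronger local depletion),
- decreases with Dv at fixed kon (diffusion homogenises Cv; as Dv → 0
  capture shares tend to the winner-take-all catchment-basin partition,
  as Dv → ∞ the uniform solution equalises all rates),
- peaks at intermediate β ≈ 0.5–1 µm, where cable networks from the
  adjacent buds (3 µm apart at the default 60° separation) begin to
  overlap; at β = 10 µm capture is spread over the whole cell and the
  CV collapses.

When kon is tied to Dv through the Smoluchowski relation kon = kon*·Dv,
the CV is exactly independent of Dv: dividing the steady equation by Dv
leaves kon* and β as the only shape parameters. This reconciles the
intuition that slow diffusion mitigates depletion — slow diffusion also
means proportionally slower (diffusion-limited) capture.

A numerical caveat: β at or below the voxel size (β = 0.1 µm on desk
grids) makes the field a near-singular point sink whose CV does not
converge under grid refinement; quantitative statements at that corner
require β-resolving grids, so ordering tests use β ≥ 0.5 µm for the
small-β side.

## Particle oracle

The stochastic check injects point particles uniformly in the interior
(matching the homogeneous source), steps them with isotropic Gaussian
displacements (per-axis variance 2·Dv·dt), and rejects-and-resamples
steps that exit the ellipsoid (unbiased for small steps; capped
retries). Capture per step occurs with probability
1 − exp(−kon·S(x)·dt) against the *discretised* field at the particle's
voxel — deliberately the same lookup the mean-field sink uses — and the
captured particle is assigned to a bud with probability ∝ γnΦn(x).
Because the model is linear, the capture shares of a uniformly injected
cohort equal the steady per-bud rate shares, which is the cross-method
test. The step size must satisfy sqrt(6·Dv·dt) < min(β, voxel size).
In the reaction-limited regime capture positions distribute like the
actin field itself; against the half-space exponential profile the
fraction of captures within x·β of a neck is the incomplete-gamma
fraction γ(3, x)/2!, ≈ 87% within 5β and ≥ 95% within 7β, which the
tests verify. (In the opposite, saturated limit kon → ∞ the per-step
capture probability approaches 1 everywhere and captures become uniform
over the cell — large kon does **not** localise captures.)

## Morphometric statistics

Per-mother sibling CV = sample sd / mean of that mother's bud volumes;
single-budded mothers are counted but excluded from CVs. Class means
use the 2 / 3 / 4 / ≥5 grouping; the population comparator pools all
bud volumes across mothers. The summed-volume fit is OLS with an
intercept (through-origin is not assumed). The positional test counts
three-budded mothers whose single "distant" bud is strictly largest and
compares [k, n−k] to the [1/3, 2/3] null with an uncorrected df=1
chi-square (ties count as not-largest and are flagged; they have
measure zero on continuous data). For k = 20, n = 49 this gives
χ² ≈ 1.23, p ≈ 0.267; an exact binomial enumeration is provided as an
independent small-n check. Growth rates are OLS slopes of volume vs
time over post-emergence frames (emergence = first frame above 1 µm³,
configurable); the compensation flag fires when the slower/faster
sibling rate ratio in the last third of a series exceeds the
first-third ratio by more than 0.25 — i.e. initially unequal buds
converge, as feedback models predict and the accuracy model forbids.

## Image quantification

Per frame: intensities outside the cell mask are zeroed; the dimmer
channel (by in-mask mean — ordinarily the cable marker) is scaled so
both channels match in mean; the cytosol channel is subtracted
voxelwise; negative residuals are clamped to zero (intensities are
physical). Scaling is computed per frame (configurable). The windowed
sibling CV is the CV across siblings of per-bud means over consecutive
non-overlapping windows (default 10 frames), matching the averaging
described for the tropomyosin probe — not the mean of per-frame CVs.
For independent per-frame fluctuations the windowed CV is ~1/sqrt(10)
of the instantaneous CV, a relation the tests verify on synthetic
signals; a general bound (windowed CV ≤ max instantaneous CV in the
window) holds for any input.

## Synthetic generators

The bud-volume generator draws mother volumes log-uniformly over a
70-fold span (default max 2100 µm³ — a realistic large multinucleate
mother; all downstream statistics are scale-free). Bud number follows
monotone volume-quantile thresholds whose class shares mirror observed
cohorts (~8% single-budded, ~30% two-budded, geometrically decaying
tail to 20), with ±1 jitter so the rule is not a hard step. Each
mother's bud allotment is 0.45 of its volume times lognormal noise
(sd 0.05), split among buds by a symmetric Dirichlet — chosen over
independent lognormals so the summed fraction is exact by construction,
matching the fixed-growth-potential picture. The Dirichlet
concentration per bud-number class is calibrated by fixed-seed Monte
Carlo so the expected sample CV hits the class target: 0.12 for
two-budded mothers, and a common ≥3-bud target solved from the realised
class counts so the cohort-wide mean CV is 0.20. The calibration uses a
second-moment initial guess (E[CV²] = k/(kα+1)) refined by a
three-step fixed-point correction; it reproduces targets within 1% of
Monte Carlo at 1e5 draws. Three-budded mothers get one "distant" and
two "adjacent" labels at random, so position does not predict size by
construction.

Growth series are linear trajectories with lognormal rate multipliers
(CV 0.15 default), uniform emergence jitter (0–10 min), 5-min frames
over 3 h; the compensation switch replaces every bud's rate by the
sibling mean halfway through, emulating a feedback model. Image stacks
default to 17 z-slices at 0.7 µm: cytosol = flat level on the cell mask
+ Gaussian noise; cable = a fixed proportion of the cytosol signal +
per-bud amplitudes fluctuating lognormally per frame (ground truth
recorded in metadata) + noise. No PSF convolution or photon statistics
are simulated, so passing tests demonstrate correctness of the
*procedures*, not robustness to real microscopy artefacts
(segmentation error, bleaching, registration drift).

All generators are deterministic given their seed and return a
metadata dict sufficient to regenerate outputs exactly.

## Problem sizes and numerical choices

Solver tests run at 32×20×20 to 64×40×40 with cross-resolution checks
(< 3% rate change under voxel halving at β = 3 µm); the particle
cross-check uses 1e4 particles (binomial SE ≈ 0.5% per share); cohort
statistics use n = 200 mothers, where the slope is recovered to ±0.005
and class-mean CVs to about ±0.01–0.015 (1 sd). Time-stepper
comparisons start from the uniform closed-form guess to shorten the
approach to steady state; this does not affect the fixed point.

## Known limitations

- Bud geometry is static: no exocytosis-driven growth feedback, cable
  turnover stochasticity, or cytoplasmic advection.
- The actin field kernel is taken literally as an exponential in
  Euclidean distance; along-surface or traced-cable geometries are out
  of scope (sensitivity to the kernel is left to users).
- The β ≲ voxel-size corner of parameter space is numerically singular
  (see above).
- The bud-number rule is a documented stand-in for an observed trend,
  not a fitted relation.
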