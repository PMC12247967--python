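"""Stochastic particle simulation of vesicle diffusion and capture.

An independent, brute-force check on the mean-field transport solver:
point vesicles are injected uniformly over the cell interior, take
Brownian steps (reflected at the cell boundary by reject-and-resample),
and at each step are captured with probability
``1 - exp(-kon * S(x) * dt)`` where ``S = sum_n gamma_n Phi_n`` is the
local capture weight evaluated at the particle's voxel.  A captured
particle is assigned to bud ``n`` with probability proportional to
``gamma_n Phi_n`` at that voxel.  Because the transport model is linear,
the long-time capture fractions of a uniformly injected cohort equal the
per-bud shares of the steady-state recruitment rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ActinFieldSet, EllipsoidGrid
from .transport import TransportParams

__all__ = ["ParticleRunSpec", "ParticleResult", "simulate_particles"]

_MAX_REFLECT_RETRIES = 50


@dataclass(frozen=True)
class ParticleRunSpec:
    n_particles: int = 10_000
    step_dt: float = 0.01
    seed: int = 0
    max_time: float = 5_000.0

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.step_dt <= 0 or self.max_time <= 0:
            raise ValueError("step_dt and max_time must be positive")


@dataclass(frozen=True)
class ParticleResult:
    """Capture fractions among captured particles, with binomial SEs."""

    fractions: np.ndarray
    standard_errors: np.ndarray
    n_captured: int
    n_particles: int
    capture_positions: np.ndarray  # (n_captured, 3)
    capture_buds: np.ndarray  # (n_captured,)
    seed: int


def _voxel_indices(grid: EllipsoidGrid, pos: np.ndarray) -> tuple[np.ndarray, ...]:
    idx = []
    for axis in range(3):
        L = grid.domain_lengths[axis]
        h = grid.voxel_sizes[axis]
        i = np.floor((pos[:, axis] + L / 2) / h).astype(np.int64)
        idx.append(np.clip(i, 0, grid.counts[axis] - 1))
    return tuple(idx)


def _inside(grid: EllipsoidGrid, pos: np.ndarray) -> np.ndarray:
    a = grid.major_axis / 2.0
    b = grid.minor_axis / 2.0
    return (pos[:, 0] / a) ** 2 + (pos[:, 1] / b) ** 2 + (pos[:, 2] / b) ** 2 <= 1.0


def _sample_interior(grid: EllipsoidGrid, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the ellipsoid (rejection from the bounding box)."""
    a = grid.major_axis / 2.0
    b = grid.minor_axis / 2.0
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-1, 1, size=(2 * (n - filled) + 16, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        cand = cand[keep][: n - filled]
        out[filled : filled + len(cand)] = cand * np.array([a, b, b])
        filled += len(cand)
    return out


def simulate_particles(
    grid: EllipsoidGrid,
    fields: ActinFieldSet,
    params: TransportParams,
    spec: ParticleRunSpec,
) -> ParticleResult:
    """Run the Brownian capture simulation.

    The step length must resolve both the actin length scale and the voxel
    size: sqrt(6 Dv dt) is required to be below min(beta, voxel size).
    Results are bit-reproducible for a fixed ``spec.seed``.
    """
    if params.kon <= 0:
        raise ValueError("particle capture requires kon > 0")
    sigma_step = np.sqrt(6.0 * params.Dv * spec.step_dt)
    resolution = min(fields.beta, min(grid.voxel_sizes))
    if sigma_step >= resolution:
        raise ValueError(
            f"step_dt too large: rms step {sigma_step:.3g} µm must be below "
            f"min(beta, voxel size) = {resolution:.3g} µm"
        )

    rng = np.random.default_rng(spec.seed)
    nbud = fields.nbud
    # Per-voxel capture weights gamma_n * Phi_n, flattened bud-major.
    weights = fields.gamma[:, None, None, None] * fields.phi
    total_weight = weights.sum(axis=0)

    pos = _sample_interior(grid, spec.n_particles, rng)
    captured_bud: list[np.ndarray] = []
    captured_pos: list[np.ndarray] = []

    sd = np.sqrt(2.0 * params.Dv * spec.step_dt)
    t = 0.0
    while t < spec.max_time and len(pos) > 0:
        step = rng.normal(0.0, sd, size=pos.shape)
        new = pos + step
        bad = ~_inside(grid, new)
        retries = 0
        while bad.any():
            retries += 1
            if retries > _MAX_REFLECT_RETRIES:
                raise RuntimeError(
                    f"{bad.sum()} particles failed boundary reflection after "
                    f"{_MAX_REFLECT_RETRIES} resampling attempts"
                )
            new[bad] = pos[bad] + rng.normal(0.0, sd, size=(int(bad.sum()), 3))
            bad = ~_inside(grid, new)
        pos = new
        t += spec.step_dt

        ix = _voxel_indices(grid, pos)
        local_total = total_weight[ix]
        p_capture = -np.expm1(-params.kon * local_total * spec.step_dt)
        hit = rng.random(len(pos)) < p_capture
        if hit.any():
            hit_idx = np.nonzero(hit)[0]
            w = weights[:, ix[0][hit_idx], ix[1][hit_idx], ix[2][hit_idx]]  # (nbud, nhit)
            w = w / w.sum(axis=0, keepdims=True)
            u = rng.random(len(hit_idx))
            bud = (np.cumsum(w, axis=0) < u).sum(axis=0)
            bud = np.minimum(bud, nbud - 1)
            captured_bud.append(bud)
            captured_pos.append(pos[hit_idx])
            pos = pos[~hit]

    buds = np.concatenate(captured_bud) if captured_bud else np.empty(0, dtype=int)
    cpos = np.concatenate(captured_pos) if captured_pos else np.empty((0, 3))
    n_cap = len(buds)
    if n_cap == 0:
        fractions = np.zeros(nbud)
        ses = np.zeros(nbud)
    else:
        fractions = np.bincount(buds, minlength=nbud) / n_cap
        ses = np.sqrt(fractions * (1 - fractions) / n_cap)
    return ParticleResult(
        fractions=fractions,
        standard_errors=ses,
        n_captured=n_cap,
        n_particles=spec.n_particles,
        capture_positions=cpos,
        capture_buds=buds,
        seed=spec.seed,
    )
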