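"""Synthetic-data generation for every pipeline stage.

The generators emulate the statistical structure of a multi-budding
yeast cohort: mother volumes spanning a ~70-fold range, 1–20 buds per
mother with bud number increasing with mother volume, summed sibling bud
volume equal to a fixed fraction (default 0.45) of the mother volume,
and sibling-volume dispersion targeting a mean CV of 0.12 for two-budded
mothers and 0.20 across all multi-budded mothers.  Sibling volumes are a
symmetric-Dirichlet split of the mother's bud allotment, so the summed
fraction is exact by construction and the per-class dispersion is set by
the Dirichlet concentration, which is calibrated by Monte Carlo to hit a
target expected sample CV.

Growth-trajectory and two-channel image-stack generators provide ground
truth for the growth-rate and cable-quantification analyses.  All
generators are deterministic given their seed and return a metadata dict
sufficient to regenerate their output exactly.
"""

from __future__ import annotations

import functools
from dataclasses import asdict, dataclass, field

import numpy as np

from .budstats import BudVolumeTable, GrowthSeries
from .imaging import SegmentationMasks, TwoChannelStack

__all__ = [
    "GeneratorParams",
    "gen_bud_volume_table",
    "gen_growth_series",
    "gen_two_channel_stack",
    "dirichlet_alpha_for_cv",
    "expected_sibling_cv",
    "default_class_probs",
]


def default_class_probs(k_max: int = 20) -> dict[int, float]:
    """Default bud-number distribution (monotone classes, most mothers few-budded).

    Mirrors the shape of observed cohorts: ~8% single-budded, ~30%
    two-budded, then a geometrically decaying tail out to ``k_max``.
    """
    probs = {1: 0.08, 2: 0.30, 3: 0.23, 4: 0.11}
    tail = np.array([0.8**(k - 5) for k in range(5, k_max + 1)])
    tail = 0.28 * tail / tail.sum()
    for k, p in zip(range(5, k_max + 1), tail):
        probs[k] = float(p)
    total = sum(probs.values())
    return {k: p / total for k, p in probs.items()}


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition parameters for the synthetic generators.

    ``seed`` is mandatory and recorded in every output's metadata.
    """

    seed: int
    n_mothers: int = 200
    mother_volume_max: float = 2100.0  # µm³
    fold_span: float = 70.0
    summed_fraction: float = 0.45
    cv_two_bud: float = 0.12
    cv_overall: float = 0.20
    total_noise_sd: float = 0.05  # lognormal sd on each mother's bud allotment
    bud_count_max: int = 20
    jitter_probs: tuple[float, float, float] = (0.2, 0.6, 0.2)
    # growth-series settings
    t_total_min: float = 180.0
    frame_min: float = 5.0
    growth_rate_cv: float = 0.15
    emergence_jitter_min: float = 10.0
    compensation: bool = False
    rate_multipliers: tuple | None = None
    # imaging settings (defaults: 17 z-slices at 0.7 µm)
    n_frames: int = 12
    stack_shape: tuple[int, int, int] = (17, 40, 40)
    stack_voxel: tuple[float, float, float] = (0.7, 0.2, 0.2)
    frame_interval_min: float = 1.0
    cytosol_level: float = 100.0
    cable_proportion: float = 0.5
    cable_amplitudes: tuple = (20.0, 35.0, 50.0)
    amplitude_fluctuation: float = 0.3
    image_noise_sd: float = 2.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 < self.summed_fraction < 1):
            raise ValueError("summed_fraction must lie in (0, 1)")
        if self.cv_two_bud < 0 or self.cv_overall < 0 or self.total_noise_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if self.fold_span < 1:
            raise ValueError("fold_span must be >= 1")

    def metadata(self) -> dict:
        meta = asdict(self)
        meta["generator"] = "multibud.synth"
        return meta


# ---------------------------------------------------------------------------
# Dirichlet concentration <-> sibling CV calibration

def expected_sibling_cv(k: int, alpha: float, n_draws: int = 100_000, seed: int = 1_234_567) -> float:
    """Monte Carlo estimate of E[sample CV] of a symmetric Dirichlet(k, alpha) split."""
    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.full(k, alpha), size=n_draws)
    cvs = shares.std(axis=1, ddof=1) / shares.mean(axis=1)
    return float(cvs.mean())


@functools.lru_cache(maxsize=256)
def dirichlet_alpha_for_cv(k: int, target_cv: float, n_draws: int = 100_000) -> float:
    """Concentration alpha such that the expected sibling sample CV hits target.

    The second moment of a symmetric Dirichlet gives the starting point
    (E[CV²] = k/(k·alpha+1)); a short fixed-point iteration then corrects
    the sqrt-of-second-moment bias using fixed-seed Monte Carlo estimates
    of E[CV].  The correction ratio varies slowly with alpha, so three
    iterations suffice for sub-percent accuracy.  Rejects targets at or
    beyond the degenerate one-bud-takes-all bound sqrt(k).
    """
    if k < 2:
        raise ValueError("sibling CV undefined for fewer than 2 buds")
    bound = float(np.sqrt(k))
    if target_cv <= 0:
        raise ValueError("target CV must be positive (use dispersion 0 explicitly)")
    if target_cv >= 0.95 * bound:
        raise ValueError(
            f"target CV {target_cv} infeasible for {k} buds (must be well below "
            f"the one-hot bound sqrt({k}) = {bound:.3f})"
        )

    def moment_alpha(cv_rms: float) -> float:
        return max((k / cv_rms**2 - 1.0) / k, 1e-4)

    alpha = moment_alpha(target_cv)
    for it in range(3):
        est = expected_sibling_cv(k, alpha, n_draws=n_draws, seed=1_234_567 + it)
        ratio = est / np.sqrt(k / (k * alpha + 1.0))  # E[CV]/sqrt(E[CV²]) ≤ 1
        alpha = moment_alpha(target_cv / ratio)
    return float(alpha)


# ---------------------------------------------------------------------------
# Bud-volume tables

def _bud_counts(volumes: np.ndarray, p: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Monotone bud-number rule: class thresholds on log-volume quantile, ±1 jitter."""
    probs = default_class_probs(p.bud_count_max)
    ks = np.array(sorted(probs))
    cum = np.cumsum([probs[k] for k in ks])
    vmin = p.mother_volume_max / p.fold_span
    u = np.log(volumes / vmin) / np.log(p.fold_span)
    base = ks[np.searchsorted(cum, np.clip(u, 0, 1), side="left").clip(0, len(ks) - 1)]
    jitter = rng.choice([-1, 0, 1], size=len(base), p=p.jitter_probs)
    return np.clip(base + jitter, 1, p.bud_count_max)


def _class_cv_targets(counts: np.ndarray, p: GeneratorParams) -> dict[int, float]:
    """Per-class CV targets: 0.12 (default) for two-budded; a common value for
    k>=3 chosen so the expected mean per-mother CV over all multi-budded
    mothers equals the overall target."""
    n2 = int((counts == 2).sum())
    n3p = int((counts >= 3).sum())
    targets = {2: p.cv_two_bud}
    if n3p > 0:
        c = (p.cv_overall * (n2 + n3p) - p.cv_two_bud * n2) / n3p
        if c <= 0:
            raise ValueError(
                "overall CV target infeasible given the two-bud target and "
                f"class mix (implied >=3-bud target {c:.3f} <= 0)"
            )
        for k in np.unique(counts[counts >= 3]):
            targets[int(k)] = c
    return targets


def gen_bud_volume_table(p: GeneratorParams) -> tuple[BudVolumeTable, dict]:
    """Generate a cohort of mothers with Dirichlet-split sibling bud volumes.

    Mother volumes are log-uniform over the fold span; each mother's bud
    allotment is ``summed_fraction * V`` (times optional lognormal noise)
    split among its buds by a symmetric Dirichlet whose concentration is
    calibrated per bud-number class.  Three-budded mothers receive one
    'distant' and two 'adjacent' labels at random.
    """
    rng = np.random.default_rng(p.seed)
    vmin = p.mother_volume_max / p.fold_span
    volumes = np.exp(rng.uniform(np.log(vmin), np.log(p.mother_volume_max), p.n_mothers))
    counts = _bud_counts(volumes, p, rng)
    targets = _class_cv_targets(counts, p)

    ids, buds, labels = [], [], []
    for i, (V, k) in enumerate(zip(volumes, counts)):
        total = p.summed_fraction * V
        if p.total_noise_sd > 0:
            total *= np.exp(rng.normal(0.0, p.total_noise_sd))
        if k == 1:
            split = np.array([total])
        else:
            target = targets[int(k)]
            if target == 0:
                shares = np.full(k, 1.0 / k)
            else:
                alpha = dirichlet_alpha_for_cv(int(k), round(float(target), 3))
                shares = rng.dirichlet(np.full(k, alpha))
            split = total * shares
        ids.append(f"m{i:04d}")
        buds.append(split)
        if k == 3:
            lab = ["adjacent", "adjacent", "distant"]
            rng.shuffle(lab)
            labels.append(tuple(lab))
        else:
            labels.append(("",) * k)

    table = BudVolumeTable(
        mother_ids=tuple(ids),
        mother_volumes=volumes,
        bud_volumes=tuple(buds),
        bud_labels=tuple(labels),
        maturity=("cytokinesis-stage",) * p.n_mothers,
    )
    meta = p.metadata()
    meta["class_cv_targets"] = {str(k): float(v) for k, v in targets.items()}
    return table, meta


# ---------------------------------------------------------------------------
# Growth series

def gen_growth_series(p: GeneratorParams, n_mothers: int | None = None) -> tuple[GrowthSeries, dict]:
    """Linear bud-growth trajectories with emergence jitter.

    Per-bud rates are the mother's mean rate times lognormal multipliers
    with the configured rate CV (or explicit ``rate_multipliers``).  With
    ``compensation=True`` every bud's rate switches to the sibling mean
    halfway through the series, emulating a feedback model; the default
    emulates the accuracy model (persistent rates, no convergence).
    """
    rng = np.random.default_rng(p.seed + 1)
    n = n_mothers if n_mothers is not None else max(1, p.n_mothers // 10)
    times = np.arange(0.0, p.t_total_min + 1e-9, p.frame_min)
    ids, tlist, trajs, emergences = [], [], [], []
    vmin = p.mother_volume_max / p.fold_span
    for i in range(n):
        V = np.exp(rng.uniform(np.log(vmin), np.log(p.mother_volume_max)))
        k = int(rng.integers(2, 5))
        mean_rate = p.summed_fraction * V / k / p.t_total_min  # µm³/min
        if p.rate_multipliers is not None:
            mult = np.resize(np.asarray(p.rate_multipliers, dtype=float), k)
        else:
            mult = np.exp(rng.normal(0.0, p.growth_rate_cv, k))
        rates = mean_rate * mult
        if (rates < 0).any():
            raise ValueError("negative growth rate generated")
        t_emerge = rng.uniform(0.0, p.emergence_jitter_min, k)
        traj = np.zeros((k, len(times)))
        t_switch = p.t_total_min / 2.0
        for b in range(k):
            dt_grow = np.clip(times - t_emerge[b], 0.0, None)
            v = rates[b] * dt_grow
            if p.compensation:
                late = times > t_switch
                v_switch = rates[b] * max(t_switch - t_emerge[b], 0.0)
                v[late] = v_switch + rates.mean() * (times[late] - t_switch)
            traj[b] = v
        ids.append(f"g{i:04d}")
        tlist.append(times.copy())
        trajs.append(traj)
        emergences.append(t_emerge)
    series = GrowthSeries(
        mother_ids=tuple(ids),
        times=tuple(tlist),
        trajectories=tuple(trajs),
        emergence_times=tuple(emergences),
    )
    return series, p.metadata()


# ---------------------------------------------------------------------------
# Two-channel image stacks

def _sphere_mask(shape, centre, radius) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2 <= radius**2


def _ellipsoid_mask(shape, centre, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - centre[0]) / semi[0]) ** 2
        + ((yy - centre[1]) / semi[1]) ** 2
        + ((xx - centre[2]) / semi[2]) ** 2
        <= 1.0
    )


def gen_two_channel_stack(p: GeneratorParams) -> tuple[TwoChannelStack, SegmentationMasks, dict]:
    """Synthetic cable/cytosol stack with known per-bud cable amplitudes.

    The cytosol channel is a flat level on the cell mask plus Gaussian
    noise; the cable channel is a fixed proportion of the cytosol signal
    plus, inside each bud mask, a per-frame fluctuating cable amplitude
    (lognormal about the configured per-bud means).  Ground-truth
    amplitudes per bud and frame are returned in the metadata.
    """
    rng = np.random.default_rng(p.seed + 2)
    shape = p.stack_shape
    mother = _ellipsoid_mask(shape, (shape[0] // 2, shape[1] // 2, 12), (6, 10, 10))
    bud_centres = [(shape[0] // 2, 10, 28), (shape[0] // 2, 20, 32), (shape[0] // 2, 30, 28)]
    nbud = len(p.cable_amplitudes)
    if nbud > len(bud_centres):
        raise ValueError(f"at most {len(bud_centres)} buds supported by the stack layout")
    spheres = [_sphere_mask(shape, c, 4) for c in bud_centres[:nbud]]
    bud_masks = []
    taken = mother.copy()
    for s in spheres:
        bm = s & ~taken
        if not bm.any():
            raise RuntimeError("internal error: bud mask vanished")
        bud_masks.append(bm)
        taken |= bm
    cell = taken
    masks = SegmentationMasks(cell_mask=cell, bud_masks=tuple(bud_masks))

    amps = np.zeros((p.n_frames, nbud))
    cable = np.zeros((p.n_frames,) + shape)
    cytosol = np.zeros_like(cable)
    for f in range(p.n_frames):
        cyt = p.cytosol_level * cell + rng.normal(0.0, p.image_noise_sd, shape)
        cab = p.cable_proportion * p.cytosol_level * cell + rng.normal(
            0.0, p.image_noise_sd, shape
        )
        for b, bm in enumerate(bud_masks):
            mean_amp = p.cable_amplitudes[b]
            if mean_amp > 0:
                a = mean_amp * np.exp(
                    rng.normal(-0.5 * p.amplitude_fluctuation**2, p.amplitude_fluctuation)
                )
            else:
                a = 0.0
            amps[f, b] = a
            cab[bm] += a
        cytosol[f] = np.clip(cyt, 0.0, None)
        cable[f] = np.clip(cab, 0.0, None)

    stack = TwoChannelStack(
        cable=cable,
        cytosol=cytosol,
        voxel_sizes=p.stack_voxel,
        frame_interval=p.frame_interval_min,
    )
    meta = p.metadata()
    meta["true_amplitudes"] = amps.tolist()
    return stack, masks, meta
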