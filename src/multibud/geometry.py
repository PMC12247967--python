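"""Ellipsoidal cell geometry, bud placement, and per-bud actin intensity fields.

The mother cell of a multi-budding yeast is approximated as a prolate
ellipsoid with full major axis ``lx`` (aligned with x) and full minor axis
``ly`` applied to both transverse axes.  The ellipsoid is embedded in a
rectangular domain and discretised on a regular voxel lattice; a voxel
belongs to the cell interior when its centre satisfies the ellipsoid
inequality.  Buds sit on the ellipsoid surface and each contributes a
normalised actin-intensity field

    Phi_n(x) = exp(-||x - x_n|| / beta)

restricted to the interior, with a per-bud constant ``gamma_n`` chosen so
that ``gamma_n * ∫ Phi_n dV = 1``.  The gammas equalise total actin
intensity across buds, so only bud *placement* (not cable amount) can
produce asymmetric vesicle delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EllipsoidGrid",
    "BudSet",
    "ActinFieldSet",
    "build_grid",
    "place_buds",
    "build_actin_fields",
    "PLACEMENT_PRESETS",
]


@dataclass(frozen=True)
class EllipsoidGrid:
    """Masked voxel lattice representing the mother-cell interior.

    Lengths are in micrometres.  ``interior_mask`` has shape
    ``(nx, ny, nz)``; axis 0 is x (the major axis).
    """

    major_axis: float
    minor_axis: float
    domain_lengths: tuple[float, float, float]
    counts: tuple[int, int, int]
    voxel_sizes: tuple[float, float, float]
    interior_mask: np.ndarray = field(repr=False)
    cell_volume: float = 0.0

    @property
    def voxel_volume(self) -> float:
        hx, hy, hz = self.voxel_sizes
        return hx * hy * hz

    @property
    def n_interior(self) -> int:
        return int(self.interior_mask.sum())

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along each axis, cell centred at origin."""
        out = []
        for L, n, h in zip(self.domain_lengths, self.counts, self.voxel_sizes):
            out.append(-L / 2 + h * (np.arange(n) + 0.5))
        return tuple(out)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, y, z = self.axis_coordinates()
        return np.meshgrid(x, y, z, indexing="ij")

    def boundary_faces(self) -> list[tuple[tuple[int, int, int], int, int]]:
        """Interior↔exterior voxel-face adjacencies.

        Returns a list of ``(interior_index, axis, direction)`` entries with
        direction ±1, encoding the stair-step approximation of the cell
        boundary across which the no-flux condition applies.  Faces on the
        domain boundary itself are included (they arise only if the
        ellipsoid touches the box).
        """
        m = self.interior_mask
        faces: list[tuple[tuple[int, int, int], int, int]] = []
        padded = np.pad(m, 1, constant_values=False)
        core = padded[1:-1, 1:-1, 1:-1]
        for axis in range(3):
            for direction in (-1, 1):
                neighbour = np.roll(padded, -direction, axis=axis)[1:-1, 1:-1, 1:-1]
                exposed = core & ~neighbour
                for idx in np.argwhere(exposed):
                    faces.append((tuple(int(i) for i in idx), axis, direction))
        return faces

    def nearest_voxel(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = []
        for c, L, n, h in zip(point, self.domain_lengths, self.counts, self.voxel_sizes):
            i = int(np.clip(np.floor((c + L / 2) / h), 0, n - 1))
            idx.append(i)
        return tuple(idx)


@dataclass(frozen=True)
class BudSet:
    """Bud-neck positions on the ellipsoid surface with free-text labels."""

    positions: np.ndarray  # (nbud, 3), µm
    labels: tuple[str, ...]
    placement_name: str = "custom"

    @property
    def nbud(self) -> int:
        return len(self.positions)

    def __post_init__(self):
        if self.nbud < 1:
            raise ValueError("BudSet requires at least one bud")
        if len(self.labels) != self.nbud:
            raise ValueError("labels length must equal number of buds")


@dataclass(frozen=True)
class ActinFieldSet:
    """Per-bud actin fields Phi_n and their normalisation constants gamma_n."""

    beta: float
    phi: np.ndarray = field(repr=False)  # (nbud, nx, ny, nz)
    gamma: np.ndarray  # (nbud,)
    buds: BudSet

    @property
    def nbud(self) -> int:
        return len(self.gamma)

    def sink_density(self) -> np.ndarray:
        """Total capture-weight field sum_n gamma_n * Phi_n (shape of the grid)."""
        return np.tensordot(self.gamma, self.phi, axes=(0, 0))


def build_grid(
    major_axis: float,
    minor_axis: float,
    domain_lengths: tuple[float, float, float] = (10.5, 6.6, 6.6),
    counts: tuple[int, int, int] = (64, 40, 40),
) -> EllipsoidGrid:
    """Build the masked ellipsoid lattice.

    Parameters
    ----------
    major_axis, minor_axis:
        Full axis lengths of the ellipsoid in µm.  The minor axis is applied
        to both transverse directions (rotational symmetry about x).
    domain_lengths:
        Rectangular domain size (Lx, Ly, Lz) in µm; the cell is centred.
    counts:
        Voxels per axis (Nx, Ny, Nz); voxel size is L/N per axis.
    """
    Lx, Ly, Lz = domain_lengths
    if major_axis <= 0 or minor_axis <= 0:
        raise ValueError("axis lengths must be positive")
    if any(L <= 0 for L in domain_lengths):
        raise ValueError("domain lengths must be positive")
    if any(int(n) <= 0 for n in counts):
        raise ValueError("voxel counts must be positive integers")
    if major_axis > Lx:
        raise ValueError(
            f"ellipsoid major axis {major_axis} µm exceeds domain length Lx={Lx} µm"
        )
    if minor_axis > min(Ly, Lz):
        raise ValueError(
            f"ellipsoid minor axis {minor_axis} µm exceeds transverse domain "
            f"size min(Ly, Lz)={min(Ly, Lz)} µm"
        )

    counts = tuple(int(n) for n in counts)
    voxel_sizes = tuple(L / n for L, n in zip(domain_lengths, counts))
    a = major_axis / 2.0
    b = minor_axis / 2.0

    coords = [
        -L / 2 + h * (np.arange(n) + 0.5)
        for L, n, h in zip(domain_lengths, counts, voxel_sizes)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    mask = (X / a) ** 2 + (Y / b) ** 2 + (Z / b) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("interior mask is empty; grid too coarse for the ellipsoid")

    voxel_volume = float(np.prod(voxel_sizes))
    return EllipsoidGrid(
        major_axis=major_axis,
        minor_axis=minor_axis,
        domain_lengths=tuple(float(L) for L in domain_lengths),
        counts=counts,
        voxel_sizes=tuple(float(h) for h in voxel_sizes),
        interior_mask=mask,
        cell_volume=float(mask.sum()) * voxel_volume,
    )


def _surface_point(grid: EllipsoidGrid, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Point on the ellipsoid surface from parametric angles in degrees.

    ``theta`` is the polar angle from the +x pole, ``phi`` the azimuth
    about the major axis.
    """
    a = grid.major_axis / 2.0
    b = grid.minor_axis / 2.0
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.array(
        [a * np.cos(th), b * np.sin(th) * np.cos(ph), b * np.sin(th) * np.sin(ph)]
    )


def _check_on_surface(grid: EllipsoidGrid, point: np.ndarray) -> None:
    a = grid.major_axis / 2.0
    b = grid.minor_axis / 2.0
    r = (point[0] / a) ** 2 + (point[1] / b) ** 2 + (point[2] / b) ** 2
    # Half-voxel tolerance expressed on the implicit-function residual.
    h = max(grid.voxel_sizes)
    tol = h / min(a, b)
    if abs(r - 1.0) > tol:
        raise ValueError(f"bud position {point} is not on the ellipsoid surface")


PLACEMENT_PRESETS = ("antipodal_2", "symmetric_3", "adjacent2_distant1")


def place_buds(
    grid: EllipsoidGrid,
    placement: str | list[tuple[float, float]],
    adjacent_angle: float = 60.0,
    labels: list[str] | None = None,
) -> BudSet:
    """Place bud necks on the ellipsoid surface.

    ``placement`` is either a preset name or an explicit list of
    ``(theta, phi)`` parametric angles in degrees.  The preset
    ``adjacent2_distant1`` puts two buds near the +x pole separated by
    ``adjacent_angle`` (default 60°) and one bud at the −x pole, the
    configuration used to probe placement asymmetry.
    """
    if isinstance(placement, str):
        name = placement
        if name == "antipodal_2":
            angle_list = [(0.0, 0.0), (180.0, 0.0)]
            lab = ["a", "b"]
        elif name == "symmetric_3":
            angle_list = [(90.0, 0.0), (90.0, 120.0), (90.0, 240.0)]
            lab = ["a", "b", "c"]
        elif name == "adjacent2_distant1":
            half = adjacent_angle / 2.0
            angle_list = [(half, 0.0), (half, 180.0), (180.0, 0.0)]
            lab = ["adjacent", "adjacent", "distant"]
        else:
            raise ValueError(
                f"unknown placement preset {name!r}; known: {PLACEMENT_PRESETS}"
            )
    else:
        if len(placement) == 0:
            raise ValueError("empty placement")
        name = "custom"
        angle_list = list(placement)
        lab = [f"bud{i}" for i in range(len(angle_list))]

    if labels is not None:
        if len(labels) != len(angle_list):
            raise ValueError("labels length must match number of buds")
        lab = list(labels)

    positions = np.array([_surface_point(grid, th, ph) for th, ph in angle_list])
    for p in positions:
        _check_on_surface(grid, p)
    return BudSet(positions=positions, labels=tuple(lab), placement_name=name)


def build_actin_fields(grid: EllipsoidGrid, buds: BudSet, beta: float) -> ActinFieldSet:
    """Construct exponential actin fields and their normalisation constants.

    Phi_n is evaluated at interior voxel centres as ``exp(-d/beta)`` with
    ``d`` the Euclidean distance to the bud neck; gamma_n is computed by
    voxel-sum quadrature of the normalisation integral, consistent with the
    finite-volume transport solver.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    for p in buds.positions:
        for c, L in zip(p, grid.domain_lengths):
            if abs(c) > L / 2:
                raise ValueError(f"bud position {p} lies outside the domain")

    X, Y, Z = grid.coordinate_grids()
    mask = grid.interior_mask
    phi = np.zeros((buds.nbud,) + mask.shape)
    gamma = np.zeros(buds.nbud)
    vv = grid.voxel_volume
    for n, p in enumerate(buds.positions):
        d = np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2)
        f = np.where(mask, np.exp(-d / beta), 0.0)
        phi[n] = f
        total = f.sum() * vv
        if total <= 0:
            raise ValueError(f"actin field of bud {n} integrates to zero")
        gamma[n] = 1.0 / total
    return ActinFieldSet(beta=float(beta), phi=phi, gamma=gamma, buds=buds)
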