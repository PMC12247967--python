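"""Parameter exploration of delivery asymmetry and the Smoluchowski on-rate.

The capture rate parameter ``kon`` can be estimated from cable geometry
using the diffusion-limited encounter rate between a spherical vesicle
(radius ``Rv``) and slender cylindrical actin cables (radius ``Rc``,
length ``Lc``, number density ``cact``):

    kon = [2 pi Lc / ln(Lc / (Rv + Rc))] * cact * Dv = kon_star * Dv

valid in the slender-cylinder limit Lc >> Rv + Rc.  ``sweep_delivery_cv``
maps the delivery-rate CV of an asymmetric bud arrangement over grids of
(kon, Dv, beta) using the direct steady-state solver, one row per
combination.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EllipsoidGrid, build_actin_fields, place_buds
from .transport import TransportParams, solve_steady_direct

__all__ = ["CableGeometry", "smoluchowski_kon", "sweep_delivery_cv"]

#: Parameter ranges explored in the study (s⁻¹, µm² s⁻¹, µm).
KON_RANGE = (1e-3, 1e-1)
DV_RANGE = (0.01, 0.5)
BETA_RANGE = (0.1, 10.0)


@dataclass(frozen=True)
class CableGeometry:
    """Actin cable geometry for the encounter-rate estimate (lengths in µm)."""

    Lc: float = 3.0
    Rv: float = 0.05
    Rc: float = 0.05
    n_cables: int = 4
    cell_volume: float = 4.0 / 3.0 * math.pi * 5.0 * 3.0 * 3.0

    def __post_init__(self):
        if min(self.Lc, self.Rv, self.Rc, self.cell_volume) <= 0 or self.n_cables < 1:
            raise ValueError("all cable-geometry quantities must be positive")
        ratio = self.Lc / (self.Rv + self.Rc)
        if ratio < 5:
            raise ValueError(
                f"slender-cylinder limit violated: Lc/(Rv+Rc) = {ratio:.2f} < 5"
            )
        if ratio < 20:
            warnings.warn(
                f"Lc/(Rv+Rc) = {ratio:.1f} is marginal for the slender-cylinder "
                "approximation (recommend >= 20)",
                stacklevel=2,
            )

    @property
    def cact(self) -> float:
        """Cables per µm³ of mother cytoplasm."""
        return self.n_cables / self.cell_volume

    @property
    def kon_star(self) -> float:
        """Encounter-rate prefactor (µm⁻²); kon = kon_star * Dv."""
        log_arg = self.Lc / (self.Rv + self.Rc)
        if log_arg <= 1:
            raise ValueError("ln argument Lc/(Rv+Rc) must exceed 1")
        return 2.0 * math.pi * self.Lc / math.log(log_arg) * self.cact


def smoluchowski_kon(geom: CableGeometry, Dv: float) -> float:
    """Diffusion-limited vesicle–cable encounter rate (s⁻¹).

    Linear in both the cable density and the vesicle diffusion coefficient.
    With the study's worked geometry (four 3 µm cables of 50 nm radius,
    50 nm vesicles, Dv = 0.02 µm²/s in a 10×6×6 µm ellipsoid) the estimate
    is of order 1e-3 s⁻¹.
    """
    if Dv <= 0:
        raise ValueError("Dv must be positive")
    return geom.kon_star * Dv


def sweep_delivery_cv(
    grid: EllipsoidGrid,
    placement: str,
    kon_values,
    Dv_values,
    beta_values,
    kgen: float = 0.01,
    adjacent_angle: float = 60.0,
    enforce_ranges: bool = True,
) -> pd.DataFrame:
    """Steady-state delivery CV over a (kon, Dv, beta) parameter grid.

    One direct sparse solve per combination; a failing combination is
    recorded in its row (``error`` column) and the sweep continues.
    Returns a tidy DataFrame with per-bud rates, the delivery CV, and
    solver/geometry provenance.
    """
    kon_values = np.atleast_1d(np.asarray(kon_values, dtype=float))
    Dv_values = np.atleast_1d(np.asarray(Dv_values, dtype=float))
    beta_values = np.atleast_1d(np.asarray(beta_values, dtype=float))
    if enforce_ranges:
        for vals, (lo, hi), name in (
            (kon_values, KON_RANGE, "kon"),
            (Dv_values, DV_RANGE, "Dv"),
            (beta_values, BETA_RANGE, "beta"),
        ):
            if vals.min() < lo * (1 - 1e-9) or vals.max() > hi * (1 + 1e-9):
                raise ValueError(
                    f"{name} values outside the study range [{lo}, {hi}]; "
                    "pass enforce_ranges=False to override"
                )

    buds = place_buds(grid, placement, adjacent_angle=adjacent_angle)
    rows = []
    for beta in beta_values:
        fields = build_actin_fields(grid, buds, beta)
        for kon, Dv in itertools.product(kon_values, Dv_values):
            row: dict = {
                "kon": kon,
                "Dv": Dv,
                "beta": beta,
                "placement_name": buds.placement_name,
                "nbud": buds.nbud,
                "grid_counts": "x".join(str(c) for c in grid.counts),
                "kgen": kgen,
                "error": "",
            }
            try:
                params = TransportParams(kgen=kgen, kon=kon, Dv=Dv)
                _, res = solve_steady_direct(grid, fields, params)
                row["delivery_cv"] = res.delivery_cv
                for i, (lab, r) in enumerate(zip(buds.labels, res.instantaneous_rates)):
                    row[f"rate_{i}_{lab}"] = r
            except Exception as exc:
                row["delivery_cv"] = np.nan
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def plot_cv_heatmap(table: pd.DataFrame, x: str, y: str, out_path, fixed: dict | None = None):
    """Save a CV heatmap over two swept parameters, the third held fixed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table
    for key, val in (fixed or {}).items():
        sub = sub[np.isclose(sub[key], val)]
    pivot = sub.pivot_table(index=y, columns=x, values="delivery_cv")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values, shading="auto")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.colorbar(im, ax=ax, label="delivery CV")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
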