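"""Two-channel cytosol subtraction and sibling cable-signal CV.

A tropomyosin cable marker carries a cytosolic background in addition to
the cable-bound pool.  The correction uses a co-expressed cytosolic
marker in a second channel: within the cell mask, the dimmer channel is
scaled so both channels have the same in-cell mean, and the cytosol
channel is then subtracted voxelwise from the cable channel (negative
residuals clamped to zero).  Mean corrected intensity per segmented bud
gives a per-bud cable-signal time series; asymmetry between siblings is
summarised as a CV either per frame (instantaneous) or after averaging
each bud's signal over a multi-frame window, which suppresses transient
cable fluctuations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoChannelStack",
    "SegmentationMasks",
    "subtract_cytosol",
    "per_bud_cable_signal",
    "windowed_sibling_cv",
]


@dataclass(frozen=True)
class TwoChannelStack:
    """Time series of co-registered cable/cytosol 3D channels.

    Arrays have shape (frames, z, y, x); intensities are non-negative.
    """

    cable: np.ndarray = field(repr=False)
    cytosol: np.ndarray = field(repr=False)
    voxel_sizes: tuple[float, float, float] = (0.7, 0.2, 0.2)  # (z, y, x) µm
    frame_interval: float = 1.0  # minutes

    def __post_init__(self):
        if self.cable.shape != self.cytosol.shape:
            raise ValueError("channels must be co-registered (identical shape)")
        if self.cable.ndim != 4:
            raise ValueError("expected (frames, z, y, x) arrays")
        if self.cable.min() < 0 or self.cytosol.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.cable.shape[0]


@dataclass(frozen=True)
class SegmentationMasks:
    """Whole-cell mask plus disjoint per-bud masks (shared across frames)."""

    cell_mask: np.ndarray = field(repr=False)
    bud_masks: tuple = ()

    def __post_init__(self):
        if not self.cell_mask.any():
            raise ValueError("cell mask is empty")
        union = np.zeros_like(self.cell_mask)
        for i, bm in enumerate(self.bud_masks):
            if bm.shape != self.cell_mask.shape:
                raise ValueError(f"bud mask {i} shape mismatch")
            if (bm & ~self.cell_mask).any():
                raise ValueError(f"bud mask {i} extends outside the cell mask")
            if (bm & union).any():
                raise ValueError(f"bud mask {i} overlaps another bud mask")
            union |= bm

    @property
    def nbud(self) -> int:
        return len(self.bud_masks)


def subtract_cytosol(stack: TwoChannelStack, masks: SegmentationMasks) -> np.ndarray:
    """Scaled-channel cytosol subtraction, per frame.

    Signal outside the cell mask is zeroed, the dimmer channel (by in-mask
    mean; typically the cable channel) is scaled so both channels match in
    mean, and the cytosol channel is subtracted voxelwise from the cable
    channel.  Negative residuals are clamped to zero.  Returns the
    corrected cable-signal stack.
    """
    cell = masks.cell_mask
    corrected = np.zeros_like(stack.cable, dtype=float)
    for f in range(stack.n_frames):
        cab = np.where(cell, stack.cable[f].astype(float), 0.0)
        cyt = np.where(cell, stack.cytosol[f].astype(float), 0.0)
        mean_cab = cab[cell].mean()
        mean_cyt = cyt[cell].mean()
        if mean_cab <= 0 or mean_cyt <= 0:
            raise ValueError(f"frame {f}: zero-mean channel within the cell mask")
        if mean_cab <= mean_cyt:
            cab = cab * (mean_cyt / mean_cab)
        else:
            cyt = cyt * (mean_cab / mean_cyt)
        corrected[f] = np.clip(cab - cyt, 0.0, None)
    return corrected


def per_bud_cable_signal(corrected: np.ndarray, masks: SegmentationMasks) -> np.ndarray:
    """Mean corrected intensity per bud mask, per frame.

    Returns an array of shape (frames, nbud); an empty bud mask yields NaN
    for that bud with a warning.
    """
    if masks.nbud == 0:
        raise ValueError("no bud masks provided")
    n_frames = corrected.shape[0]
    out = np.full((n_frames, masks.nbud), np.nan)
    for i, bm in enumerate(masks.bud_masks):
        if not bm.any():
            warnings.warn(f"bud {i}: empty mask, reporting NaN", stacklevel=2)
            continue
        out[:, i] = corrected[:, bm].mean(axis=1)
    return out


def windowed_sibling_cv(signals: np.ndarray, window: int = 10) -> dict:
    """Instantaneous and window-averaged sibling-signal CVs.

    ``signals`` has shape (frames, nbud).  The instantaneous CV is the
    sample sd/mean across siblings at each frame.  The windowed CV is the
    CV across siblings of each bud's mean signal over consecutive
    non-overlapping windows of ``window`` frames (partial trailing windows
    are dropped); with window=1 it reduces to the instantaneous CV.
    """
    signals = np.asarray(signals, dtype=float)
    n_frames, nbud = signals.shape
    if nbud < 2:
        raise ValueError("need at least two sibling buds")
    if window < 1 or window > n_frames:
        raise ValueError(f"window {window} incompatible with {n_frames} frames")

    means = signals.mean(axis=1)
    sds = signals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        instantaneous = np.where(means > 0, sds / means, 0.0)

    n_windows = n_frames // window
    trimmed = signals[: n_windows * window].reshape(n_windows, window, nbud)
    window_means = trimmed.mean(axis=1)  # (n_windows, nbud)
    wm = window_means.mean(axis=1)
    ws = window_means.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        windowed = np.where(wm > 0, ws / wm, 0.0)

    return {
        "instantaneous_cv": instantaneous,
        "windowed_cv": windowed,
        "mean_instantaneous_cv": float(instantaneous.mean()),
        "mean_windowed_cv": float(windowed.mean()),
        "window": int(window),
    }
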