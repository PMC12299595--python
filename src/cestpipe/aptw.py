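"""B0-corrected MTR-asymmetry quantification of APTw z-spectra.

Per voxel the chain is: normalize the saturated series by S0, interpolate
the z-spectrum to a fine frequency grid (default 0.01 ppm), translate the
frequency axis by the voxel's WASSR-estimated water shift so water sits at
0 ppm, resample back onto the original acquisition offsets, and take

    APTw = MTRasym(3.5 ppm) = MTR(+3.5) - MTR(-3.5)
         = 100 * [z(-3.5) - z(+3.5)]   (percent),

with MTR = 1 - S_sat/S0.  Resampled points that would fall outside the
acquired frequency range are never extrapolated: the corresponding samples
are marked unavailable, and a voxel becomes invalid only if a sample its
statistic actually needs (+/- the analysis offset) is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .errors import ConfigError, DataError
from .io import OffsetGrid, PipelineConfig, ZSpectrumStack
from .wassr import B0Map, fine_grid

__all__ = [
    "APTwMap",
    "MTRasymCurve",
    "normalize",
    "correct_voxel",
    "mtr_asym",
    "aptw_map",
    "mean_mtr_asym_curve",
    "render_overlay",
]


@dataclass
class APTwMap:
    """Per-voxel MTRasym at the analysis offset, in percent."""

    aptw_percent: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.aptw_percent.shape

    def values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid APTw values, optionally restricted to a mask."""
        sel = self.valid if mask is None else (self.valid & mask)
        return self.aptw_percent[sel]


@dataclass
class MTRasymCurve:
    """ROI-mean MTR asymmetry at each positive offset of the grid."""

    offsets_ppm: np.ndarray
    mean_percent: np.ndarray
    sem_percent: np.ndarray
    n_voxels: np.ndarray


def normalize(stack: ZSpectrumStack) -> tuple[np.ndarray, np.ndarray]:
    """S0-normalize the stack: z = s_sat / s0 per voxel and offset.

    Returns (z, usable) where usable flags voxels with S0 > 0; at other
    voxels z is NaN rather than an exception — they are simply excluded
    downstream.
    """
    usable = stack.s0 > 0
    z = np.full_like(stack.s_sat, np.nan)
    z[usable] = stack.s_sat[usable] / stack.s0[usable][:, None]
    return z, usable


def _interpolator(x: np.ndarray, y: np.ndarray, kind: str):
    if kind == "cubic":
        return CubicSpline(x, y, axis=0, bc_type="natural")
    return interp1d(x, y, axis=0, assume_sorted=True)


def correct_voxel(
    grid: OffsetGrid,
    z: np.ndarray,
    shift_ppm: float,
    resolution_ppm: float = 0.01,
    method: str = "nearest-fine",
    interpolation: str = "cubic",
) -> tuple[np.ndarray, np.ndarray]:
    """B0-correct one voxel's z-spectrum back onto its original grid.

    The spectrum is interpolated at ``resolution_ppm``, the axis shifted by
    ``-shift_ppm`` (so the corrected value at offset x is the measured value
    at x + shift), and re-sampled at the original offsets.  ``method``
    "nearest-fine" looks up the nearest fine-grid node (error <= half a
    fine step); "spline" re-evaluates the interpolant exactly.

    Returns (corrected, available): samples needing data beyond the
    acquired range are NaN with available=False.
    """
    if not np.isfinite(shift_ppm):
        raise DataError("non-finite shift")
    z = np.asarray(z, dtype=float).ravel()
    if z.size != len(grid):
        raise DataError(f"z has {z.size} samples but grid has {len(grid)}")
    x = grid.offsets_ppm
    lo, hi = grid.span
    targets = x + shift_ppm
    available = (targets >= lo - 1e-12) & (targets <= hi + 1e-12)
    corrected = np.full(x.size, np.nan)
    interp = _interpolator(x, z, interpolation)
    if method == "spline":
        corrected[available] = interp(targets[available])
    elif method == "nearest-fine":
        fine = fine_grid(grid, resolution_ppm)
        curve = interp(fine)
        idx = np.rint((targets[available] - lo) / resolution_ppm).astype(int)
        idx = np.clip(idx, 0, fine.size - 1)
        corrected[available] = curve[idx]
    else:
        raise ConfigError(f"unknown resample method '{method}'")
    return corrected, available


def mtr_asym(z: np.ndarray, grid: OffsetGrid, at_ppm: float = 3.5) -> float:
    """MTR asymmetry (percent) of a corrected spectrum at ``at_ppm``.

    100 * [(1 - z(+at)) - (1 - z(-at))] = 100 * [z(-at) - z(+at)].
    NaN if either required sample is unavailable.
    """
    try:
        i_neg = grid.index_of(-at_ppm)
        i_pos = grid.index_of(at_ppm)
    except Exception as exc:
        raise ConfigError(
            f"analysis offsets +/-{at_ppm} ppm not on the acquisition grid"
        ) from exc
    z = np.asarray(z, dtype=float)
    return float(100.0 * (z[..., i_neg] - z[..., i_pos]))


def _corrected_z_field(
    stack: ZSpectrumStack,
    b0map: B0Map,
    mask: np.ndarray,
    config: PipelineConfig,
    apply_correction: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected z for all processable voxels, batched.

    Returns (zc, base_valid) where zc has shape (rows, cols, n_offsets)
    with NaN at unavailable samples and base_valid flags voxels that were
    processed (in mask, valid B0, S0 > 0, finite data).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape or b0map.shape != stack.shape:
        raise DataError("mask/B0 map shapes do not match the stack")
    z, usable = normalize(stack)
    base = mask & usable & b0map.valid
    base &= np.all(np.isfinite(z), axis=-1)
    zc = np.full_like(z, np.nan)
    if not base.any():
        return zc, base

    x = stack.grid.offsets_ppm
    lo, hi = stack.grid.span
    res = config.resolution_ppm
    zmat = z[base].T  # (n_off, n_vox)
    shifts = b0map.shift_ppm[base] if apply_correction else np.zeros(base.sum())
    interp = _interpolator(x, zmat, config.interpolation)

    if config.resample_method == "nearest-fine":
        fine = fine_grid(stack.grid, res)
        curves = interp(fine)  # (n_fine, n_vox)
        orig_idx = np.rint((x - lo) / res).astype(int)
        steps = np.rint(shifts / res).astype(int)
        idx = orig_idx[:, None] + steps[None, :]  # (n_off, n_vox)
        out = (idx < 0) | (idx >= fine.size)
        idx = np.clip(idx, 0, fine.size - 1)
        vals = np.take_along_axis(curves, idx, axis=0)
        vals[out] = np.nan
    else:  # exact spline re-evaluation, voxel by voxel
        vals = np.full((x.size, zmat.shape[1]), np.nan)
        for j in range(zmat.shape[1]):
            vj = _interpolator(x, zmat[:, j], config.interpolation)
            targets = x + shifts[j]
            ok = (targets >= lo - 1e-12) & (targets <= hi + 1e-12)
            vals[ok, j] = vj(targets[ok])
    zc[base] = vals.T
    return zc, base


def aptw_map(
    aptw_stack: ZSpectrumStack,
    b0map: B0Map,
    mask: np.ndarray,
    config: PipelineConfig | None = None,
    apply_correction: bool = True,
) -> APTwMap:
    """Normalize -> B0-correct -> MTRasym for every in-mask voxel.

    ``apply_correction=False`` skips the B0 translation (ablation mode:
    quantifies the bias the correction removes).
    """
    config = config or PipelineConfig()
    at = config.analysis_offset_ppm
    if not (aptw_stack.grid.contains(at) and aptw_stack.grid.contains(-at)):
        raise ConfigError(
            f"analysis offsets +/-{at} ppm not on the acquisition grid"
        )
    zc, base = _corrected_z_field(
        aptw_stack, b0map, mask, config, apply_correction
    )
    i_neg = aptw_stack.grid.index_of(-at)
    i_pos = aptw_stack.grid.index_of(at)
    values = 100.0 * (zc[:, :, i_neg] - zc[:, :, i_pos])
    valid = base & np.isfinite(values)
    values[~valid] = np.nan
    return APTwMap(values, valid)


def mean_mtr_asym_curve(
    aptw_stack: ZSpectrumStack,
    b0map: B0Map,
    roi_mask: np.ndarray,
    config: PipelineConfig | None = None,
) -> MTRasymCurve:
    """ROI-averaged MTR-asymmetry spectrum.

    Evaluated at every positive grid offset whose negative counterpart is
    also on the grid; each voxel contributes at an offset only where both
    corrected samples are available.
    """
    config = config or PipelineConfig()
    zc, base = _corrected_z_field(aptw_stack, b0map, roi_mask, config)
    if not base.any():
        raise DataError("no valid voxels in ROI")
    grid = aptw_stack.grid
    pos = [x for x in grid.offsets_ppm if x > 0 and grid.contains(-x)]
    offsets, means, sems, counts = [], [], [], []
    for x in pos:
        vox = 100.0 * (
            zc[base][:, grid.index_of(-x)] - zc[base][:, grid.index_of(x)]
        )
        vox = vox[np.isfinite(vox)]
        if vox.size == 0:
            continue
        offsets.append(x)
        means.append(vox.mean())
        sems.append(vox.std(ddof=1) / np.sqrt(vox.size) if vox.size > 1 else 0.0)
        counts.append(vox.size)
    return MTRasymCurve(
        np.asarray(offsets), np.asarray(means), np.asarray(sems),
        np.asarray(counts),
    )


def render_overlay(
    aptw: APTwMap,
    s0: np.ndarray,
    path,
    window: tuple[float, float] = (-5.0, 5.0),
    overlay_mask: np.ndarray | None = None,
    title: str | None = None,
) -> None:
    """Render the APTw map over the S0 anatomy and save a PNG.

    Diverging colormap windowed to ``window`` (percent); invalid voxels and
    voxels outside ``overlay_mask`` show the grayscale anatomy only.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    show = aptw.valid if overlay_mask is None else (aptw.valid & overlay_mask)
    overlay = np.ma.masked_where(~show, aptw.aptw_percent)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.asarray(s0, float), cmap="gray", interpolation="nearest")
    im = ax.imshow(
        overlay, cmap="RdBu_r", vmin=window[0], vmax=window[1],
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="APTw = MTRasym(3.5 ppm) [%]")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
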