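"""Per-voxel water frequency (B0) estimation from WASSR z-spectra.

Each voxel's low-power z-spectrum samples only the direct water saturation
line; its minimum marks the voxel's apparent water frequency.  The spectrum
is fitted with a high-order polynomial (default order 12) on offsets
rescaled to [-1, 1] for conditioning, the fit is evaluated on a fine grid at
the configured resolution (default 0.01 ppm) spanning the acquired range,
and the fine-grid location of the minimum is the shift estimate.  Ties are
broken toward the smallest |offset|; minima on the boundary of the acquired
range, degenerate (flat) spectra, and shifts beyond the validity bound are
flagged invalid rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, FitError
from .io import OffsetGrid, PipelineConfig, ZSpectrumStack

__all__ = ["B0Map", "WassrFit", "fit_wassr_voxel", "b0_map", "fine_grid"]


@dataclass
class B0Map:
    """Per-voxel water frequency shift (ppm) with validity flags.

    ``fit_residual`` is the RMS of the polynomial fit residual in
    normalized-signal units; a diagnostic, not a gate.
    """

    shift_ppm: np.ndarray
    valid: np.ndarray
    fit_residual: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.shift_ppm.shape

    @property
    def fraction_valid(self) -> float:
        return float(np.mean(self.valid))


@dataclass
class WassrFit:
    """Single-voxel fit result (shift plus the interpolated curve)."""

    shift_ppm: float
    residual: float
    fine_offsets_ppm: np.ndarray
    fine_curve: np.ndarray
    valid: bool


def fine_grid(grid: OffsetGrid, resolution_ppm: float) -> np.ndarray:
    """Fine evaluation grid at the stated resolution spanning the range."""
    lo, hi = grid.span
    n = int(round((hi - lo) / resolution_ppm)) + 1
    return np.linspace(lo, hi, n)


def _design_matrices(
    grid: OffsetGrid, order: int, resolution_ppm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vandermonde matrices on the acquired and fine grids, plus |offset| order.

    Offsets are rescaled to [-1, 1] before building the basis: raw-ppm
    power bases at order 12 are numerically ill-conditioned.
    The fine grid is returned permuted so ascending |offset| comes first;
    a first-minimum search on the permuted curve then breaks exact ties
    toward the smallest |offset| for free.
    """
    lo, hi = grid.span
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    x = (grid.offsets_ppm - mid) / half
    fine = fine_grid(grid, resolution_ppm)
    xf = (fine - mid) / half
    V = np.vander(x, order + 1, increasing=True)
    perm = np.argsort(np.abs(fine), kind="stable")
    Vf = np.vander(xf[perm], order + 1, increasing=True)
    return V, Vf, fine[perm], fine


def fit_wassr_voxel(
    grid: OffsetGrid,
    z: np.ndarray,
    order: int = 12,
    resolution_ppm: float = 0.01,
) -> WassrFit:
    """Fit one voxel's WASSR spectrum and locate its minimum.

    ``z`` is the S0-normalized spectrum sampled on ``grid`` (the minimum
    location is invariant to positive rescaling, so raw signal works too).
    Requires at least ``order + 1`` samples.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size != len(grid):
        raise DataError(f"z has {z.size} samples but grid has {len(grid)}")
    if not np.all(np.isfinite(z)):
        raise DataError("non-finite values in WASSR spectrum")
    if z.size < order + 1:
        raise FitError(
            f"need at least order+1 = {order + 1} samples, got {z.size}"
        )
    V, Vf, fine_perm, fine = _design_matrices(grid, order, resolution_ppm)
    coef, *_ = np.linalg.lstsq(V, z, rcond=None)
    curve_perm = Vf @ coef
    residual = float(np.sqrt(np.mean((V @ coef - z) ** 2)))

    idx = int(np.argmin(curve_perm))
    shift = float(fine_perm[idx])
    lo, hi = grid.span
    on_boundary = shift in (lo, hi) or np.isclose(shift, lo) or np.isclose(shift, hi)
    degenerate = float(np.ptp(curve_perm)) < 1e-12
    valid = not (on_boundary or degenerate)

    # report the curve in ascending-offset order for plotting/inspection
    unperm = np.argsort(fine_perm, kind="stable")
    return WassrFit(
        shift_ppm=shift,
        residual=residual,
        fine_offsets_ppm=fine_perm[unperm],
        fine_curve=curve_perm[unperm],
        valid=valid,
    )


def b0_map(
    wassr_stack: ZSpectrumStack,
    analysis_mask: np.ndarray,
    config: PipelineConfig | None = None,
) -> B0Map:
    """Estimate the water shift at every in-mask voxel.

    All in-mask voxels are fitted in one batched least-squares solve (the
    design matrix depends only on the shared grid).  Voxels are invalid when
    out of mask, non-finite, S0 <= 0, degenerate, minimum on the range
    boundary, or |shift| beyond ``config.max_shift_ppm``.
    """
    config = config or PipelineConfig()
    mask = np.asarray(analysis_mask, dtype=bool)
    if mask.shape != wassr_stack.shape:
        raise DataError(
            f"mask shape {mask.shape} != image shape {wassr_stack.shape}"
        )
    if not mask.any():
        raise DataError("analysis mask is empty")
    lo, hi = wassr_stack.grid.span
    if lo > -config.max_shift_ppm or hi < config.max_shift_ppm:
        raise DataError(
            f"WASSR grid [{lo}, {hi}] ppm does not span the +/-"
            f"{config.max_shift_ppm} ppm validity bound"
        )

    shape = wassr_stack.shape
    shift = np.zeros(shape)
    residual = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    s0 = wassr_stack.s0[mask]
    usable = mask.copy()
    usable[mask] &= s0 > 0
    zmat = (
        wassr_stack.s_sat[usable] / wassr_stack.s0[usable][:, None]
    )  # (n_vox, n_off)
    finite = np.all(np.isfinite(zmat), axis=1)
    zmat = zmat[finite]
    vox_idx = np.flatnonzero(usable.ravel())[finite]
    if vox_idx.size == 0:
        return B0Map(shift, valid, residual)

    V, Vf, fine_perm, _ = _design_matrices(
        wassr_stack.grid, config.polynomial_order, config.resolution_ppm
    )
    coef, *_ = np.linalg.lstsq(V, zmat.T, rcond=None)  # (order+1, n_vox)
    curves = Vf @ coef  # (n_fine, n_vox), rows ordered by ascending |offset|
    idx = np.argmin(curves, axis=0)  # first minimum == smallest |offset| tie
    est = fine_perm[idx]
    res = np.sqrt(np.mean((V @ coef - zmat.T) ** 2, axis=0))
    degenerate = np.ptp(curves, axis=0) < 1e-12
    boundary = np.isclose(est, lo) | np.isclose(est, hi)
    ok = (~degenerate) & (~boundary) & (np.abs(est) <= config.max_shift_ppm)

    flat = shift.ravel()
    flat[vox_idx] = est
    shift = flat.reshape(shape)
    flat = residual.ravel()
    flat[vox_idx] = res
    residual = flat.reshape(shape)
    flat = valid.ravel()
    flat[vox_idx] = ok
    valid = flat.reshape(shape)
    return B0Map(shift, valid, residual)
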