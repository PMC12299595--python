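"""Synthetic z-spectrum phantoms with known ground truth.

The generator emulates a single-slice APTw CEST study: every voxel carries a
multi-pool Lorentzian z-spectrum, a spatially smooth B0 (water frequency)
offset field shifts the spectra, and additive Gaussian noise models the
high-SNR magnitude-MRI regime.  Two acquisitions are produced per subject:

* an APTw stack on a wide offset grid (default -6..+6 ppm, 0.5 ppm steps,
  25 offsets) with the full pool set — water direct saturation, a +3.5 ppm
  amide pool whose amplitude carries the group effect, and a broad
  aliphatic/NOE pool at -3.5 ppm that makes healthy-tissue MTR asymmetry
  negative;
* a WASSR stack on a narrow grid (default -0.8..+0.8 ppm, 0.05 ppm steps,
  33 offsets) containing only a narrow, shallow water line, emulating the
  low-saturation-power regime used for B0 referencing.

The steady-state Lorentzian superposition is used instead of Bloch-McConnell
integration: the processing chain consumes spectra, not magnetization
dynamics, and the Lorentzian form admits a closed-form MTR-asymmetry oracle
(:func:`true_mtr_asym`) against which the whole pipeline can be checked.
Saturation power enters implicitly through per-acquisition pool amplitudes
and linewidths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import DataError, GridError, ModelError
from .io import OffsetGrid, ROIMaskSet, ZSpectrumStack, write_stack, write_map

__all__ = [
    "PoolSpec",
    "TissueClass",
    "PhantomSpec",
    "GroundTruth",
    "SubjectData",
    "make_offset_grid",
    "aptw_grid",
    "wassr_grid",
    "zspectrum_model",
    "true_mtr_asym",
    "build_phantom",
    "simulate_cohort",
    "default_tissues",
    "save_cohort",
    "AMIDE_AMPLITUDE_CTRL",
    "AMIDE_AMPLITUDE_LPS",
]

# Amide-pool peak depths calibrated so that, with the default water and NOE
# pools below, noiseless hippocampal MTRasym(3.5 ppm) is about -2.0% for a
# control-like tissue and about -0.5% for an inflamed (LPS-like) tissue.
# These are simulator defaults, not measured truths.
AMIDE_AMPLITUDE_CTRL = 0.028
AMIDE_AMPLITUDE_LPS = 0.043


@dataclass(frozen=True)
class PoolSpec:
    """One saturable proton pool: a Lorentzian line in the z-spectrum.

    Parameters
    ----------
    center_ppm : resonance offset from water (ppm); amide sits at +3.5.
    amplitude : peak saturation depth in [0, 1).
    linewidth_ppm : full width at half maximum (ppm), > 0.
    """

    center_ppm: float
    amplitude: float
    linewidth_ppm: float

    def __post_init__(self) -> None:
        if not (0 <= self.amplitude < 1):
            raise ModelError(f"pool amplitude {self.amplitude} not in [0, 1)")
        if self.linewidth_ppm <= 0:
            raise ModelError(f"pool linewidth {self.linewidth_ppm} must be > 0")

    def lineshape(self, offsets_ppm: np.ndarray) -> np.ndarray:
        """Unit-amplitude Lorentzian evaluated at the given offsets."""
        hw2 = (self.linewidth_ppm / 2.0) ** 2
        return hw2 / ((np.asarray(offsets_ppm, float) - self.center_ppm) ** 2 + hw2)


@dataclass(frozen=True)
class TissueClass:
    """A named pool composition with an unsaturated signal level."""

    name: str
    pools: tuple[PoolSpec, ...]
    s0_mean: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", tuple(self.pools))
        if self.s0_mean <= 0:
            raise ModelError("s0_mean must be > 0")
        n_water = sum(1 for p in self.pools if p.center_ppm == 0.0)
        if n_water != 1:
            raise ModelError(
                f"tissue '{self.name}' must contain exactly one water pool "
                f"at 0 ppm (found {n_water})"
            )
        _check_amplitudes(self.pools)


def _check_amplitudes(pools: Iterable[PoolSpec]) -> None:
    total = sum(p.amplitude for p in pools)
    if total >= 1:
        raise ModelError(
            f"pool amplitudes sum to {total:.3f} >= 1; normalized signal "
            "would go non-positive"
        )


def make_offset_grid(start_ppm: float, stop_ppm: float, step_ppm: float) -> OffsetGrid:
    """Inclusive, ascending, evenly spaced offset grid.

    The span must be an integer multiple of the step (tolerance 1e-9).
    A zero span yields the single-offset grid {start}.
    """
    if step_ppm <= 0:
        raise GridError("step must be > 0")
    if stop_ppm < start_ppm:
        raise GridError("stop must be >= start")
    span = stop_ppm - start_ppm
    n_steps = round(span / step_ppm)
    if abs(span - n_steps * step_ppm) > 1e-9:
        raise GridError(
            f"span {span} ppm is not an integer multiple of step {step_ppm} ppm"
        )
    return OffsetGrid(np.linspace(start_ppm, stop_ppm, n_steps + 1))


def aptw_grid() -> OffsetGrid:
    """The standard APTw acquisition grid: -6..+6 ppm in 0.5 ppm steps."""
    return make_offset_grid(-6.0, 6.0, 0.5)


def wassr_grid() -> OffsetGrid:
    """The standard WASSR acquisition grid: -0.8..+0.8 ppm in 0.05 ppm steps."""
    return make_offset_grid(-0.8, 0.8, 0.05)


def zspectrum_model(
    offsets: OffsetGrid | np.ndarray,
    pools: Sequence[PoolSpec],
    b0_shift: float = 0.0,
) -> np.ndarray:
    """Normalized saturated signal Z at each offset.

    Z(dw) = 1 - sum_i A_i * (G_i^2/4) / ((dw - d_i - b0)^2 + G_i^2/4),
    where A_i, d_i, G_i are pool amplitude, center and FWHM.  Values lie in
    (0, 1] as long as amplitudes sum below 1.
    """
    _check_amplitudes(pools)
    x = np.asarray(
        offsets.offsets_ppm if isinstance(offsets, OffsetGrid) else offsets, float
    )
    z = np.ones_like(x)
    for pool in pools:
        z = z - pool.amplitude * pool.lineshape(x - b0_shift)
    return z


def true_mtr_asym(pools: Sequence[PoolSpec], at_ppm: float = 3.5) -> float:
    """Analytic MTR asymmetry (percent) of a noiseless, unshifted pool model.

    Returns 100 * (Z(-at) - Z(+at)); the oracle the processing pipeline is
    expected to reproduce voxelwise.
    """
    z = zspectrum_model(np.array([-at_ppm, at_ppm]), pools, b0_shift=0.0)
    return float(100.0 * (z[0] - z[1]))


def default_tissues(
    amide_amplitude: float = AMIDE_AMPLITUDE_CTRL,
) -> dict[str, TissueClass]:
    """Default tissue set: background, cortex, hippocampus.

    Water: depth 0.85, FWHM 1.6 ppm (direct saturation at APTw power).
    NOE/MT surrogate: depth 0.05, FWHM 3.0 ppm at -3.5 ppm.
    Amide: FWHM 1.0 ppm at +3.5 ppm; cortex keeps the control depth while
    the hippocampus depth carries the group effect.
    """
    water = PoolSpec(0.0, 0.85, 1.6)
    noe = PoolSpec(-3.5, 0.05, 3.0)
    return {
        "background": TissueClass(
            "background", (PoolSpec(0.0, 0.10, 1.6),), s0_mean=0.05
        ),
        "cortex": TissueClass(
            "cortex",
            (water, PoolSpec(3.5, AMIDE_AMPLITUDE_CTRL, 1.0), noe),
            s0_mean=1.0,
        ),
        "hippocampus": TissueClass(
            "hippocampus",
            (water, PoolSpec(3.5, amide_amplitude, 1.0), noe),
            s0_mean=1.0,
        ),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one subject's pair of stacks.

    ``amide_amplitude`` sets the hippocampal amide-pool depth (the group
    effect); ``between_subject_sd`` is the SD of the per-subject random
    deviation applied to it by :func:`simulate_cohort`.  ``noise_sd`` is the
    additive Gaussian noise SD relative to the tissue's S0 level;
    ``b0_amplitude_ppm`` bounds the smooth water-shift field (must stay
    within reach of the WASSR grid, |bound| <= 0.5 ppm).
    """

    grid_shape: tuple[int, int] = (32, 32)
    amide_amplitude: float = AMIDE_AMPLITUDE_CTRL
    between_subject_sd: float = 0.003
    noise_sd: float = 0.01
    b0_amplitude_ppm: float = 0.15
    b0_smoothness_vox: float = 8.0
    wassr_pool: PoolSpec = field(
        default_factory=lambda: PoolSpec(0.0, 0.5, 0.5)
    )

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 8 or cols < 8:
            raise ModelError("grid_shape must be at least 8 x 8")
        if abs(self.b0_amplitude_ppm) > 0.5:
            raise ModelError("b0 amplitude bound must be within +/-0.5 ppm")
        if self.noise_sd < 0 or self.between_subject_sd < 0:
            raise ModelError("noise/between-subject SDs must be >= 0")

    def tissues(self) -> dict[str, TissueClass]:
        return default_tissues(self.amide_amplitude)


@dataclass
class GroundTruth:
    """Noiseless per-voxel truths the pipeline is asked to recover."""

    true_b0_map: np.ndarray  # ppm
    true_aptw_map: np.ndarray  # percent
    roi_masks: ROIMaskSet
    tissue_labels: np.ndarray  # object array of tissue names


@dataclass
class SubjectData:
    subject_id: str
    group: str
    seed: int
    spec: PhantomSpec
    aptw_stack: ZSpectrumStack
    wassr_stack: ZSpectrumStack
    truth: GroundTruth


def _layout(shape: tuple[int, int]) -> tuple[np.ndarray, ROIMaskSet]:
    """Default slice geometry: a brain disk holding two hippocampus disks.

    Geometry scales with the grid so the same layout works at 16x16 test
    size and 96x96 acquisition size.
    """
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    scale = min(rows, cols)

    def disk(frac_r: float, frac_c: float, frac_radius: float) -> np.ndarray:
        r0, c0 = frac_r * (rows - 1), frac_c * (cols - 1)
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= (frac_radius * scale) ** 2

    brain = disk(0.5, 0.5, 0.44)
    left = disk(0.55, 0.30, 0.12) & brain
    right = disk(0.55, 0.70, 0.12) & brain
    labels = np.full(shape, "background", dtype=object)
    labels[brain] = "cortex"
    labels[left | right] = "hippocampus"
    masks = ROIMaskSet(
        {"left_hippocampus": left, "right_hippocampus": right, "brain": brain}
    )
    return labels, masks


def _b0_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth bounded water-shift field: filtered white noise, peak-scaled."""
    if spec.b0_amplitude_ppm == 0:
        return np.zeros(spec.grid_shape)
    raw = gaussian_filter(
        rng.standard_normal(spec.grid_shape), spec.b0_smoothness_vox, mode="reflect"
    )
    peak = np.max(np.abs(raw))
    if peak == 0:  # pathological but possible at extreme smoothing
        return np.zeros(spec.grid_shape)
    return raw * (spec.b0_amplitude_ppm / peak)


def _render_stack(
    grid: OffsetGrid,
    tissue_labels: np.ndarray,
    tissues: dict[str, TissueClass],
    pools_of,
    b0: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> ZSpectrumStack:
    shape = tissue_labels.shape
    offs = grid.offsets_ppm
    s_sat = np.empty(shape + (len(grid),))
    s0 = np.empty(shape)
    for name, tissue in tissues.items():
        mask = tissue_labels == name
        if not mask.any():
            continue
        shifts = b0[mask][:, None]  # (m, 1) vs offsets (n,)
        z = np.ones((mask.sum(), offs.size))
        for pool in pools_of(tissue):
            z -= pool.amplitude * pool.lineshape(offs[None, :] - shifts)
        s_sat[mask] = z * tissue.s0_mean
        s0[mask] = tissue.s0_mean
    if noise_sd > 0:
        s_sat = s_sat + rng.normal(0.0, noise_sd * s0[..., None], s_sat.shape)
        s0 = s0 + rng.normal(0.0, noise_sd * s0, shape)
    return ZSpectrumStack(s_sat, s0, grid, provenance=["synthetic phantom"])


def build_phantom(
    spec: PhantomSpec,
    aptw_acquisition: OffsetGrid | None = None,
    wassr_acquisition: OffsetGrid | None = None,
    seed: int = 0,
) -> tuple[ZSpectrumStack, ZSpectrumStack, GroundTruth]:
    """Generate the (APTw stack, WASSR stack, ground truth) triple.

    The B0 field is shared between the two stacks; noise is drawn
    independently per voxel and offset from a generator seeded with *seed*,
    so identical (spec, seed) pairs give bit-identical output.
    """
    agrid = aptw_acquisition or aptw_grid()
    wgrid = wassr_acquisition or wassr_grid()
    rng = np.random.default_rng(seed)
    tissue_labels, masks = _layout(spec.grid_shape)
    tissues = spec.tissues()
    b0 = _b0_field(spec, rng)

    aptw_stack = _render_stack(
        agrid, tissue_labels, tissues, lambda t: t.pools, b0, spec.noise_sd, rng
    )
    # WASSR: only the water line, rescaled to the low-power depth/width.
    wassr_pools = {
        name: (replace(spec.wassr_pool, center_ppm=0.0),) for name in tissues
    }
    wassr_stack = _render_stack(
        wgrid,
        tissue_labels,
        tissues,
        lambda t: wassr_pools[t.name],
        b0,
        spec.noise_sd,
        rng,
    )

    true_aptw = np.empty(spec.grid_shape)
    for name, tissue in tissues.items():
        true_aptw[tissue_labels == name] = true_mtr_asym(tissue.pools, 3.5)
    truth = GroundTruth(b0, true_aptw, masks, tissue_labels)
    return aptw_stack, wassr_stack, truth


def simulate_cohort(
    groups: dict[str, PhantomSpec],
    n_per_group: int = 7,
    base_seed: int = 0,
    aptw_acquisition: OffsetGrid | None = None,
    wassr_acquisition: OffsetGrid | None = None,
) -> list[SubjectData]:
    """Simulate ``n_per_group`` subjects for each group.

    Per-subject seeds are derived deterministically from ``base_seed``; each
    subject's hippocampal amide amplitude is drawn from a normal with the
    group mean and the spec's between-subject SD (clipped to stay a valid
    amplitude), giving group comparisons realistic dispersion.
    """
    if n_per_group < 1:
        raise DataError("n_per_group must be >= 1")
    master = np.random.default_rng(base_seed)
    subjects: list[SubjectData] = []
    for group, spec in groups.items():
        for i in range(n_per_group):
            seed = int(master.integers(0, 2**31 - 1))
            amide = spec.amide_amplitude
            if spec.between_subject_sd > 0:
                amide += float(master.normal(0.0, spec.between_subject_sd))
            amide = float(np.clip(amide, 0.0, 0.5))
            subj_spec = replace(spec, amide_amplitude=amide)
            stacks = build_phantom(
                subj_spec, aptw_acquisition, wassr_acquisition, seed=seed
            )
            subjects.append(
                SubjectData(
                    subject_id=f"{group}_{i + 1:02d}",
                    group=group,
                    seed=seed,
                    spec=subj_spec,
                    aptw_stack=stacks[0],
                    wassr_stack=stacks[1],
                    truth=stacks[2],
                )
            )
    return subjects


def save_cohort(subjects: Sequence[SubjectData], outdir: str | Path) -> pd.DataFrame:
    """Write each subject's stacks, truth and masks; return the manifest.

    The manifest CSV (subject_id, group, seed, file paths) lands in
    ``outdir/manifest.csv``; per-subject files go in per-subject folders.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in subjects:
        d = outdir / subj.subject_id
        d.mkdir(exist_ok=True)
        paths = {
            "aptw_image": d / "aptw_stack.nii",
            "aptw_offsets": d / "aptw_offsets.json",
            "aptw_s0": d / "aptw_s0.nii",
            "wassr_image": d / "wassr_stack.nii",
            "wassr_offsets": d / "wassr_offsets.json",
            "wassr_s0": d / "wassr_s0.nii",
            "true_b0": d / "true_b0.nii",
            "true_aptw": d / "true_aptw.nii",
            "roi_labels": d / "roi_labels.nii",
            "roi_label_map": d / "roi_label_map.json",
        }
        write_stack(
            subj.aptw_stack, paths["aptw_image"], paths["aptw_offsets"], paths["aptw_s0"]
        )
        write_stack(
            subj.wassr_stack,
            paths["wassr_image"],
            paths["wassr_offsets"],
            paths["wassr_s0"],
        )
        write_map(subj.truth.true_b0_map, paths["true_b0"])
        write_map(subj.truth.true_aptw_map, paths["true_aptw"])
        from .io import write_masks

        write_masks(subj.truth.roi_masks, paths["roi_labels"], paths["roi_label_map"])
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "seed": subj.seed,
                # paths relative to the manifest so a run directory can be
                # moved (and hashed) as a unit
                **{k: str(v.relative_to(outdir)) for k, v in paths.items()},
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
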