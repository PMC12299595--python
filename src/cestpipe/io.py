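"""Containers and file I/O for z-spectrum stacks, masks, maps and configs.

Conventions
-----------
* Images are single-slice, voxel-indexed, row-major, 0-based; no world
  coordinates (the acquisitions this pipeline targets are single 2D slices).
* A z-spectrum stack on disk is a NIfTI-1 volume of shape
  ``(rows, cols, n_offsets)`` plus a separate 2D S0 NIfTI and a JSON sidecar
  listing the saturation offsets in ppm in stack order.  NIfTI has no
  standard field for saturation offsets, hence the sidecar.
* ROI masks are either a single integer-label NIfTI with a JSON label map,
  or one binary NIfTI per label.
* Reading never silently reorders data: any normalization performed on load
  (e.g. sorting offsets ascending) is appended to the stack's provenance log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigError, DataError, FormatError, GridError

__all__ = [
    "OffsetGrid",
    "ZSpectrumStack",
    "ROIMaskSet",
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "read_map",
    "write_map",
    "read_masks",
    "write_masks",
    "load_config",
]


@dataclass(frozen=True)
class OffsetGrid:
    """Ordered list of saturation frequency offsets (ppm) shared by a stack."""

    offsets_ppm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets_ppm, dtype=float).ravel()
        object.__setattr__(self, "offsets_ppm", arr)
        if arr.size == 0:
            raise GridError("offset grid is empty")
        if not np.all(np.isfinite(arr)):
            raise GridError("offset grid contains non-finite values")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise GridError("offsets must be strictly ascending (no duplicates)")

    def __len__(self) -> int:
        return int(self.offsets_ppm.size)

    def __iter__(self):
        return iter(self.offsets_ppm)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.offsets_ppm[0]), float(self.offsets_ppm[-1])

    def index_of(self, ppm: float, tol: float = 1e-9) -> int:
        """Index of the offset equal to *ppm* within *tol*.

        Raises GridError if absent.
        """
        hits = np.flatnonzero(np.abs(self.offsets_ppm - ppm) <= tol)
        if hits.size == 0:
            raise GridError(f"offset {ppm} ppm not on grid {self.span}")
        return int(hits[0])

    def contains(self, ppm: float, tol: float = 1e-9) -> bool:
        return bool(np.any(np.abs(self.offsets_ppm - ppm) <= tol))


@dataclass
class ZSpectrumStack:
    """Per-voxel saturated signal series plus the unsaturated S0 image.

    ``s_sat`` has shape (rows, cols, n_offsets); ``s0`` has shape
    (rows, cols).  Signal units are arbitrary but shared between the two.
    """

    s_sat: np.ndarray
    s0: np.ndarray
    grid: OffsetGrid
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.s_sat = np.asarray(self.s_sat, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.s_sat.ndim != 3:
            raise FormatError(f"s_sat must be 3D, got shape {self.s_sat.shape}")
        if self.s0.shape != self.s_sat.shape[:2]:
            raise FormatError(
                f"s0 shape {self.s0.shape} != image shape {self.s_sat.shape[:2]}"
            )
        if self.s_sat.shape[2] != len(self.grid):
            raise FormatError(
                f"stack has {self.s_sat.shape[2]} volumes but offset list has "
                f"{len(self.grid)} entries"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.s_sat.shape[:2]

    def log(self, message: str) -> None:
        self.provenance.append(message)


@dataclass
class ROIMaskSet:
    """Named boolean masks over the image grid.

    Labels may overlap (a voxel can belong to several ROIs); each mask must
    be non-empty and share the image shape.
    """

    labels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.labels:
            raise DataError("mask set is empty")
        shapes = set()
        for name, mask in self.labels.items():
            mask = np.asarray(mask, dtype=bool)
            self.labels[name] = mask
            if not mask.any():
                raise DataError(f"mask '{name}' is empty")
            shapes.add(mask.shape)
        if len(shapes) != 1:
            raise FormatError(f"masks have inconsistent shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.labels.values())).shape

    def union(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for mask in self.labels.values():
            out |= mask
        return out

    def __getitem__(self, name: str) -> np.ndarray:
        return self.labels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.labels


@dataclass(frozen=True)
class PipelineConfig:
    """Processing parameters shared across pipeline stages.

    Defaults follow standard APTw/WASSR practice: a 12th-order polynomial
    fitted to each WASSR z-spectrum, interpolation at 0.01 ppm resolution,
    MTR asymmetry evaluated at +/-3.5 ppm, voxels with |water shift| beyond
    0.5 ppm discarded, and alpha = 0.05 for all significance tests.
    """

    polynomial_order: int = 12
    resolution_ppm: float = 0.01
    analysis_offset_ppm: float = 3.5
    max_shift_ppm: float = 0.5
    alpha: float = 0.05
    resample_method: str = "nearest-fine"  # or "spline"
    interpolation: str = "cubic"  # or "linear"
    welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polynomial_order < 1:
            raise ConfigError("polynomial_order must be >= 1")
        if self.resolution_ppm <= 0:
            raise ConfigError("resolution_ppm must be > 0")
        if self.max_shift_ppm <= 0:
            raise ConfigError("max_shift_ppm must be > 0")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.resample_method not in ("nearest-fine", "spline"):
            raise ConfigError(f"unknown resample_method '{self.resample_method}'")
        if self.interpolation not in ("cubic", "linear"):
            raise ConfigError(f"unknown interpolation '{self.interpolation}'")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON; unknown keys are rejected.

    Keys omitted from the file take their documented defaults.  Keyword
    overrides are applied after the file.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        try:
            text = path.read_text()
            data = yaml.safe_load(text) or {}
        except (yaml.YAMLError, json.JSONDecodeError) as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
    data.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O


def _nifti(arr: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine=np.eye(4))


def _load(path: str | Path) -> np.ndarray:
    try:
        return np.asarray(nib.load(str(path)).get_fdata())
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises various ImageFileErrors
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc


def write_stack(stack: ZSpectrumStack, image_path, offsets_path, s0_path) -> None:
    """Write a stack as NIfTI volumes plus a JSON offsets sidecar."""
    nib.save(_nifti(stack.s_sat), str(image_path))
    nib.save(_nifti(stack.s0), str(s0_path))
    Path(offsets_path).write_text(
        json.dumps({"offsets_ppm": stack.grid.offsets_ppm.tolist()}, indent=1)
    )


def read_stack(image_path, offsets_path, s0_path) -> ZSpectrumStack:
    """Read a stack, validating counts and normalizing offset order.

    If the sidecar lists offsets in non-ascending order the volumes are
    reordered to ascending and the reordering is recorded in provenance.
    """
    data = _load(image_path)
    s0 = _load(s0_path)
    try:
        sidecar = json.loads(Path(offsets_path).read_text())
        offsets = np.asarray(sidecar["offsets_ppm"], dtype=float)
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"bad offsets sidecar {offsets_path}: {exc}") from exc
    if data.ndim == 4 and data.shape[2] == 1:  # tolerate (r, c, 1, n) NIfTI
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise FormatError(f"stack image must be 3D, got shape {data.shape}")
    if data.shape[2] != offsets.size:
        raise FormatError(
            f"stack has {data.shape[2]} volumes but sidecar lists "
            f"{offsets.size} offsets"
        )
    provenance = [f"read_stack({image_path})"]
    order = np.argsort(offsets)
    if not np.array_equal(order, np.arange(offsets.size)):
        data = data[:, :, order]
        offsets = offsets[order]
        provenance.append("offsets reordered to ascending to match grid convention")
    return ZSpectrumStack(data, s0, OffsetGrid(offsets), provenance)


def write_map(field_2d: np.ndarray, path) -> None:
    """Write a 2D scalar field (e.g. APTw %, B0 ppm) as NIfTI."""
    arr = np.asarray(field_2d, dtype=float)
    if arr.ndim != 2:
        raise FormatError(f"map must be 2D, got shape {arr.shape}")
    nib.save(_nifti(arr), str(path))


def read_map(path) -> np.ndarray:
    arr = _load(path)
    if arr.ndim != 2:
        arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise FormatError(f"map at {path} is not 2D")
    return arr


def write_masks(masks: ROIMaskSet, label_image_path, label_map_path) -> None:
    """Write masks as one integer-label NIfTI plus a JSON label map.

    Overlapping masks cannot be represented in a single label image; in
    that case use one binary file per label via write_map.
    """
    labels = sorted(masks.labels)
    img = np.zeros(masks.shape, dtype=float)
    for i, name in enumerate(labels, start=1):
        img[masks[name]] = i
    nib.save(_nifti(img), str(label_image_path))
    Path(label_map_path).write_text(
        json.dumps({name: i for i, name in enumerate(labels, start=1)}, indent=1)
    )


def read_masks(paths: Mapping[str, str | Path] | tuple) -> ROIMaskSet:
    """Read an ROIMaskSet.

    Accepts either a mapping label -> binary NIfTI path, or a
    (label_image_path, label_map_path) pair for an integer-label image.
    """
    if isinstance(paths, Mapping):
        labels = {name: _load(p) > 0.5 for name, p in paths.items()}
    else:
        label_image_path, label_map_path = paths
        img = _load(label_image_path)
        label_map = json.loads(Path(label_map_path).read_text())
        labels = {
            name: np.isclose(img, value) for name, value in label_map.items()
        }
    return ROIMaskSet(labels)
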