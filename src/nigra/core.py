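"""Core containers shared across the pipeline.

All volumes are numpy arrays indexed (x, y, z) with the slice axis configurable
on the :class:`VoxelGrid` (default: axis 2, increasing index = caudal).
Susceptibility is carried in parts per billion (ppb), fields in Hz, phase in
radians wrapped to (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

GAMMA_BAR_HZ_PER_T = 42.577e6  # reduced gyromagnetic ratio of 1H, Hz/T

REGION_LABELS = ("SN_L", "SN_R", "RN_L", "RN_R", "N1_L", "N1_R")


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase into (-pi, pi] via the complex argument."""
    return np.angle(np.exp(1j * np.asarray(phase, dtype=float)))


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D sampling grid.

    dims are voxel counts, voxel_size is (dx, dy, dz) in mm, slice_axis the
    axis along which 2-D analysis slices are taken.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.0)
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    @property
    def n_slices(self) -> int:
        return self.dims[self.slice_axis]

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


@dataclass
class RegionMaskSet:
    """Boolean region supports: SN / red nucleus / nigrosome-1, per hemisphere."""

    masks: dict[str, np.ndarray]
    grid: VoxelGrid

    def __post_init__(self) -> None:
        for label, m in self.masks.items():
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            if m.shape != self.grid.dims:
                raise ValueError(f"mask {label} shape {m.shape} != grid {self.grid.dims}")
            self.masks[label] = m.astype(bool)
        for side in ("L", "R"):
            n1, sn = self.masks.get(f"N1_{side}"), self.masks.get(f"SN_{side}")
            if n1 is not None and sn is not None and np.any(n1 & ~sn):
                raise ValueError(f"N1_{side} must be contained in SN_{side}")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.masks[label]


@dataclass
class ComplexEchoSeries:
    """Multi-channel multi-echo GRE acquisition as magnitude + wrapped phase.

    magnitude and phase are arrays of shape (n_channels, n_echoes, *grid.dims).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    te_list_ms: tuple[float, ...]
    b0_tesla: float
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude/phase shape mismatch")
        if self.magnitude.ndim != 5:
            raise ValueError("expected (channel, echo, x, y, z) arrays")
        if self.magnitude.shape[1] != len(self.te_list_ms):
            raise ValueError("echo count does not match te_list")
        if self.magnitude.shape[2:] != self.grid.dims:
            raise ValueError("volume shape does not match grid")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.magnitude.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.magnitude.shape[1]


@dataclass
class FrequencyMap:
    """Per-voxel off-resonance frequency in Hz, defined inside a brain mask."""

    values_hz: np.ndarray
    mask: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values_hz = np.asarray(self.values_hz, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values_hz.shape != self.grid.dims or self.mask.shape != self.grid.dims:
            raise ValueError("shape mismatch with grid")
        if not np.all(np.isfinite(self.values_hz[self.mask])):
            raise ValueError("non-finite frequency inside mask")
        self.values_hz = np.where(self.mask, self.values_hz, 0.0)


@dataclass
class SusceptibilityMap:
    """Voxelwise magnetic susceptibility in ppb, referenced to zero mask mean."""

    values_ppb: np.ndarray
    mask: np.ndarray
    grid: VoxelGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_ppb = np.asarray(self.values_ppb, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values_ppb.shape != self.grid.dims:
            raise ValueError("shape mismatch with grid")
        if not np.all(np.isfinite(self.values_ppb[self.mask])):
            raise ValueError("non-finite susceptibility inside mask")


@dataclass
class SMWIVolume:
    """Susceptibility-map-weighted image: combined magnitude x paramagnetic mask."""

    values: np.ndarray
    grid: VoxelGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("SMWI values must be nonnegative")


def save_nifti(volume: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine())
    img.header.set_zooms(grid.voxel_size[: volume.ndim] + (1.0,) * (volume.ndim - 3))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(dims=tuple(data.shape[:3]), voxel_size=tuple(float(z) for z in zooms))
    return data, grid


def save_mask_set(masks: RegionMaskSet, out_dir: str | Path, subject_id: str) -> None:
    out = Path(out_dir)
    for label, m in masks.masks.items():
        save_nifti(m.astype(np.uint8), masks.grid, out / f"{subject_id}_mask_{label}.nii.gz")


def load_mask_set(in_dir: str | Path, subject_id: str, grid: VoxelGrid) -> RegionMaskSet:
    masks: dict[str, np.ndarray] = {}
    for label in REGION_LABELS:
        p = Path(in_dir) / f"{subject_id}_mask_{label}.nii.gz"
        if p.exists():
            data, _ = load_nifti(p)
            masks[label] = data > 0.5
    return RegionMaskSet(masks=masks, grid=grid)


def region_medians(values: np.ndarray, masks: Mapping[str, np.ndarray]) -> dict[str, float]:
    return {k: float(np.median(values[m])) for k, m in masks.items() if np.any(m)}
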