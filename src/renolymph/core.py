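"""Core domain types for cleared-organ confocal volumes.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based, matching TIFF page order;
* all physical quantities are micrometres (µm) internally; cubic
  millimetres appear only in reporting (1 mm³ = 1e9 µm³);
* voxel spacing is a per-axis physical size ``(z, y, x)`` in µm and is
  always supplied explicitly — file metadata from cleared-tissue
  acquisitions is frequently wrong and is never trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "ChannelStack",
    "BinaryMask",
    "LabeledComponents",
    "physical_volume",
    "UM3_PER_MM3",
]

#: cubic micrometres per cubic millimetre
UM3_PER_MM3 = 1e9

#: z-step of the study's confocal acquisitions, used as the default when a
#: caller gives no spacing at all (lateral pixel size has no published
#: default and must always be supplied in real analyses).
DEFAULT_Z_STEP_UM = 2.77


def _validate_spacing(spacing: Tuple[float, float, float]) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components (z, y, x), got {spacing!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacing components must be > 0, got {spacing!r}")
    return spacing


@dataclass
class VoxelGrid:
    """A single-channel 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    data:
        3D scalar array in ``(z, y, x)`` order.
    spacing:
        Per-axis voxel size in µm, ``(z, y, x)``.
    dtype_bits:
        Declared acquisition bit depth (8 for the study's stacks).
        Intensities must lie within ``[0, 2**dtype_bits - 1]``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    dtype_bits: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (z, y, x), got ndim={self.data.ndim}")
        self.spacing = _validate_spacing(self.spacing)
        if self.dtype_bits <= 0:
            raise ValueError("dtype_bits must be positive")
        lo, hi = float(self.data.min(initial=0)), float(self.data.max(initial=0))
        limit = 2 ** self.dtype_bits - 1
        if lo < 0 or hi > limit:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside declared {self.dtype_bits}-bit "
                f"range [0, {limit}]"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.spacing, self.dtype_bits)


@dataclass
class ChannelStack:
    """Co-registered named channels of one acquisition.

    All channels share shape and spacing.  Channel names follow the
    markers they image, e.g. ``"PROX1"`` (nuclear lymphatic marker),
    ``"LYVE1"`` (membranous lymphatic marker), ``"AUTOFLUOR"``
    (tissue autofluorescence / organ envelope).
    """

    channels: Dict[str, VoxelGrid]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a ChannelStack needs at least one channel")
        shapes = {g.shape for g in self.channels.values()}
        spacings = {g.spacing for g in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if len(spacings) > 1:
            raise ValueError(f"channels disagree on spacing: {spacings}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return next(iter(self.channels.values())).spacing

    def __getitem__(self, name: str) -> VoxelGrid:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass
class BinaryMask:
    """A 3D boolean mask sharing the shape/spacing contract of its source grid."""

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabeledComponents:
    """Connected components as an integer label image plus a per-label table.

    ``labels`` uses 0 for background; the table has one row per positive
    label with its voxel count and physical volume in µm³.
    """

    labels: np.ndarray
    spacing: Tuple[float, float, float]
    table: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = _validate_spacing(self.spacing)
        if self.table is None:
            self.table = self._build_table()

    def _build_table(self) -> pd.DataFrame:
        voxel_volume = float(np.prod(self.spacing))
        counts = np.bincount(self.labels.ravel())
        labels = np.nonzero(counts)[0]
        labels = labels[labels > 0]
        return pd.DataFrame(
            {
                "label": labels.astype(int),
                "voxel_count": counts[labels].astype(int),
                "volume_um3": counts[labels] * voxel_volume,
            }
        )

    @property
    def n_components(self) -> int:
        return len(self.table)

    def component_mask(self, label: int) -> BinaryMask:
        return BinaryMask(self.labels == label, self.spacing)


def physical_volume(mask: BinaryMask) -> float:
    """Physical volume of a mask in µm³: true-voxel count × voxel volume.

    Additive over disjoint masks and monotone under union.
    """
    return mask.voxel_count * mask.voxel_volume
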