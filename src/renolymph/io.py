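"""Readers and writers for every on-disk format the pipeline touches.

TIFF/OME-TIFF stacks in, masks and label images out as TIFF, branch
tables as CSV, vessel graphs as SWC, summaries as JSON, configuration as
YAML.  Spacing is always supplied by the caller (config/CLI) and
overrides whatever the file metadata claims.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .core import BinaryMask, ChannelStack, DEFAULT_Z_STEP_UM, LabeledComponents, VoxelGrid
from .graph import Branch, VesselGraph

__all__ = [
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_labels",
    "write_branch_table",
    "read_branch_table",
    "write_swc",
    "read_swc",
    "write_json",
    "read_json",
]

#: fixed header of the per-branch CSV export
BRANCH_TABLE_COLUMNS = [
    "branch_id",
    "length_um",
    "mean_diameter_um",
    "volume_um3",
    "end0_z_um",
    "end0_y_um",
    "end0_x_um",
    "end1_z_um",
    "end1_y_um",
    "end1_x_um",
]


def read_stack(
    path,
    channel_names: Sequence[str],
    spacing: Optional[Tuple[float, float, float]] = None,
) -> ChannelStack:
    """Read a multi-channel TIFF/OME-TIFF into a :class:`ChannelStack`.

    The file must hold ``len(channel_names)`` channels, either as the
    leading axis of a 4D array (CZYX) or as channel-interleaved pages.
    ``spacing`` is (z, y, x) in µm; when omitted, the study's 2.77 µm
    z-step is assumed with 1 µm lateral pixels (lateral size has no
    published default and should be given explicitly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if spacing is None:
        spacing = (DEFAULT_Z_STEP_UM, 1.0, 1.0)
    arr = tifffile.imread(path)
    n_ch = len(channel_names)
    if len(set(channel_names)) != n_ch:
        raise ValueError("channel names must be unique")
    if arr.ndim == 3:
        if n_ch != 1:
            raise ValueError(f"file has 1 channel but {n_ch} names were given")
        channels = [arr]
    elif arr.ndim == 4:
        if arr.shape[0] == n_ch:
            channels = [arr[i] for i in range(n_ch)]
        elif arr.shape[1] == n_ch:  # ZCYX page order
            channels = [arr[:, i] for i in range(n_ch)]
        else:
            raise ValueError(
                f"cannot match {n_ch} channel names to array of shape {arr.shape}"
            )
    else:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")
    bits = arr.dtype.itemsize * 8
    return ChannelStack(
        channels={
            name: VoxelGrid(ch, spacing, dtype_bits=bits)
            for name, ch in zip(channel_names, channels)
        },
        metadata={"source": str(path)},
    )


def write_stack(stack: ChannelStack, path) -> None:
    """Write a stack as a CZYX TIFF (8- or 16-bit as stored)."""
    names = list(stack.channels)
    arr = np.stack([stack.channels[n].data for n in names], axis=0)
    tifffile.imwrite(
        path,
        arr,
        metadata={"axes": "CZYX", "channel_names": names},
    )


def read_mask(path, spacing: Tuple[float, float, float]) -> BinaryMask:
    return BinaryMask(tifffile.imread(path) > 0, spacing)


def write_mask(mask: BinaryMask, path) -> None:
    tifffile.imwrite(path, mask.data.astype(np.uint8) * np.uint8(255))


def write_labels(components: LabeledComponents, path) -> None:
    labels = components.labels
    dtype = np.uint16 if labels.max(initial=0) < 2 ** 16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


def write_branch_table(graph: VesselGraph, path) -> None:
    """Write one CSV row per branch (id, length, mean diameter, volume, endpoints)."""
    rows = []
    for b in graph.branches:
        p0, p1 = b.centerline[0], b.centerline[-1]
        rows.append(
            [b.id, b.length, b.mean_diameter, b.volume, *p0.tolist(), *p1.tolist()]
        )
    pd.DataFrame(rows, columns=BRANCH_TABLE_COLUMNS).to_csv(path, index=False)


def read_branch_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BRANCH_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"branch table missing columns {sorted(missing)}")
    return df


def write_swc(graph: VesselGraph, path) -> None:
    """Export the centerline graph as SWC (one node per centerline point).

    SWC columns: index, type, x, y, z, radius, parent.  Coordinates are
    µm with SWC's (x, y, z) order; the radius is the branch's mean
    radius.  Each branch is a parent-linked chain; chains are not joined
    across junctions (sufficient for morphology viewers and round-trip).
    """
    lines = ["# index type x y z radius parent"]
    idx = 0
    for b in graph.branches:
        radius = b.mean_diameter / 2.0 if b.mean_diameter else 1.0
        parent = -1
        for pt in b.centerline:
            idx += 1
            z, y, x = pt
            lines.append(f"{idx} 2 {x:.4f} {y:.4f} {z:.4f} {radius:.4f} {parent}")
            parent = idx
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, t, x, y, z, r, parent = line.split()
        rows.append(
            (int(i), int(t), float(x), float(y), float(z), float(r), int(parent))
        )
    return pd.DataFrame(
        rows, columns=["index", "type", "x", "y", "z", "radius", "parent"]
    )


def write_json(obj: Dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> Dict:
    return json.loads(Path(path).read_text())
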