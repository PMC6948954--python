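"""Centerline-graph containers for vessel networks.

A :class:`VesselGraph` is the common currency between the synthetic
phantom generator (which knows the true graph) and the morphometry stage
(which estimates one from a segmented plexus): nodes are junctions or
endpoints, edges are branches carrying a centerline polyline plus the
per-branch measurements (length, mean diameter, volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["Branch", "VesselGraph", "NetworkSummary", "polyline_length"]


def polyline_length(points: np.ndarray) -> float:
    """Length of a polyline given as an (N, 3) array of physical points (µm)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


@dataclass
class Branch:
    """One vessel branch: a maximal junction-free centerline path."""

    id: int
    centerline: np.ndarray  # (N, 3) physical coordinates (z, y, x) in µm
    endpoints: Tuple[int, int]  # node ids
    length: float = 0.0  # µm
    mean_diameter: float = 0.0  # µm
    volume: float = 0.0  # µm³

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if self.length == 0.0:
            self.length = polyline_length(self.centerline)

    @property
    def euclidean_span(self) -> float:
        """Straight-line distance between the branch's two ends (µm)."""
        if len(self.centerline) < 2:
            return 0.0
        return float(np.linalg.norm(self.centerline[-1] - self.centerline[0]))


@dataclass
class VesselGraph:
    """Centerline graph of a vessel plexus."""

    nodes: Dict[int, np.ndarray]  # node id -> (z, y, x) µm
    branches: List[Branch]
    spacing: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.nodes = {int(k): np.asarray(v, dtype=float) for k, v in self.nodes.items()}
        node_ids = set(self.nodes)
        for b in self.branches:
            if b.endpoints[0] not in node_ids or b.endpoints[1] not in node_ids:
                raise ValueError(f"branch {b.id} references unknown node(s) {b.endpoints}")

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    def total_volume(self) -> float:
        return float(sum(b.volume for b in self.branches))

    def node_degrees(self) -> Dict[int, int]:
        """Degree of each node counted over branch incidences (self-loops count 2)."""
        deg = {n: 0 for n in self.nodes}
        for b in self.branches:
            deg[b.endpoints[0]] += 1
            deg[b.endpoints[1]] += 1
        return deg

    def is_connected(self) -> bool:
        """True if all nodes touched by branches form one component."""
        if not self.branches:
            return True
        adj: Dict[int, set] = {}
        for b in self.branches:
            a, c = b.endpoints
            adj.setdefault(a, set()).add(c)
            adj.setdefault(c, set()).add(a)
        start = next(iter(adj))
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen == set(adj)


@dataclass
class NetworkSummary:
    """The four per-kidney network statistics.

    ``length_range`` is the spread (max − min) of branch lengths within
    one kidney, a single scalar per organ; ``max_mean_diameter`` is the
    largest per-branch mean diameter.
    """

    n_branches: int
    length_range: float  # µm
    max_mean_diameter: float  # µm
    total_volume: float  # µm³

    def as_dict(self) -> Dict[str, float]:
        return {
            "n_branches": int(self.n_branches),
            "length_range_um": float(self.length_range),
            "max_mean_diameter_um": float(self.max_mean_diameter),
            "total_volume_um3": float(self.total_volume),
        }
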