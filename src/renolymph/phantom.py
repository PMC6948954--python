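"""Synthetic two-channel phantoms of the embryonic-kidney lymphatic scene.

The generator builds, with exact ground truth, the features a cleared
embryonic kidney presents to the analysis pipeline:

* a ring-like lymphatic anastomosis at the hilum feeding a bifurcating
  tubular plexus (branch lengths of tens to ~100 µm, diameters tapering
  through generations),
* PROX1+ nuclei spaced along vessel centerlines,
* isolated PROX1+/LYVE-1+ cell clusters of 1 to 8+ touching cells,
* LYVE-1-only macrophage blobs and weak PROX1-only tubular-epithelium
  patches as confounders,
* an ellipsoidal organ envelope in an autofluorescence channel, and
* Poisson and/or Gaussian noise.

Everything is reproducible bit-exactly from ``(config, seed)``; a single
seed expands into fixed per-stage substreams.  Tubes are rasterized by
distance-to-polyline in physical coordinates, which is exact under
anisotropic voxels, and every rasterized foreground voxel is attributed
to exactly one ground-truth branch through a membership label image.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BinaryMask, ChannelStack, LabeledComponents, VoxelGrid
from .graph import Branch, VesselGraph, polyline_length

__all__ = [
    "VesselTreeSpec",
    "ClusterSpec",
    "ConfounderSpec",
    "NoiseParams",
    "PhantomConfig",
    "GroundTruthCluster",
    "Confounder",
    "SyntheticGroundTruth",
    "PhantomGeometryError",
    "sample_network",
    "rasterize",
    "place_nuclei",
    "add_clusters",
    "add_confounders_and_noise",
    "generate_phantom",
]


class PhantomGeometryError(RuntimeError):
    """Raised when the requested geometry cannot be placed within budget."""


# ---------------------------------------------------------------------------
# specs


@dataclass
class VesselTreeSpec:
    """Geometry of the ring anastomosis plus bifurcating tree.

    ``branch_radius_distribution`` is the (mean, sd) of first-generation
    branch radii in µm; each further generation multiplies the radius by
    ``radius_taper``.  The ring tube itself is one generation thicker
    (mean radius / taper) unless ``ring_tube_radius`` is given.
    """

    ring_radius: float = 60.0  # µm, centerline radius of the anastomosis
    n_generations: int = 3
    branch_length_distribution: Tuple[float, float] = (70.0, 12.0)  # µm
    branch_radius_distribution: Tuple[float, float] = (11.0, 1.5)  # µm
    radius_taper: float = 0.75  # per generation, in (0, 1]
    nucleus_spacing: float = 10.0  # µm along centerlines
    ring_tube_radius: Optional[float] = None
    center: Optional[Tuple[float, float, float]] = None  # ring center, µm (z, y, x)
    min_clearance: float = 8.0  # µm surface-to-surface between non-adjacent tubes
    attempt_budget: int = 80

    def __post_init__(self) -> None:
        if self.ring_radius <= 0 or self.branch_length_distribution[0] <= 0:
            raise ValueError("lengths and radii must be positive")
        if self.branch_radius_distribution[0] <= 0:
            raise ValueError("lengths and radii must be positive")
        if not (0 < self.radius_taper <= 1):
            raise ValueError("radius_taper must be in (0, 1]")

    @property
    def effective_ring_tube_radius(self) -> float:
        if self.ring_tube_radius is not None:
            return self.ring_tube_radius
        return self.branch_radius_distribution[0] / self.radius_taper


@dataclass
class ClusterSpec:
    """Isolated PROX1+/LYVE-1+ cluster population."""

    n_clusters: int = 12
    #: probability of a cluster holding 1, 2, ... cells (renormalized)
    cells_per_cluster_probs: Tuple[float, ...] = (
        0.25, 0.20, 0.15, 0.12, 0.10, 0.08, 0.05, 0.05,
    )
    cell_radius: float = 5.0  # µm
    min_distance_to_plexus: float = 20.0  # µm, surface distance; 0 allowed -> contiguous

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if len(self.cells_per_cluster_probs) > 12:
            raise ValueError("cells-per-cluster support is {1..12}")


@dataclass
class ConfounderSpec:
    """Non-lymphatic structures that carry one marker only."""

    n_macrophages: int = 20  # strong LYVE-1-only blobs
    n_tubule_patches: int = 6  # weak PROX1-only regions
    intensity_fraction: float = 0.3  # tubule brightness relative to foreground

    def __post_init__(self) -> None:
        if self.n_macrophages < 0 or self.n_tubule_patches < 0:
            raise ValueError("confounder counts must be >= 0")
        if not (0 < self.intensity_fraction <= 1):
            raise ValueError("intensity_fraction must be in (0, 1]")


@dataclass
class NoiseParams:
    gaussian_sd: float = 20.0  # intensity units (10% of the default foreground)
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables


@dataclass
class PhantomConfig:
    """Full phantom description: field of view, scene and noise."""

    shape: Tuple[int, int, int] = (256, 256, 256)  # voxels (z, y, x)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)  # µm
    foreground: float = 200.0  # marker intensity (8-bit scale)
    envelope_intensity: float = 120.0
    envelope_semiaxes: Tuple[float, float, float] = (200.0, 230.0, 230.0)  # µm
    envelope_center: Optional[Tuple[float, float, float]] = None  # default: FOV center
    nucleus_radius: float = 3.5  # µm, vessel-wall nuclei
    vessels: VesselTreeSpec = field(default_factory=VesselTreeSpec)
    clusters: ClusterSpec = field(default_factory=ClusterSpec)
    confounders: ConfounderSpec = field(default_factory=ConfounderSpec)
    noise: NoiseParams = field(default_factory=NoiseParams)

    def field_of_view(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def resolved_envelope_center(self) -> np.ndarray:
        if self.envelope_center is not None:
            return np.asarray(self.envelope_center, dtype=float)
        return self.field_of_view() / 2.0

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("shape", "spacing", "envelope_semiaxes", "envelope_center"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        nested = {
            "vessels": VesselTreeSpec,
            "clusters": ClusterSpec,
            "confounders": ConfounderSpec,
            "noise": NoiseParams,
        }
        kwargs = {}
        for key, value in d.items():
            if key in nested and isinstance(value, dict):
                value = dict(value)
                for tup_field in ("branch_length_distribution",
                                  "branch_radius_distribution",
                                  "cells_per_cluster_probs", "center"):
                    if tup_field in value and value[tup_field] is not None:
                        value[tup_field] = tuple(value[tup_field])
                kwargs[key] = nested[key](**value)
            elif key in ("shape", "spacing", "envelope_semiaxes", "envelope_center"):
                kwargs[key] = tuple(value) if value is not None else None
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruthCluster:
    centroid: np.ndarray  # µm
    n_cells: int
    cell_centers: np.ndarray  # (n_cells, 3) µm
    contiguous: bool = False


@dataclass
class Confounder:
    kind: str  # "macrophage" | "tubule"
    center: np.ndarray  # µm
    size: Tuple[float, ...]  # radius, or ellipsoid semi-axes


@dataclass
class SyntheticGroundTruth:
    """Exact scene description keyed by seed — the acceptance oracle."""

    graph: VesselGraph
    clusters: List[GroundTruthCluster] = field(default_factory=list)
    confounders: List[Confounder] = field(default_factory=list)
    organ_volume: float = 0.0  # µm³, analytic ellipsoid volume
    seed: Optional[int] = None
    noise_params: Optional[NoiseParams] = None
    nucleus_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    membership: Optional[LabeledComponents] = None  # voxel -> branch id
    foreground: float = 200.0

    @property
    def n_branches(self) -> int:
        return self.graph.n_branches

    def vessel_mask(self) -> BinaryMask:
        if self.membership is None:
            raise ValueError("phantom was not rasterized")
        return BinaryMask(self.membership.labels > 0, self.membership.spacing)

    def summary_dict(self) -> Dict:
        return {
            "seed": self.seed,
            "n_branches": self.n_branches,
            "total_length_um": self.graph.total_length(),
            "total_volume_um3": self.graph.total_volume(),
            "n_clusters": len([c for c in self.clusters if not c.contiguous]),
            "cluster_cells": [int(c.n_cells) for c in self.clusters],
            "organ_volume_um3": self.organ_volume,
        }


# ---------------------------------------------------------------------------
# geometry helpers

_EPS = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise ValueError("zero vector")
    return v / n


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        m = np.cross(v, _random_unit(rng))
        n = np.linalg.norm(m)
        if n > 1e-3:
            return m / n


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between segments [p0,p1] and [q0,q1] (physical µm)."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > _EPS:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > _EPS else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for the clamped t
    if a > _EPS:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm((p0 + s * u) - (q0 + t * v)))


def _sample_segment(p0: np.ndarray, p1: np.ndarray, step: float = 3.0) -> np.ndarray:
    n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / step)) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


# ---------------------------------------------------------------------------
# network sampling


class _Scene:
    """Collision bookkeeping: segments with radii, plus placement bounds."""

    def __init__(self, bounds_lo, bounds_hi, envelope_center=None, envelope_semiaxes=None):
        # (p0, p1, radius, node ids of the owning branch)
        self.segments: List[Tuple[np.ndarray, np.ndarray, float, frozenset]] = []
        self.lo = np.asarray(bounds_lo, dtype=float)
        self.hi = np.asarray(bounds_hi, dtype=float)
        self.env_c = envelope_center
        self.env_s = envelope_semiaxes

    def in_bounds(self, p: np.ndarray, r: float, margin: float = 4.0) -> bool:
        if np.any(p - r - margin < self.lo) or np.any(p + r + margin > self.hi):
            return False
        if self.env_c is not None:
            rel = (p - self.env_c) / (np.asarray(self.env_s) - r - margin)
            if rel @ rel > 1.0:
                return False
        return True

    def clear_of(self, p0, p1, r, clearance: float, start_node: int = -1) -> bool:
        for q0, q1, rq, owner in self.segments:
            rsum = r + rq + clearance
            # branches meeting the candidate at its start node (the
            # parent, siblings, the ring at an attachment) legitimately
            # overlap there; they still must clear the candidate outside
            # a junction ball, so near-parallel siblings cannot fuse
            # into a single tube.  Everything else is checked strictly.
            if start_node in owner:
                if _min_distance_outside(p0, p1, q0, q1, p0, rsum) < rsum:
                    return False
                continue
            if _segment_distance(p0, p1, q0, q1) < rsum:
                return False
        return True

    def add(self, p0, p1, r, owner=frozenset()) -> None:
        self.segments.append(
            (np.asarray(p0, float), np.asarray(p1, float), float(r), frozenset(owner))
        )


def _min_distance_outside(p0, p1, q0, q1, center, exclusion, step: float = 2.5) -> float:
    """Min distance between two segments, ignoring points inside a ball."""
    P = _sample_segment(p0, p1, step)
    Q = _sample_segment(q0, q1, step)
    P = P[np.linalg.norm(P - center, axis=1) > exclusion]
    Q = Q[np.linalg.norm(Q - center, axis=1) > exclusion]
    if len(P) == 0 or len(Q) == 0:
        return np.inf
    return float(np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=2).min())


def _point_segment_distance(p, q0, q1) -> float:
    v = q1 - q0
    c = v @ v
    t = np.clip((p - q0) @ v / c, 0.0, 1.0) if c > _EPS else 0.0
    return float(np.linalg.norm(p - (q0 + t * v)))


def _ring_point(center: np.ndarray, radius: float, theta: float) -> np.ndarray:
    return center + radius * np.array([0.0, np.cos(theta), np.sin(theta)])


def _arc_polyline(center, radius, theta0, theta1, step=3.0) -> np.ndarray:
    span = theta1 - theta0
    n = max(2, int(np.ceil(abs(span) * radius / step)) + 1)
    thetas = np.linspace(theta0, theta1, n)
    return np.stack([_ring_point(center, radius, t) for t in thetas])


def sample_network(
    spec: VesselTreeSpec,
    seed,
    bounds: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
    envelope: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> VesselGraph:
    """Sample a ring anastomosis with ``n_generations`` of bifurcations.

    Branch radii are stored as ``Branch.mean_diameter = 2 r``; volumes
    are filled in after rasterization from the membership labels.  The
    returned graph is connected; non-adjacent tubes keep a surface
    clearance of ``spec.min_clearance`` so downstream segmentation and
    skeletonization see them as distinct branches.  A tree that crowds
    itself into a corner is resampled wholesale (deterministically)
    before the attempt budget is declared exhausted.

    Raises
    ------
    PhantomGeometryError
        if a branch cannot be placed without overlap within the
        attempt budget.
    """
    base = _seed_int(seed)
    last_error: Optional[Exception] = None
    for trial in range(30):
        rng = np.random.default_rng(np.random.SeedSequence([base, trial]))
        try:
            return _sample_network_once(spec, rng, bounds, envelope)
        except PhantomGeometryError as exc:
            last_error = exc
    raise PhantomGeometryError(
        f"network sampling failed after 30 whole-tree retries: {last_error}"
    )


def _sample_network_once(
    spec: VesselTreeSpec,
    rng: np.random.Generator,
    bounds,
    envelope,
) -> VesselGraph:
    center = np.asarray(
        spec.center if spec.center is not None else (150.0, 256.0, 256.0), dtype=float
    )
    if bounds is None:
        bounds = (center - 1e6, center + 1e6)
    scene = _Scene(
        bounds[0],
        bounds[1],
        envelope_center=None if envelope is None else envelope[0],
        envelope_semiaxes=None if envelope is None else envelope[1],
    )

    nodes: Dict[int, np.ndarray] = {}
    branches: List[Branch] = []
    next_node = [0]
    next_branch = [1]

    def new_node(p: np.ndarray) -> int:
        nodes[next_node[0]] = np.asarray(p, dtype=float)
        next_node[0] += 1
        return next_node[0] - 1

    def add_branch(
        poly: np.ndarray, n0: int, n1: int, radius: float, straight: bool = False
    ) -> Branch:
        b = Branch(
            id=next_branch[0],
            centerline=poly,
            endpoints=(n0, n1),
            mean_diameter=2.0 * radius,
        )
        next_branch[0] += 1
        branches.append(b)
        owner = frozenset((n0, n1))
        if straight:  # collision geometry: one chord suffices
            scene.add(poly[0], poly[-1], radius, owner)
        else:
            for i in range(len(poly) - 1):
                scene.add(poly[i], poly[i + 1], radius, owner)
        return b

    r_ring = spec.effective_ring_tube_radius
    n_roots = 2 if spec.n_generations >= 1 else 0

    # --- ring -------------------------------------------------------------
    if n_roots == 0:
        theta0 = float(rng.uniform(0, 2 * np.pi))
        p = _ring_point(center, spec.ring_radius, theta0)
        n0 = new_node(p)
        poly = _arc_polyline(center, spec.ring_radius, theta0, theta0 + 2 * np.pi)
        poly[-1] = poly[0]  # exact closure
        add_branch(poly, n0, n0, r_ring)
        return VesselGraph(nodes=nodes, branches=branches)

    theta0 = float(rng.uniform(0, 2 * np.pi))
    thetas = [theta0, theta0 + np.pi + float(rng.normal(0, 0.15))]
    attach_pts = [_ring_point(center, spec.ring_radius, t) for t in thetas]
    attach_nodes = [new_node(p) for p in attach_pts]
    arcs = [
        _arc_polyline(center, spec.ring_radius, thetas[0], thetas[1]),
        _arc_polyline(center, spec.ring_radius, thetas[1], thetas[0] + 2 * np.pi),
    ]
    for arc, (na, nb) in zip(arcs, [(0, 1), (1, 0)]):
        arc[0] = attach_pts[na]
        arc[-1] = attach_pts[nb]
        add_branch(arc, attach_nodes[na], attach_nodes[nb], r_ring)

    # --- bifurcating tree ---------------------------------------------------
    axis = np.array([1.0, 0.0, 0.0])  # growth into the organ (+z)
    mean_len, sd_len = spec.branch_length_distribution
    mean_rad, sd_rad = spec.branch_radius_distribution

    def sample_length(r_parent: float, r_child: float) -> float:
        # floor: a branch shorter than the two junction blobs it spans is
        # not a resolvable vessel segment and is not generated
        floor = max(0.45 * mean_len, 2.0 * (r_parent + r_child) + spec.min_clearance)
        return float(np.clip(rng.normal(mean_len, sd_len), floor, 1.8 * mean_len))

    def sample_root_radius() -> float:
        return float(np.clip(rng.normal(mean_rad, sd_rad), 0.5 * mean_rad, 1.6 * mean_rad))

    # frontier entries: (start point, start node, direction, radius, generation)
    frontier = []
    for node_id, pt, theta in zip(attach_nodes, attach_pts, thetas):
        radial = _unit(pt - center)
        for attempt in range(spec.attempt_budget):
            direction = _unit(
                0.9 * axis + 0.5 * radial + 0.25 * _random_unit(rng)
            )
            radius = sample_root_radius()
            length = sample_length(r_ring, radius)
            end = pt + direction * length
            if scene.in_bounds(end, radius) and scene.clear_of(
                pt, end, radius, spec.min_clearance, start_node=node_id
            ):
                break
        else:
            raise PhantomGeometryError("could not place a root branch")
        n_end = new_node(end)
        add_branch(_sample_segment(pt, end), node_id, n_end, radius, straight=True)
        frontier.append((end, n_end, direction, radius, 1))

    while frontier:
        start, start_node, parent_dir, parent_radius, gen = frontier.pop(0)
        if gen >= spec.n_generations:
            continue
        child_radius = parent_radius * spec.radius_taper
        placed = 0
        for k in range(2):
            for attempt in range(spec.attempt_budget):
                alpha = float(rng.uniform(0.55, 0.85))  # rad off the parent axis
                m = _perpendicular(parent_dir, rng)
                n = np.cross(parent_dir, m)
                if k == 1 and attempt < spec.attempt_budget // 3:
                    phi = phi0 + np.pi + float(rng.normal(0, 0.3))
                else:
                    phi = float(rng.uniform(0, 2 * np.pi))
                lateral = np.cos(phi) * m + np.sin(phi) * n
                direction = _unit(np.cos(alpha) * parent_dir + np.sin(alpha) * lateral)
                if scene.env_c is not None:
                    # steer away from the envelope wall
                    rel = (start - scene.env_c) / np.asarray(scene.env_s)
                    r2 = float(rel @ rel)
                    if r2 > 0.2:
                        inward = -rel / np.linalg.norm(rel)
                        direction = _unit(direction + 1.2 * r2 * inward)
                length = sample_length(parent_radius, child_radius)
                end = start + direction * length
                if scene.in_bounds(end, child_radius) and scene.clear_of(
                    start, end, child_radius, spec.min_clearance, start_node=start_node
                ):
                    if k == 0:
                        phi0 = phi
                    break
            else:
                raise PhantomGeometryError(
                    f"could not place generation-{gen + 1} branch within budget"
                )
            n_end = new_node(end)
            add_branch(_sample_segment(start, end), start_node, n_end, child_radius, straight=True)
            frontier.append((end, n_end, direction, child_radius, gen + 1))
            placed += 1

    return VesselGraph(nodes=nodes, branches=branches)


# ---------------------------------------------------------------------------
# rasterization


def _branch_radius(branch: Branch) -> float:
    return branch.mean_diameter / 2.0


def rasterize(
    graph: VesselGraph,
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    foreground: float = 200.0,
) -> Tuple[VoxelGrid, LabeledComponents]:
    """Draw every branch as a tube of its radius; label voxels by branch.

    A voxel belongs to branch *b* if its center lies within ``r_b`` of
    the branch centerline; where tubes overlap (at junctions) the voxel
    goes to the branch whose surface it lies deepest inside
    (most negative ``distance - radius``).
    """
    shape = tuple(int(s) for s in shape)
    sp = np.asarray(spacing, dtype=float)
    best = np.full(shape, np.inf, dtype=np.float32)  # d - r, signed depth
    labels = np.zeros(shape, dtype=np.int32)

    for b in graph.branches:
        r = _branch_radius(b)
        if r <= 0:
            raise ValueError(f"branch {b.id} has non-positive radius")
        poly = b.centerline
        for i in range(len(poly) - 1):
            p0, p1 = poly[i], poly[i + 1]
            lo = np.minimum(p0, p1) - r - sp
            hi = np.maximum(p0, p1) + r + sp
            i0 = np.maximum(np.floor(lo / sp).astype(int), 0)
            i1 = np.minimum(np.ceil(hi / sp).astype(int) + 1, shape)
            if np.any(i0 >= i1):
                continue
            zz = (np.arange(i0[0], i1[0]) * sp[0])[:, None, None]
            yy = (np.arange(i0[1], i1[1]) * sp[1])[None, :, None]
            xx = (np.arange(i0[2], i1[2]) * sp[2])[None, None, :]
            v = p1 - p0
            vv = float(v @ v)
            wz, wy, wx = zz - p0[0], yy - p0[1], xx - p0[2]
            if vv > _EPS:
                t = (wz * v[0] + wy * v[1] + wx * v[2]) / vv
                np.clip(t, 0.0, 1.0, out=t)
            else:
                t = 0.0
            dz = wz - t * v[0]
            dy = wy - t * v[1]
            dx = wx - t * v[2]
            d = np.sqrt(dz * dz + dy * dy + dx * dx)
            depth = (d - r).astype(np.float32)
            sl = (slice(i0[0], i1[0]), slice(i0[1], i1[1]), slice(i0[2], i1[2]))
            sub_best = best[sl]
            update = (d <= r) & (depth < sub_best)
            if np.any(update):
                sub_best[update] = depth[update]
                labels[sl][update] = b.id
            best[sl] = sub_best

    grid = VoxelGrid(
        np.where(labels > 0, np.uint8(round(foreground)), np.uint8(0)),
        tuple(spacing),
        dtype_bits=8,
    )
    membership = LabeledComponents(labels, tuple(spacing))
    return grid, membership


def assign_branch_volumes(graph: VesselGraph, membership: LabeledComponents) -> None:
    """Fill each branch's ground-truth volume from the membership labels."""
    voxel_volume = float(np.prod(membership.spacing))
    counts = np.bincount(membership.labels.ravel())
    for b in graph.branches:
        b.volume = float(counts[b.id]) * voxel_volume if b.id < len(counts) else 0.0


# ---------------------------------------------------------------------------
# spheres / ellipsoids


def _add_sphere(data, center, radius, spacing, value) -> None:
    sp = np.asarray(spacing, dtype=float)
    c = np.asarray(center, dtype=float)
    i0 = np.maximum(np.floor((c - radius) / sp).astype(int), 0)
    i1 = np.minimum(np.ceil((c + radius) / sp).astype(int) + 1, data.shape)
    if np.any(i0 >= i1):
        return
    zz = (np.arange(i0[0], i1[0]) * sp[0] - c[0])[:, None, None]
    yy = (np.arange(i0[1], i1[1]) * sp[1] - c[1])[None, :, None]
    xx = (np.arange(i0[2], i1[2]) * sp[2] - c[2])[None, None, :]
    inside = zz * zz + yy * yy + xx * xx <= radius * radius
    sub = data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    sub[inside] = np.maximum(sub[inside], value)


def _add_ellipsoid(data, center, semiaxes, spacing, value) -> None:
    sp = np.asarray(spacing, dtype=float)
    c = np.asarray(center, dtype=float)
    s = np.asarray(semiaxes, dtype=float)
    i0 = np.maximum(np.floor((c - s) / sp).astype(int), 0)
    i1 = np.minimum(np.ceil((c + s) / sp).astype(int) + 1, data.shape)
    if np.any(i0 >= i1):
        return
    zz = ((np.arange(i0[0], i1[0]) * sp[0] - c[0]) / s[0])[:, None, None]
    yy = ((np.arange(i0[1], i1[1]) * sp[1] - c[1]) / s[1])[None, :, None]
    xx = ((np.arange(i0[2], i1[2]) * sp[2] - c[2]) / s[2])[None, None, :]
    inside = zz * zz + yy * yy + xx * xx <= 1.0
    sub = data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    sub[inside] = np.maximum(sub[inside], value)


# ---------------------------------------------------------------------------
# nuclei


def place_nuclei(
    graph: VesselGraph,
    spacing_along: float,
    nucleus_radius: float,
    seed,
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    foreground: float = 200.0,
    jitter_fraction: float = 0.2,
) -> Tuple[VoxelGrid, np.ndarray]:
    """Render PROX1+ nuclei as spheres along every branch centerline.

    Nuclei sit every ``spacing_along`` µm of arc length (both ends
    included), jittered along the centerline by up to
    ``jitter_fraction × spacing_along``.  Returns the PROX1 grid and the
    (N, 3) array of nucleus centers recorded in ground truth.
    """
    if spacing_along <= 0:
        raise ValueError("spacing_along must be > 0")
    rng = np.random.default_rng(seed)
    data = np.zeros(shape, dtype=np.uint8)
    centers: List[np.ndarray] = []
    for b in graph.branches:
        poly = b.centerline
        if len(poly) < 2:
            continue
        steps = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        total = cum[-1]
        if total <= 0:
            continue
        n_pts = int(np.floor(total / spacing_along)) + 1
        for k in range(n_pts):
            s = k * spacing_along
            if jitter_fraction > 0:
                s += float(rng.uniform(-1, 1)) * jitter_fraction * spacing_along
                s = float(np.clip(s, 0.0, total))
            j = int(np.searchsorted(cum, s, side="right") - 1)
            j = min(j, len(steps) - 1)
            frac = (s - cum[j]) / steps[j] if steps[j] > 0 else 0.0
            p = poly[j] * (1 - frac) + poly[j + 1] * frac
            centers.append(p)
            _add_sphere(data, p, nucleus_radius, spacing, np.uint8(round(foreground)))
    grid = VoxelGrid(data, tuple(spacing), dtype_bits=8)
    return grid, np.asarray(centers).reshape(-1, 3)


# ---------------------------------------------------------------------------
# clusters


def _build_cluster_cells(n_cells: int, cell_radius: float, rng):
    """Centers of ``n_cells`` mutually contacting spheres plus their bonds.

    Cells sit just under two radii apart; the returned bond list records
    which pairs are in contact so the renderer can draw a thin
    cytoplasmic bridge between them — spheres in exact point contact
    fragment on a discrete grid, which would corrupt the ground truth.
    """
    contact = 1.9 * cell_radius
    centers = [np.zeros(3)]
    bonds = []
    while len(centers) < n_cells:
        base_idx = int(rng.integers(len(centers)))
        base = centers[base_idx]
        for _ in range(200):
            cand = base + contact * _random_unit(rng)
            dists = [np.linalg.norm(cand - c) for c in centers]
            if min(dists) >= contact * 0.999:
                bonds.append((base_idx, len(centers)))
                centers.append(cand)
                break
        else:  # fall back to a fresh base cell
            continue
    return np.asarray(centers), bonds


def _add_capsule(data, p0, p1, radius, spacing, value) -> None:
    """Render a capsule (cylinder with spherical caps) by max-blend."""
    sp = np.asarray(spacing, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.minimum(p0, p1) - radius - sp
    hi = np.maximum(p0, p1) + radius + sp
    i0 = np.maximum(np.floor(lo / sp).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / sp).astype(int) + 1, data.shape)
    if np.any(i0 >= i1):
        return
    zz = (np.arange(i0[0], i1[0]) * sp[0])[:, None, None]
    yy = (np.arange(i0[1], i1[1]) * sp[1])[None, :, None]
    xx = (np.arange(i0[2], i1[2]) * sp[2])[None, None, :]
    v = p1 - p0
    vv = float(v @ v)
    wz, wy, wx = zz - p0[0], yy - p0[1], xx - p0[2]
    if vv > _EPS:
        t = np.clip((wz * v[0] + wy * v[1] + wx * v[2]) / vv, 0.0, 1.0)
    else:
        t = 0.0
    d2 = (wz - t * v[0]) ** 2 + (wy - t * v[1]) ** 2 + (wx - t * v[2]) ** 2
    inside = d2 <= radius * radius
    sub = data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    sub[inside] = np.maximum(sub[inside], value)



def _surface_distance_fn(vessel_mask: np.ndarray, spacing):
    """Fast point -> distance-to-vessel-surface queries via a KD-tree.

    Uses surface voxel centers, which is accurate to within one voxel —
    ample for placement margins of tens of µm.
    """
    if not vessel_mask.any():
        return lambda pts: np.full(len(np.atleast_2d(pts)), np.inf)
    surface = vessel_mask & ~ndimage.binary_erosion(vessel_mask)
    tree = cKDTree(np.argwhere(surface) * np.asarray(spacing, dtype=float))
    return lambda pts: np.atleast_1d(tree.query(np.atleast_2d(pts))[0])


def add_clusters(
    stack: ChannelStack,
    gt: SyntheticGroundTruth,
    spec: ClusterSpec,
    seed,
    envelope: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    _vessel_distance: Optional[np.ndarray] = None,
) -> None:
    """Plant isolated cell clusters in both channels; record ground truth.

    Each cluster is ``n_cells`` touching solid spheres rendered in the
    LYVE-1 channel with a PROX1 nuclear core (radius 0.55 × cell radius)
    at each cell center.  Clusters keep ``min_distance_to_plexus`` of
    clear space to the vessel surface; with ``min_distance_to_plexus ==
    0`` they are planted touching the plexus and flagged ``contiguous``.
    """
    if spec.n_clusters == 0:
        return
    rng = np.random.default_rng(seed)
    lyve = stack["LYVE1"].data
    prox = stack["PROX1"].data
    spacing = stack.spacing
    fg = np.uint8(round(gt.foreground))

    if _vessel_distance is None:
        _vessel_distance = _surface_distance_fn(lyve > 0, spacing)
    distance_at = _vessel_distance

    probs = np.asarray(spec.cells_per_cluster_probs, dtype=float)
    probs = probs / probs.sum()
    sizes = rng.choice(np.arange(1, len(probs) + 1), size=spec.n_clusters, p=probs)

    sp = np.asarray(spacing, dtype=float)
    shape = stack.shape
    placed_centers: List[np.ndarray] = []
    for n_cells in sizes:
        placed = False
        for rebuild in range(8):  # a more compact arrangement may fit
            cells, bonds = _build_cluster_cells(int(n_cells), spec.cell_radius, rng)
            extent = float(np.linalg.norm(cells, axis=1).max()) + spec.cell_radius
            contiguous = spec.min_distance_to_plexus <= 0
            if contiguous:
                lo_d, hi_d = 0.0, spec.cell_radius
            else:
                lo_d = spec.min_distance_to_plexus + extent
                hi_d = np.inf
            for attempt in range(800):
                idx = np.array(
                    [rng.integers(2, s - 2) for s in shape], dtype=float
                )
                p = idx * sp
                d = float(distance_at(p)[0])
                if not (lo_d <= d <= max(lo_d + 1.0, min(hi_d, lo_d + 200.0))):
                    continue
                if envelope is not None:
                    rel = (p - envelope[0]) / (np.asarray(envelope[1]) - extent - 4.0)
                    if rel @ rel > 1.0:
                        continue
                # keep clusters well apart; in a crowded field accept the
                # minimum that still keeps them distinct components
                sep = (2 * extent + 25.0) if attempt < 400 else (2 * extent + 10.0)
                if placed_centers and min(
                    np.linalg.norm(p - q) for q in placed_centers
                ) < sep:
                    continue
                placed = True
                break
            if placed:
                break
        if not placed:
            raise PhantomGeometryError("no free space for cluster placement")
        placed_centers.append(p)
        abs_cells = cells + p
        for c in abs_cells:
            _add_sphere(lyve, c, spec.cell_radius, spacing, fg)
            _add_sphere(prox, c, 0.55 * spec.cell_radius, spacing, fg)
        for a, b in bonds:  # cytoplasmic bridges keep the cluster connected
            _add_capsule(lyve, abs_cells[a], abs_cells[b],
                         0.6 * spec.cell_radius, spacing, fg)
        gt.clusters.append(
            GroundTruthCluster(
                centroid=abs_cells.mean(axis=0),
                n_cells=int(n_cells),
                cell_centers=abs_cells,
                contiguous=contiguous,
            )
        )


# ---------------------------------------------------------------------------
# confounders, envelope and noise


def add_confounders_and_noise(
    stack: ChannelStack,
    gt: SyntheticGroundTruth,
    cspec: ConfounderSpec,
    noise_params: NoiseParams,
    seed,
    envelope_center: Optional[np.ndarray] = None,
    envelope_semiaxes: Optional[np.ndarray] = None,
    envelope_intensity: float = 120.0,
    _vessel_distance: Optional[np.ndarray] = None,
) -> None:
    """Add marker-specific confounders, the organ envelope and noise.

    Macrophage blobs (strong, LYVE-1 only) and weak tubular-epithelium
    patches (PROX1 only) are placed clear of the plexus and clusters so
    ground truth stays unambiguous.  An ``AUTOFLUOR`` channel holding an
    ellipsoidal organ envelope is appended and its analytic volume
    (4/3 π abc) recorded.  Poisson noise (if enabled) then Gaussian
    noise is applied to every channel.
    """
    rng_place = np.random.default_rng(np.random.SeedSequence([_seed_int(seed), 0]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([_seed_int(seed), 1]))
    lyve = stack["LYVE1"].data
    prox = stack["PROX1"].data
    spacing = stack.spacing
    sp = np.asarray(spacing, dtype=float)
    fg = gt.foreground

    if _vessel_distance is None:
        _vessel_distance = _surface_distance_fn(lyve > 0, spacing)
    distance_at = _vessel_distance
    cluster_pts = (
        np.concatenate([c.cell_centers for c in gt.clusters])
        if gt.clusters
        else np.zeros((0, 3))
    )
    shape = stack.shape

    placed_confounders: List[Tuple[np.ndarray, float]] = []

    def clear_spot(extent: float) -> np.ndarray:
        for attempt in range(1600):
            idx = np.array([rng_place.integers(2, s - 2) for s in shape])
            p = idx * sp
            margin = 10.0 if attempt < 800 else 4.0
            if float(distance_at(p)[0]) < extent + margin:
                continue
            if len(cluster_pts) and np.min(
                np.linalg.norm(cluster_pts - p, axis=1)
            ) < extent + margin + 5.0:
                continue
            # confounders of different kinds must not overlap each other:
            # a macrophage fused with a weak nuclear patch would fake a
            # dual-positive cluster and corrupt the ground truth
            if any(
                np.linalg.norm(p - q) < extent + e + margin
                for q, e in placed_confounders
            ):
                continue
            if envelope_center is not None:
                rel = (p - envelope_center) / (
                    np.asarray(envelope_semiaxes) - extent - 4.0
                )
                if rel @ rel > 1.0:
                    continue
            placed_confounders.append((p, extent))
            return p
        raise PhantomGeometryError("no free space for confounder placement")

    for _ in range(cspec.n_macrophages):
        r = float(rng_place.uniform(5.0, 9.0))
        p = clear_spot(r)
        _add_sphere(lyve, p, r, spacing, np.uint8(round(fg)))
        gt.confounders.append(Confounder("macrophage", p, (r,)))

    for _ in range(cspec.n_tubule_patches):
        semi = (
            float(rng_place.uniform(6.0, 10.0)),
            float(rng_place.uniform(15.0, 30.0)),
            float(rng_place.uniform(15.0, 30.0)),
        )
        p = clear_spot(max(semi))
        value = np.uint8(round(cspec.intensity_fraction * fg))
        _add_ellipsoid(prox, p, semi, spacing, value)
        gt.confounders.append(Confounder("tubule", p, semi))

    # organ envelope -> AUTOFLUOR channel
    if envelope_center is not None:
        auto = np.zeros(stack.shape, dtype=np.uint8)
        _add_ellipsoid(
            auto, envelope_center, envelope_semiaxes, spacing,
            np.uint8(round(envelope_intensity)),
        )
        stack.channels["AUTOFLUOR"] = VoxelGrid(auto, spacing, dtype_bits=8)
        a, b, c = envelope_semiaxes
        gt.organ_volume = 4.0 / 3.0 * np.pi * float(a) * float(b) * float(c)

    gt.noise_params = noise_params
    if noise_params.poisson_scale > 0 or noise_params.gaussian_sd > 0:
        for name in sorted(stack.channels):
            x = stack.channels[name].data.astype(np.float64)
            if noise_params.poisson_scale > 0:
                s = noise_params.poisson_scale
                x = rng_noise.poisson(x * s) / s
            if noise_params.gaussian_sd > 0:
                x = x + noise_params.gaussian_sd * rng_noise.standard_normal(
                    x.shape, dtype=np.float32
                )
            stack.channels[name] = VoxelGrid(
                np.clip(np.rint(x), 0, 255).astype(np.uint8), spacing, dtype_bits=8
            )


def _seed_int(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    # SeedSequence or similar: derive a stable integer
    return int(np.random.default_rng(seed).integers(0, 2 ** 31 - 1))


# ---------------------------------------------------------------------------
# orchestration


def generate_phantom(config: PhantomConfig, seed: int) -> Tuple[ChannelStack, SyntheticGroundTruth]:
    """Generate a complete phantom stack plus its exact ground truth.

    One global seed expands into fixed per-stage substreams (network,
    nuclei, clusters, confounders/noise), so the result is bit-identical
    for identical ``(config, seed)``.
    """
    ss = np.random.SeedSequence(int(seed))
    s_net, s_nuc, s_clu, s_con = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)]

    fov = config.field_of_view()
    env_c = config.resolved_envelope_center()
    env_s = np.asarray(config.envelope_semiaxes, dtype=float)

    vessels = config.vessels
    if vessels.center is None:
        from dataclasses import replace

        ring_z = env_c[0] - 0.55 * env_s[0]
        vessels = replace(vessels, center=(float(ring_z), float(env_c[1]), float(env_c[2])))

    graph = sample_network(
        vessels, s_net, bounds=(np.zeros(3), fov), envelope=(env_c, env_s)
    )
    lyve, membership = rasterize(graph, config.shape, config.spacing, config.foreground)
    assign_branch_volumes(graph, membership)
    prox, nucleus_centers = place_nuclei(
        graph,
        vessels.nucleus_spacing,
        config.nucleus_radius,
        s_nuc,
        config.shape,
        config.spacing,
        foreground=config.foreground,
    )
    stack = ChannelStack(channels={"PROX1": prox, "LYVE1": lyve})
    gt = SyntheticGroundTruth(
        graph=graph,
        seed=int(seed),
        nucleus_centers=nucleus_centers,
        membership=membership,
        foreground=config.foreground,
    )
    vessel_distance = _surface_distance_fn(membership.labels > 0, config.spacing)
    add_clusters(
        stack, gt, config.clusters, s_clu, envelope=(env_c, env_s),
        _vessel_distance=vessel_distance,
    )
    add_confounders_and_noise(
        stack,
        gt,
        config.confounders,
        config.noise,
        s_con,
        envelope_center=env_c,
        envelope_semiaxes=env_s,
        envelope_intensity=config.envelope_intensity,
        _vessel_distance=vessel_distance,
    )
    return stack, gt
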