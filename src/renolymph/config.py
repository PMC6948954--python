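"""Analysis configuration: every tunable of every stage, with units.

All defaults are stated here once and serialize losslessly to/from
YAML.  Defaults the user did not override are logged at run time by the
pipeline so that every filled-in gap is visible.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = [
    "SegmentationParams",
    "MorphometryParams",
    "ClusterParams",
    "OrganSegmentationParams",
    "AnalysisConfig",
]


@dataclass
class SegmentationParams:
    """Dual-marker segmentation tunables.

    ``despeckle_radius`` is the in-plane median-filter radius in voxels
    (1 -> 3x3 per slice); ``rolling_ball_radius`` is the background-ball
    radius in µm and must exceed the largest true structure;
    ``threshold_method`` is one of li/otsu/triangle/manual.
    """

    despeckle_radius: int = 1  # voxels, in-plane
    unsharp_amount: float = 0.0  # 0 disables sharpening
    unsharp_radius: float = 2.0  # voxels
    rolling_ball_radius: float = 50.0  # µm; 0 disables background subtraction
    threshold_method: str = "robust_otsu"
    robust_percentile: float = 99.0  # used by robust_otsu
    manual_threshold: Optional[float] = None
    connectivity: int = 26  # 6 or 26
    min_component_voxels: int = 10  # suppress shot-noise specks

    def __post_init__(self) -> None:
        if self.threshold_method not in {"li", "otsu", "robust_otsu", "triangle", "manual"}:
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "manual" and self.manual_threshold is None:
            raise ValueError("manual threshold method requires manual_threshold")
        if self.connectivity not in {6, 26}:
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class MorphometryParams:
    """Centerline extraction and branch measurement tunables."""

    prune_spur_factor: float = 2.0  # terminal spurs shorter than factor×local diameter go
    min_spur_length: float = 4.0  # µm, absolute floor for spur pruning
    junction_merge_length: float = 6.0  # µm; junction-junction edges shorter than this merge
    centerline_smoothing: int = 2  # half-window (points) for polyline smoothing; 0 = off
    diameter_bin_edges: Tuple[float, ...] = (20.0, 70.0)  # µm, color-coding bins


@dataclass
class ClusterParams:
    """Isolated-cluster detection and nucleus counting tunables."""

    continuity_radius: float = 5.0  # µm; surface distance below which a component is
    # "contiguous" with the plexus and not a cluster
    nucleus_min_distance: float = 7.0  # µm ≈ endothelial nucleus size
    nucleus_smoothing_sigma: float = 2.0  # µm, Gaussian smoothing before peak finding


@dataclass
class OrganSegmentationParams:
    """Whole-kidney volume estimation tunables.

    ``gaussian_sigma`` is in *pixels* (in-plane convention; the z sigma
    is scaled by the spacing ratio so smoothing is physically isotropic).
    """

    gaussian_sigma: float = 5.0  # pixels, in-plane
    threshold_method: str = "li"
    refine_intermeans: bool = True  # pull the threshold to the blurred edge's half-height
    fill_holes: bool = True
    connectivity: int = 26
    channel: Optional[str] = None  # None -> AUTOFLUOR if present, else smoothed LYVE1


@dataclass
class AnalysisConfig:
    """Full per-kidney analysis configuration."""

    spacing: Tuple[float, float, float] = (2.77, 1.66, 1.66)  # µm (z, y, x)
    nuclear_channel: str = "PROX1"
    cellular_channel: str = "LYVE1"
    organ_channel: Optional[str] = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    clusters: ClusterParams = field(default_factory=ClusterParams)
    organ: OrganSegmentationParams = field(default_factory=OrganSegmentationParams)
    seed: int = 0

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spacing"] = list(d["spacing"])
        d["morphometry"]["diameter_bin_edges"] = list(
            d["morphometry"]["diameter_bin_edges"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        kwargs = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            value = d[f.name]
            if f.name == "spacing":
                value = tuple(value)
            elif f.name == "segmentation":
                value = SegmentationParams(**value)
            elif f.name == "morphometry":
                value = dict(value)
                if "diameter_bin_edges" in value:
                    value["diameter_bin_edges"] = tuple(value["diameter_bin_edges"])
                value = MorphometryParams(**value)
            elif f.name == "clusters":
                value = ClusterParams(**value)
            elif f.name == "organ":
                value = OrganSegmentationParams(**value)
            kwargs[f.name] = value
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls.from_dict(yaml.safe_load(text))

    def content_hash(self) -> str:
        """Stable hash of the configuration for provenance stamps."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def non_default_fields(self) -> dict:
        """Fields differing from package defaults (for run-time logging)."""
        default = AnalysisConfig().to_dict()
        mine = self.to_dict()

        def diff(a, b, prefix=""):
            out = {}
            for k, v in a.items():
                if isinstance(v, dict):
                    out.update(diff(v, b[k], prefix + k + "."))
                elif v != b[k]:
                    out[prefix + k] = v
            return out

        return diff(mine, default)
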