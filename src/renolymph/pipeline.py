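"""End-to-end orchestration: one kidney -> report; many reports -> study.

``run_quantify`` executes preprocess → threshold → colocalize →
largest-component split → skeleton/graph/measurement → cluster
detection and counting → organ volume → normalized metrics, and
assembles a serializable per-kidney report stamped with the config
hash.  ``run_study`` collects reports into a metric table and runs the
group-comparison battery.  Reports contain no timestamps, so rerunning
with identical input and config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .clusters import ClusterSummary, analyze_clusters, summarize_clusters
from .config import AnalysisConfig
from .core import ChannelStack
from .graph import NetworkSummary, VesselGraph
from .morphometry import summarize_network, trace_plexus
from .organ import OrganMetrics, estimate_kidney_volume, normalize_metrics, organ_channel
from .segmentation import segment_lymphatics
from .stats import MetricTable, compare_groups, fold_change

__all__ = ["KidneyReport", "run_quantify", "run_study", "StageError"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class KidneyReport:
    """Per-kidney analysis result with provenance."""

    config_hash: str
    source: str
    network: NetworkSummary
    clusters: ClusterSummary
    organ: OrganMetrics
    qc: Dict = field(default_factory=dict)
    graph: Optional[VesselGraph] = None  # not serialized

    def as_dict(self) -> Dict:
        return {
            "config_hash": self.config_hash,
            "source": self.source,
            "network": self.network.as_dict(),
            "clusters": self.clusters.as_dict(),
            "organ": self.organ.as_dict(),
            "qc": self.qc,
        }

    def metric_rows(self, kidney_id: str, group: str) -> List[tuple]:
        """Long-format rows for the study-level metric table."""
        values = {
            "n_branches": self.network.n_branches,
            "length_range_um": self.network.length_range,
            "max_mean_diameter_um": self.network.max_mean_diameter,
            "total_volume_um3": self.network.total_volume,
            "n_clusters": self.clusters.n_clusters,
            "total_cluster_cells": self.clusters.total_cells,
            "kidney_volume_mm3": self.organ.kidney_volume,
            "branches_per_mm3": self.organ.branches_per_mm3,
            "occupancy_percent": self.organ.occupancy_percent,
        }
        return [(kidney_id, group, k, float(v)) for k, v in values.items()]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, exc) from exc

    return wrap


def run_quantify(
    stack: "ChannelStack | str | Path",
    config: Optional[AnalysisConfig] = None,
    out_dir: Optional[Path] = None,
) -> KidneyReport:
    """Run the full per-kidney analysis.

    ``stack`` is a loaded :class:`ChannelStack` or a path to a
    multi-channel TIFF (channels then named per the config).  When
    ``out_dir`` is given, all artifacts (masks, branch table, SWC,
    report JSON) are written there.
    """
    config = config or AnalysisConfig()
    for key, value in config.non_default_fields().items():
        logger.info("config override: %s = %r", key, value)

    if not isinstance(stack, ChannelStack):
        source = str(stack)
        names = [config.nuclear_channel, config.cellular_channel]
        if config.organ_channel:
            names.append(config.organ_channel)
        stack = _stage("read_stack")(rio.read_stack, stack, names, config.spacing)
    else:
        source = stack.metadata.get("source", "<memory>")

    for required in (config.nuclear_channel, config.cellular_channel):
        if required not in stack:
            raise StageError(
                "input_validation",
                KeyError(f"required channel {required!r} missing from stack"),
            )

    nuclear = stack[config.nuclear_channel]
    cellular = stack[config.cellular_channel]

    coloc, plexus, residual, qc = _stage("segmentation")(
        segment_lymphatics, nuclear, cellular, config.segmentation
    )
    graph = _stage("morphometry")(trace_plexus, plexus, config.morphometry)
    network = summarize_network(graph)
    cluster_set = _stage("clusters")(
        analyze_clusters, residual, plexus, nuclear, config.clusters
    )
    cluster_summary = summarize_clusters(cluster_set)
    grid = organ_channel(stack, config.organ_channel or config.organ.channel)
    kidney_volume, organ_mask = _stage("organ")(
        estimate_kidney_volume, grid, config.organ
    )
    metrics = normalize_metrics(network, kidney_volume)

    qc = dict(qc)
    qc["n_contiguous_components"] = len(cluster_set.excluded)
    qc["defaults_not_overridden"] = sorted(
        set(_all_config_keys(config)) - set(config.non_default_fields())
    )
    report = KidneyReport(
        config_hash=config.content_hash(),
        source=source,
        network=network,
        clusters=cluster_summary,
        organ=metrics,
        qc=qc,
        graph=graph,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rio.write_mask(plexus, out_dir / "plexus_mask.tif")
        rio.write_labels(residual, out_dir / "residual_labels.tif")
        rio.write_mask(organ_mask, out_dir / "organ_mask.tif")
        rio.write_branch_table(graph, out_dir / "branches.csv")
        rio.write_swc(graph, out_dir / "graph.swc")
        rio.write_json(report.as_dict(), out_dir / "report.json")
    return report


def _all_config_keys(config: AnalysisConfig) -> List[str]:
    keys = []

    def walk(d, prefix=""):
        for k, v in d.items():
            if isinstance(v, dict):
                walk(v, prefix + k + ".")
            else:
                keys.append(prefix + k)

    walk(config.to_dict())
    return keys


def run_study(
    reports: "Dict[str, KidneyReport] | str | Path",
    design: Dict[str, str],
    metrics: Optional[Sequence[str]] = None,
    baseline_group: Optional[str] = None,
) -> Dict:
    """Compare per-kidney metrics across groups.

    ``reports`` maps kidney id -> report (or is a directory of
    ``<kidney_id>/report.json``); ``design`` maps kidney id -> group
    label.  For each metric the assumption checks pick the classical or
    Welch path, post hocs run for >= 3 groups, and fold changes are
    reported against ``baseline_group`` (default: first group in the
    design).  Returns a serializable study report.
    """
    if not isinstance(reports, dict):
        root = Path(reports)
        loaded: Dict[str, Dict] = {}
        for sub in sorted(root.iterdir()):
            rp = sub / "report.json"
            if rp.exists():
                loaded[sub.name] = rio.read_json(rp)
        rows = []
        for kid, group in design.items():
            if kid not in loaded:
                raise ValueError(f"no report found for kidney {kid!r}")
            rep = loaded[kid]
            flat = {
                **rep["network"], **rep["clusters"], **rep["organ"],
            }
            flat.pop("size_histogram", None)
            rows.extend((kid, group, k, float(v)) for k, v in flat.items())
    else:
        rows = []
        for kid, group in design.items():
            rows.extend(reports[kid].metric_rows(kid, group))

    table = MetricTable(pd.DataFrame(rows, columns=["kidney_id", "group", "metric", "value"]))
    group_order = list(dict.fromkeys(design.values()))
    if len(group_order) < 2:
        raise ValueError("a study needs at least two groups")
    counts = {g: list(design.values()).count(g) for g in group_order}
    small = [g for g, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"groups with < 2 kidneys: {small}")
    baseline = baseline_group or group_order[0]

    chosen = metrics or table.metrics()
    out: Dict[str, Dict] = {"groups": group_order, "metrics": {}}
    for metric in chosen:
        result = compare_groups(table, metric)
        entry = {
            "statistic_name": result.statistic_name,
            "statistic": result.statistic,
            "df": list(result.df),
            "p_value": result.p_value,
            "tier": result.tier,
            "brown_forsythe_p": result.assumption_report.brown_forsythe[1],
            "fold_changes": {
                g: fold_change(table, metric, baseline, g)
                for g in group_order
                if g != baseline
                and np.asarray(table.groups(metric)[baseline]).mean() != 0
            },
        }
        if result.posthoc is not None:
            entry["posthoc"] = result.posthoc.to_dict(orient="records")
        out["metrics"][metric] = entry
    return out
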