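"""End-to-end orchestration: phantom or user volume -> graph -> topology
report, with optional disector verification and segmentation evaluation.

A run is configured by :class:`RunConfig`, executes the stage chain
preprocess -> skeletonize -> graph -> prune -> topology per subregion,
and writes DOT, VTK, CSV and a JSON summary under one run directory with
a manifest. Runs are deterministic for a given seed: repeated runs
produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import networkx as nx

import capnet
from capnet import disector as dis
from capnet import graphx, synthdata, topo, volio

__all__ = ["RunConfig", "run_pipeline", "compare_groups", "write_comparison_csv"]

logger = logging.getLogger(__name__)

COMPARE_METRICS = ("n_nodes", "n_edges", "n_scl_polygon", "nv_polygon_per_mm3")


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    Exactly one of `input_paths` (existing volumes, one per subregion) or
    `phantom` (lattice phantom parameters) must be given.
    """

    out_dir: str
    input_paths: list[str] = field(default_factory=list)
    spacing_nm: float | None = None
    subregions: list[dict] = field(default_factory=list)  # {"origin_vx": ..., "size_vx": ...}
    phantom: dict | None = None
    fill_holes_mode: str = "full_3d"
    prune_to_fixpoint: bool = True
    dissolve_chains: bool = True
    run_disector: bool = False
    h_dis_um: float = 1.0
    frame_margin_px: int = 0
    seed: int = 0

    def validate(self) -> None:
        if bool(self.input_paths) == bool(self.phantom):
            raise ValueError("config needs exactly one of input_paths or phantom")
        for p in self.input_paths:
            if not os.path.exists(p):
                raise ValueError(f"input path does not exist: {p!r}")
        if self.input_paths and self.spacing_nm is None:
            # spacing may still come from file metadata; checked at read time
            pass


def _config_hash(config: RunConfig) -> str:
    payload = asdict(config)
    payload.pop("out_dir")  # where results land does not change what they are
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_subregion_volumes(config: RunConfig) -> list[volio.VoxelVolume]:
    vols = []
    for path in config.input_paths:
        vol = volio.read_stack(path, spacing_nm=None if config.spacing_nm is None else (config.spacing_nm,) * 3)
        vols.append(vol)
    if config.subregions:
        cut = []
        for vol in vols:
            for sub in config.subregions:
                cut.append(volio.extract_subregion(vol, sub["origin_vx"], sub["size_vx"]))
        vols = cut
    return vols


def _make_phantom_volumes(config: RunConfig):
    p = dict(config.phantom or {})
    rows = int(p.get("rows", 5))
    cols = int(p.get("cols", 5))
    pitch_vx = float(p.get("pitch_vx", 14))
    radius_vx = float(p.get("radius_vx", 2))
    spacing = float(p.get("spacing_nm", 150.0))
    orientation = float(p.get("orientation_deg", 30.0))
    shape = tuple(p.get("volume_shape", _default_phantom_shape(rows, cols, pitch_vx, radius_vx, orientation)))
    spec, gt = synthdata.make_lattice_network(
        rows, cols, pitch_nm=pitch_vx * spacing, orientation_deg=orientation,
        removed_edges=p.get("removed_edges"), jitter_nm=float(p.get("jitter_nm", 0.0)),
        seed=config.seed,
    )
    spec = synthdata.center_network(spec, shape, (spacing,) * 3)
    vol, gt = synthdata.voxelize_network(spec, radius_vx, shape, (spacing,) * 3)
    return [vol], gt


def _default_phantom_shape(rows, cols, pitch_vx, radius_vx, orientation_deg):
    import math

    margin = int(2 * radius_vx + 8)
    ny = int((rows - 1) * pitch_vx * math.cos(math.radians(orientation_deg))) + margin
    nz = int((rows - 1) * pitch_vx * math.sin(math.radians(orientation_deg))) + margin
    nx = int((cols - 1) * pitch_vx) + margin
    return (nz, ny, nx)


def volume_to_graph(
    vol: volio.VoxelVolume,
    fill_holes_mode: str = "full_3d",
    prune_to_fixpoint: bool = True,
    dissolve_chains: bool = True,
) -> nx.MultiGraph:
    """The standard segmentation -> spatial graph chain."""
    vol = volio.fill_holes(vol, mode=fill_holes_mode)
    vol = volio.largest_component(vol)
    skel = graphx.skeletonize(vol)
    g = graphx.build_graph(skel)
    g = graphx.prune_degree_one(g, to_fixpoint=prune_to_fixpoint)
    if dissolve_chains:
        g = graphx.dissolve_degree_two(g)
    return g


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the JSON-serializable summary."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    gt = None
    if config.phantom is not None:
        vols, gt = _make_phantom_volumes(config)
    else:
        vols = _load_subregion_volumes(config)

    graphs = []
    volumes_mm3 = []
    disector_rows = []
    for i, vol in enumerate(vols):
        try:
            g = volume_to_graph(
                vol,
                fill_holes_mode=config.fill_holes_mode,
                prune_to_fixpoint=config.prune_to_fixpoint,
                dissolve_chains=config.dissolve_chains,
            )
        except Exception as exc:
            raise RuntimeError(f"graph extraction failed for subregion {i}: {exc}") from exc
        graphs.append(g)
        volumes_mm3.append(vol.volume_mm3())
        graphx.write_dot(g, os.path.join(config.out_dir, f"subregion_{i}.dot"))
        graphx.write_vtk_polylines(
            g, os.path.join(config.out_dir, f"subregion_{i}.vtk"), spacing_nm=vol.spacing_nm
        )
        if config.run_disector:
            frame = (
                dis.FrameSpec("guarded", config.frame_margin_px)
                if config.frame_margin_px
                else dis.FrameSpec()
            )
            res = dis.disector_estimate(vol, h_dis_um=config.h_dis_um, frame=frame, seed=config.seed)
            res.write_csv(os.path.join(config.out_dir, f"subregion_{i}_disector.csv"))
            disector_rows.append(
                {
                    "subregion": i,
                    "chi_stereol": res.chi_stereol,
                    "nv_stereol_per_mm3": res.nv_stereol_per_mm3,
                    "n_events": res.n_events,
                }
            )

    report = topo.analyze_subregions(graphs, volumes_mm3)
    _write_topology_csv(report, os.path.join(config.out_dir, "topology.csv"))

    summary = {
        "capnet_version": capnet.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_subregions": report.n_subregions,
        "per_subregion": report.to_rows()[: report.n_subregions],
        "mean": report.mean,
        "sd": report.sd,
    }
    if gt is not None:
        summary["ground_truth"] = {
            "n_nodes_true": gt.n_nodes_true,
            "n_edges_true": gt.n_edges_true,
            "n_cycles_true": gt.n_cycles_true,
        }
    if disector_rows:
        summary["disector"] = disector_rows
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    manifest = sorted(
        f for f in os.listdir(config.out_dir) if os.path.isfile(os.path.join(config.out_dir, f))
    )
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump({"files": manifest, "config_hash": summary["config_hash"]}, fh, indent=1)
    logger.info("run complete: %s (config %s)", config.out_dir, summary["config_hash"])
    return summary


def _write_topology_csv(report: topo.TopologyReport, path: str) -> None:
    rows = report.to_rows()
    cols = [
        "subregion",
        "n_nodes",
        "n_edges",
        "chi_graph",
        "n_scl_graph",
        "n_scl_polygon",
        "volume_mm3",
        "nv_polygon_per_mm3",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for row in rows:
            w.writerow({c: _fmt(row.get(c, "")) for c in cols})


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.6g}"
    return v


def compare_groups(reports: dict[str, topo.TopologyReport], pairs: list[tuple[str, str]]) -> list[dict]:
    """Percentage deviation of dataset means for each (reference, comparison) pair.

    Returns one row per pair with percent change for node, edge, loop and
    density means, rounded to 2 decimals as displayed in reports.
    """
    if len(reports) < 2:
        raise ValueError("need at least two dataset reports to compare")
    rows = []
    for ref_key, cmp_key in pairs:
        for key in (ref_key, cmp_key):
            if key not in reports:
                raise KeyError(f"unknown dataset key {key!r}")
        row = {"reference": ref_key, "comparison": cmp_key}
        for m in COMPARE_METRICS:
            row[m + "_pct"] = round(
                topo.percent_change(reports[ref_key].mean[m], reports[cmp_key].mean[m]), 2
            )
        rows.append(row)
    return rows


def write_comparison_csv(rows: list[dict], path: str) -> None:
    cols = ["reference", "comparison"] + [m + "_pct" for m in COMPARE_METRICS]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for row in rows:
            w.writerow(row)
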