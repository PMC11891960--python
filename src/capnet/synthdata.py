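"""Voxelized capillary-network phantoms with exactly known topology.

The real object of interest is a sheet-like mesh of short tube segments
around tissue pillars. The phantoms here are planar lattice networks,
tilted out of the slicing plane, voxelized as unions of cylinders and
node balls, with optional degradations (tube occlusions emulating
blood-cell blockages, enclosed cavities, salt noise). Ground-truth node,
edge and cycle counts are carried alongside so downstream graph and
disector analyses can be validated exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from capnet.volio import VoxelVolume

__all__ = [
    "NetworkSpec",
    "PhantomGroundTruth",
    "make_lattice_network",
    "center_network",
    "voxelize_network",
    "degrade_segmentation",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass
class NetworkSpec:
    """Geometric description of a tube network.

    node_positions are 3D physical coordinates in nm, (z, y, x) order.
    Edges are pairs of node indices; parallel edges and self-loops are
    permitted.
    """

    node_positions: list[tuple[float, float, float]]
    edges: list[tuple[int, int]]
    lattice_dims: tuple[int, int] | None = None
    orientation_deg: float = 0.0
    spacing_nm: float | None = None

    def __post_init__(self) -> None:
        n = len(self.node_positions)
        for a, b in self.edges:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a}, {b}) references a nonexistent node (n={n})")

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(range(len(self.node_positions)))
        for i, (a, b) in enumerate(self.edges):
            g.add_edge(a, b, key=i)
        return g

    def is_connected(self) -> bool:
        g = self.graph()
        return g.number_of_nodes() > 0 and nx.is_connected(g)

    def to_dot(self, path: str) -> None:
        """Serialize as DOT with a pos attribute (x,y,z in nm) per node."""
        lines = ["graph network {"]
        for i, (z, y, x) in enumerate(self.node_positions):
            lines.append(f'  {i} [pos="{x:g},{y:g},{z:g}"];')
        for a, b in self.edges:
            lines.append(f"  {a} -- {b};")
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class PhantomGroundTruth:
    """True topology of a generated phantom plus its degradation log."""

    n_nodes_true: int
    n_edges_true: int
    n_components_true: int
    n_cycles_true: int
    occlusion_events: list[dict] = field(default_factory=list)
    cavity_events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = self.n_edges_true - self.n_nodes_true + self.n_components_true
        if self.n_cycles_true != expected or self.n_cycles_true < 0:
            raise ValueError(
                f"inconsistent ground truth: cycles={self.n_cycles_true}, "
                f"E-V+C={expected}"
            )


def write_ground_truth(gt: PhantomGroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(gt.__dict__, fh, indent=1, sort_keys=True)


def read_ground_truth(path: str) -> PhantomGroundTruth:
    with open(path) as fh:
        return PhantomGroundTruth(**json.load(fh))


def _lattice_edge_list(rows: int, cols: int) -> list[tuple[int, int]]:
    """Deterministic edge order: all horizontal (along cols) row by row,
    then all vertical (along rows)."""
    edges = []
    for r in range(rows):
        for c in range(cols - 1):
            edges.append((r * cols + c, r * cols + c + 1))
    for r in range(rows - 1):
        for c in range(cols):
            edges.append((r * cols + c, (r + 1) * cols + c))
    return edges


def make_lattice_network(
    rows: int,
    cols: int,
    pitch_nm: float,
    removed_edges: list[int] | None = None,
    orientation_deg: float = 30.0,
    jitter_nm: float = 0.0,
    seed: int = 0,
) -> tuple[NetworkSpec, PhantomGroundTruth]:
    """Planar grid network embedded in 3D, tilted about the x axis.

    The default 30 degree tilt keeps every lattice loop transverse to the
    slicing (z) axis, so a disector sweep never meets a loop lying
    entirely within one slice. Ground-truth counts are exact: a full
    rows x cols grid has rows*cols nodes, 2*rows*cols - rows - cols
    edges and (rows-1)*(cols-1) independent cycles.

    `removed_edges` indexes the deterministic edge list (horizontal edges
    row by row, then vertical); a removal set that disconnects the
    lattice is rejected.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must both be >= 2")
    if pitch_nm <= 0:
        raise ValueError("pitch_nm must be > 0")
    removed = sorted(set(int(i) for i in (removed_edges or [])))
    all_edges = _lattice_edge_list(rows, cols)
    for i in removed:
        if not 0 <= i < len(all_edges):
            raise ValueError(f"removed edge id {i} out of range (E={len(all_edges)})")
    edges = [e for i, e in enumerate(all_edges) if i not in removed]

    rng = np.random.default_rng(seed)
    theta = math.radians(orientation_deg)
    positions = []
    for r in range(rows):
        for c in range(cols):
            x = c * pitch_nm
            y = r * pitch_nm
            if jitter_nm > 0:
                jx, jy = rng.uniform(-jitter_nm, jitter_nm, size=2)
                x += jx
                y += jy
            # rotate the sheet plane about the x axis
            positions.append((y * math.sin(theta), y * math.cos(theta), x))

    spec = NetworkSpec(
        node_positions=positions,
        edges=edges,
        lattice_dims=(rows, cols),
        orientation_deg=orientation_deg,
        spacing_nm=pitch_nm,
    )
    if not spec.is_connected():
        raise ValueError(f"removing edges {removed} disconnects the lattice")
    n_nodes = rows * cols
    n_edges = len(edges)
    gt = PhantomGroundTruth(
        n_nodes_true=n_nodes,
        n_edges_true=n_edges,
        n_components_true=1,
        n_cycles_true=n_edges - n_nodes + 1,
    )
    return spec, gt


def center_network(spec: NetworkSpec, volume_shape, spacing_nm) -> NetworkSpec:
    """Translate node positions so the network bounding box is centred in
    a volume of `volume_shape` voxels at `spacing_nm` (z, y, x) spacing."""
    if not spec.node_positions:
        return spec
    pos = np.asarray(spec.node_positions, dtype=float)
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    extent = np.array([(n - 1) * s for n, s in zip(volume_shape, np.broadcast_to(spacing_nm, (3,)))])
    shift = (extent - (hi - lo)) / 2.0 - lo
    shifted = [tuple(p + shift) for p in pos]
    return NetworkSpec(
        shifted, list(spec.edges), spec.lattice_dims, spec.orientation_deg, spec.spacing_nm
    )


def _paint_segment(mask, p0_vx, p1_vx, radius_vx, value=True) -> None:
    """Set all voxels within `radius_vx` of segment p0-p1 (voxel units)."""
    p0 = np.asarray(p0_vx, dtype=float)
    p1 = np.asarray(p1_vx, dtype=float)
    r = float(radius_vx)
    lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(mask.shape) - 1)
    if np.any(hi < lo):
        return
    grids = np.meshgrid(
        *[np.arange(a, b + 1) for a, b in zip(lo, hi)], indexing="ij", sparse=False
    )
    pts = np.stack([g.astype(float) for g in grids], axis=-1)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        dist2 = ((pts - p0) ** 2).sum(axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = ((pts - proj) ** 2).sum(axis=-1)
    sel = dist2 <= r * r
    region = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
    mask[region][sel] = value


def voxelize_network(
    spec: NetworkSpec,
    radius_vx: float,
    volume_shape,
    spacing_nm,
) -> tuple[VoxelVolume, PhantomGroundTruth]:
    """Rasterise a network as the union of tubes of radius `radius_vx`
    around each edge segment plus balls at the nodes.

    Spacing must be isotropic (tube radii are given in voxels). Geometry
    that touches or clips the volume boundary is rejected: downstream
    topology analysis assumes the structure lies strictly inside the
    grid. Positions are mapped to voxel index space by dividing by the
    spacing; use :func:`center_network` to place a network first.
    """
    spacing = np.broadcast_to(np.asarray(spacing_nm, dtype=float), (3,))
    if not np.allclose(spacing, spacing[0]):
        raise ValueError("voxelize_network requires isotropic spacing")
    s = float(spacing[0])
    if radius_vx <= 0:
        raise ValueError("radius_vx must be > 0")
    shape = tuple(int(n) for n in volume_shape)
    mask = np.zeros(shape, dtype=bool)
    pos_vx = [np.asarray(p, dtype=float) / s for p in spec.node_positions]
    margin = radius_vx + 1.0
    for p in pos_vx:
        if np.any(p - margin < 0) or np.any(p + margin > np.array(shape) - 1):
            raise ValueError(
                f"node at voxel position {tuple(np.round(p, 2))} (radius {radius_vx}) "
                f"clips the volume boundary {shape}"
            )
    for p in pos_vx:
        _paint_segment(mask, p, p, radius_vx)
    for a, b in spec.edges:
        _paint_segment(mask, pos_vx[a], pos_vx[b], radius_vx)

    g = spec.graph()
    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
    gt = PhantomGroundTruth(
        n_nodes_true=len(spec.node_positions),
        n_edges_true=len(spec.edges),
        n_components_true=n_comp,
        n_cycles_true=len(spec.edges) - len(spec.node_positions) + n_comp,
    )
    return VoxelVolume(mask.astype(np.uint8), (s, s, s)), gt


def _edge_is_cycle_edge(spec: NetworkSpec, edge_id: int) -> bool:
    """True when removing the edge lowers the cycle rank (i.e. the edge
    is not a graph bridge). Self-loops and parallel edges always are."""
    a, b = spec.edges[edge_id]
    if a == b:
        return True
    g = nx.MultiGraph()
    g.add_nodes_from(range(len(spec.node_positions)))
    for i, (u, v) in enumerate(spec.edges):
        if i != edge_id:
            g.add_edge(u, v)
    return nx.has_path(g, a, b)


def degrade_segmentation(
    volume: VoxelVolume,
    spec: NetworkSpec,
    radius_vx: float,
    occlusions: list[tuple[int, float]] | None = None,
    cavities: list[tuple[tuple[int, int, int], float]] | None = None,
    salt_noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[VoxelVolume, list[dict]]:
    """Apply controlled defects to a voxelized phantom.

    Occlusions carve out the middle `fraction` of a tube (emulating a
    blood cell fully blocking a capillary); the event log records whether
    the occluded edge was a cycle edge, i.e. whether the phantom's cycle
    rank drops by one. Cavities carve enclosed balls (fillable by hole
    filling); a cavity that would not be fully enclosed by foreground is
    rejected. Salt noise flips isolated background voxels to foreground.
    With no degradations requested the volume is returned unchanged.
    """
    fg = volume.require_binary().copy()
    events: list[dict] = []
    s = volume.spacing_nm[0]
    pos_vx = [np.asarray(p, dtype=float) / s for p in spec.node_positions]

    for edge_id, fraction in occlusions or []:
        if not 0 <= edge_id < len(spec.edges):
            raise ValueError(f"occlusion edge id {edge_id} out of range")
        if not 0 < fraction <= 1:
            raise ValueError("occlusion fraction must be in (0, 1]")
        a, b = spec.edges[edge_id]
        p0, p1 = pos_vx[a], pos_vx[b]
        mid = (p0 + p1) / 2.0
        half = (p1 - p0) * (fraction / 2.0)
        # carve slightly beyond the tube radius to guarantee a clean cut
        _paint_segment(fg, mid - half, mid + half, radius_vx + 1.5, value=False)
        events.append(
            {
                "kind": "occlusion",
                "edge_id": int(edge_id),
                "fraction": float(fraction),
                "cycle_edge": _edge_is_cycle_edge(spec, edge_id),
                "expected_cycle_rank_delta": -1 if _edge_is_cycle_edge(spec, edge_id) else 0,
            }
        )

    for center, radius in cavities or []:
        center = np.asarray(center, dtype=float)
        probe = np.zeros_like(fg)
        _paint_segment(probe, center, center, radius + 1.0)
        if not fg[probe].all():
            raise ValueError(
                f"cavity at {tuple(center)} radius {radius} is not fully enclosed "
                "by foreground (it would not be fillable by hole filling)"
            )
        _paint_segment(fg, center, center, radius, value=False)
        events.append(
            {"kind": "cavity", "center_vx": [float(c) for c in center], "radius_vx": float(radius)}
        )

    if salt_noise_rate > 0:
        rng = np.random.default_rng(seed)
        bg = ~fg
        salt = (rng.random(fg.shape) < salt_noise_rate) & bg
        fg |= salt
        events.append({"kind": "salt", "rate": float(salt_noise_rate), "n_voxels": int(salt.sum())})

    return volume.copy_with(fg.astype(volume.data.dtype)), events
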