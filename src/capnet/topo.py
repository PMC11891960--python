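"""Euler number, capillary-loop counts and numerical densities.

For a spatial graph with N_nodes nodes and N_edges edges the Euler
number is chi = N_nodes - N_edges. For a single connected network with
chi <= 0 the number of capillary loops equals |chi| + 1, which coincides
with the size of a cycle basis (the cycle rank E - V + C). Dividing the
loop count by the analysed tissue volume yields the numerical density
reported per mm^3 (displayed as 10^3/mm^3).

The Euler-number route and the cycle-basis route are implemented
independently so that their agreement is a genuine cross-check rather
than a tautology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "TopologyReport",
    "euler_number",
    "scl_from_euler",
    "scl_from_cycle_basis",
    "numerical_density",
    "percent_change",
    "analyze_subregions",
]


def euler_number(n_nodes: int, n_edges: int) -> int:
    """chi = N_nodes - N_edges (may be positive, zero or negative)."""
    if n_nodes < 0 or n_edges < 0:
        raise ValueError("counts must be nonnegative")
    return int(n_nodes) - int(n_edges)


def scl_from_euler(chi: int, n_components: int = 1) -> int:
    """Loop count |chi| + 1 for a single connected network.

    Valid only for one component with chi <= 0: the cycle rank of a
    connected graph is 1 - chi, which equals |chi| + 1 exactly when
    chi <= 0. A tree (chi = +1) has zero loops, not two, so chi > 0 is
    rejected rather than silently mis-counted.
    """
    if n_components != 1:
        raise ValueError(
            f"|chi| + 1 assumes one connected network, got {n_components} components; "
            "use scl_from_cycle_basis for multi-component graphs"
        )
    if chi > 0:
        raise ValueError(
            f"|chi| + 1 assumes chi <= 0 (a connected network with at least one "
            f"loop or exactly tree-plus-one-loop structure); got chi = {chi}"
        )
    return abs(int(chi)) + 1


def scl_from_cycle_basis(graph: nx.MultiGraph) -> int:
    """Cycle rank via a spanning forest: every edge (self-loops and
    parallel edges included) whose endpoints are already connected in the
    growing forest contributes one independent basis cycle.

    Works per component; equals ``scl_from_euler`` on connected graphs
    with chi <= 0.
    """
    parent: dict = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rank = 0
    for u, v in graph.edges(keys=False):
        ru, rv = find(u), find(v)
        if ru == rv:
            rank += 1
        else:
            parent[ru] = rv
    return rank


def numerical_density(n_scl: int, volume_mm3: float) -> float:
    """Loops per mm^3 (tables display this as 10^3/mm^3)."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be > 0")
    return float(n_scl) / float(volume_mm3)


def percent_change(reference: float, comparison: float) -> float:
    """(comparison - reference) / reference * 100."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return (float(comparison) - float(reference)) / float(reference) * 100.0


_METRICS = ("n_nodes", "n_edges", "chi_graph", "n_scl_graph", "n_scl_polygon", "nv_polygon_per_mm3")


@dataclass
class TopologyReport:
    """Per-subregion topology metrics with per-dataset mean and sample SD."""

    n_nodes: list[int]
    n_edges: list[int]
    chi_graph: list[int]
    n_scl_graph: list[int]
    n_scl_polygon: list[int]
    volume_mm3: list[float]
    nv_polygon_per_mm3: list[float]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    @property
    def n_subregions(self) -> int:
        return len(self.n_nodes)

    def to_rows(self) -> list[dict]:
        """One dict per subregion plus a summary row (mean) and an SD row."""
        rows = []
        for i in range(self.n_subregions):
            rows.append(
                {
                    "subregion": str(i),
                    "n_nodes": self.n_nodes[i],
                    "n_edges": self.n_edges[i],
                    "chi_graph": self.chi_graph[i],
                    "n_scl_graph": self.n_scl_graph[i],
                    "n_scl_polygon": self.n_scl_polygon[i],
                    "volume_mm3": self.volume_mm3[i],
                    "nv_polygon_per_mm3": self.nv_polygon_per_mm3[i],
                }
            )
        for label, stats in (("mean", self.mean), ("sd", self.sd)):
            row = {"subregion": label, "volume_mm3": ""}
            for m in _METRICS:
                row[m] = stats[m]
            rows.append(row)
        return rows


def analyze_subregions(graphs: list[nx.MultiGraph], volumes_mm3: list[float]) -> TopologyReport:
    """Compute per-subregion topology metrics and aggregate mean / sample SD.

    Each graph must be a single connected component with chi <= 0 for
    the Euler route; the cycle-basis count is computed independently.
    With a single subregion the SD is reported as 0 with a warning.
    """
    if len(graphs) != len(volumes_mm3):
        raise ValueError("graphs and volumes lists must have equal length")
    if not graphs:
        raise ValueError("at least one subregion is required")
    rep = TopologyReport([], [], [], [], [], [], [])
    for g, v in zip(graphs, volumes_mm3):
        n_nodes = g.number_of_nodes()
        n_edges = g.number_of_edges()
        chi = euler_number(n_nodes, n_edges)
        n_comp = nx.number_connected_components(g)
        rep.n_nodes.append(n_nodes)
        rep.n_edges.append(n_edges)
        rep.chi_graph.append(chi)
        rep.n_scl_graph.append(scl_from_euler(chi, n_comp))
        rep.n_scl_polygon.append(scl_from_cycle_basis(g))
        rep.volume_mm3.append(float(v))
        rep.nv_polygon_per_mm3.append(numerical_density(rep.n_scl_polygon[-1], v))
    n = rep.n_subregions
    if n == 1:
        warnings.warn("single subregion: SD reported as 0", stacklevel=2)
    for m in _METRICS:
        values = np.asarray(getattr(rep, m), dtype=float)
        rep.mean[m] = float(values.mean())
        rep.sd[m] = float(values.std(ddof=1)) if n > 1 else 0.0
    return rep
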