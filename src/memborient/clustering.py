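"""Oligomerisation analytics for multi-copy coarse-grained scenes.

Per frame, protein copies form a contact graph (edge when any particle of
one copy is within a cutoff of any particle of another, minimum image);
clusters are the single-linkage connected components of that graph.
Single linkage over full particle sets — rather than COM–COM distance —
is deliberate: fibril-like end-on chains (tip-to-base contacts) are
exactly the case a COM criterion misses.

Also houses the down/intermediate/up classification of the extracellular
domain by pitch angle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import DEFAULT_CG_CUTOFF_NM, _pairs_within
from .traj_model import Frame, Selection, Trajectory

__all__ = [
    "ClusterPartition",
    "ClusterTimeSeries",
    "IgState",
    "contact_graph",
    "connected_components",
    "cluster_timeseries",
    "classify_ig_state",
    "DEFAULT_STATE_THRESHOLDS",
]

DEFAULT_STATE_THRESHOLDS = (20.0, 60.0)  # degrees; declared defaults, configurable


@dataclass
class ClusterPartition:
    time: float
    assignment: np.ndarray  # copy -> cluster id (id = lowest member index)
    sizes: Counter

    @property
    def n_copies(self) -> int:
        return int(self.assignment.size)

    def __post_init__(self) -> None:
        if sum(k * v for k, v in self.sizes.items()) != self.n_copies:
            raise ValueError("cluster sizes do not partition the copies")


@dataclass
class ClusterTimeSeries:
    partitions: list[ClusterPartition]

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time for p in self.partitions])

    def size_histogram(self) -> pd.DataFrame:
        """Frame × size-class table: number of copies living in clusters of each size."""
        max_size = max(max(p.sizes) for p in self.partitions)
        rows = []
        for p in self.partitions:
            row = {"time_ps": p.time}
            for s in range(1, max_size + 1):
                row[f"in_size_{s}"] = p.sizes.get(s, 0) * s
            rows.append(row)
        return pd.DataFrame(rows)

    def assignments_frame(self) -> pd.DataFrame:
        recs = []
        for p in self.partitions:
            for copy, cid in enumerate(p.assignment):
                recs.append({"time_ps": p.time, "copy": copy, "cluster": int(cid)})
        return pd.DataFrame(recs)


@dataclass(frozen=True)
class IgState:
    state: str  # down | intermediate | up
    pitch: float
    thresholds: tuple = DEFAULT_STATE_THRESHOLDS


def contact_graph(
    frame: Frame, copies: list[Selection], cutoff: float = DEFAULT_CG_CUTOFF_NM
) -> set[tuple[int, int]]:
    """Edges (i, j), i<j, between copies with any particle pair within cutoff."""
    all_idx = np.concatenate([c.atom_indices for c in copies])
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("copy selections overlap")
    copy_of = np.concatenate(
        [np.full(len(c.atom_indices), k, dtype=int) for k, c in enumerate(copies)]
    )
    pts = frame.coordinates[all_idx]
    pairs = _pairs_within(pts, pts, cutoff, frame.box)
    edges = set()
    for i, j in pairs:
        a, b = int(copy_of[i]), int(copy_of[j])
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return edges


def connected_components(
    edges: set[tuple[int, int]], n_copies: int, time: float = 0.0
) -> ClusterPartition:
    """Single-linkage clusters = connected components of the copy graph.

    Cluster ids are deterministic: the lowest member index of the component.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_copies))
    g.add_edges_from(edges)
    assignment = np.empty(n_copies, dtype=int)
    sizes: Counter = Counter()
    for comp in nx.connected_components(g):
        cid = min(comp)
        for node in comp:
            assignment[node] = cid
        sizes[len(comp)] += 1
    return ClusterPartition(time=time, assignment=assignment, sizes=sizes)


def cluster_timeseries(
    traj: Trajectory,
    copies: list[Selection],
    cutoff: float = DEFAULT_CG_CUTOFF_NM,
    smoothing_window: int = 1,
) -> ClusterTimeSeries:
    """Per-frame partitions with optional temporal edge smoothing.

    ``smoothing_window`` > 1 applies a centered majority vote (the boolean
    median) over the window to each copy-pair adjacency series before the
    components are re-derived, suppressing single-frame touch events.
    Window 1 disables smoothing. Copy count is conserved at every frame.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be an odd integer ≥ 1")
    per_frame_edges = [contact_graph(f, copies, cutoff) for f in traj.frames]
    n = len(copies)
    if smoothing_window > 1:
        all_pairs = sorted(set().union(*per_frame_edges)) if per_frame_edges else []
        half = smoothing_window // 2
        T = len(per_frame_edges)
        presence = {
            pair: np.array([pair in e for e in per_frame_edges]) for pair in all_pairs
        }
        smoothed: list[set] = [set() for _ in range(T)]
        for pair, pres in presence.items():
            for t in range(T):
                lo, hi = max(0, t - half), min(T, t + half + 1)
                if pres[lo:hi].sum() * 2 > (hi - lo):
                    smoothed[t].add(pair)
        per_frame_edges = smoothed
    partitions = [
        connected_components(e, n, time=f.time)
        for e, f in zip(per_frame_edges, traj.frames)
    ]
    return ClusterTimeSeries(partitions=partitions)


def classify_ig_state(
    pitch: float, thresholds: tuple[float, float] = DEFAULT_STATE_THRESHOLDS
) -> IgState:
    """Classify the extracellular-domain pitch into down/intermediate/up.

    |pitch| < low → ``down`` (long axis parallel to the membrane plane,
    membrane-bound); low ≤ |pitch| ≤ high → ``intermediate`` (inclusive at
    both bounds); |pitch| > high → ``up`` (pointing away from the membrane,
    crystal-like). Thresholds are package defaults, not literature values.
    """
    low, high = thresholds
    if not low < high:
        raise ValueError("thresholds must satisfy low < high")
    if not -90.0 <= pitch <= 90.0:
        raise ValueError("pitch must lie in [-90, 90] degrees")
    p = abs(pitch)
    if p < low:
        state = "down"
    elif p <= high:
        state = "intermediate"
    else:
        state = "up"
    return IgState(state=state, pitch=pitch, thresholds=(low, high))
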