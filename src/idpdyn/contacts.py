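"""Inter-residue contact detection, occupancy maps, and contact-graph clusters.

A contact exists in a snapshot when the *nearest* distance between atoms
of two different residues is strictly smaller than the cutoff (default
4 Å); first- and second-sequence-neighbor pairs (i, i+1), (i, i+2) are
excluded as uninformative.  Each snapshot's contact set is an undirected
graph (nodes = residues, edges = contacts); its connected components of
at least two residues are the snapshot's *clusters*.  Occupancy is the
fraction of frames a pair is in contact.

Neighbor search uses a KD-tree with an exact strict-< distance filter,
so it is bit-identical to the brute-force all-pairs scan.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .trajectory import Topology, Trajectory, select_atoms

__all__ = [
    "ContactSeries",
    "OccupancyMap",
    "ClusterStats",
    "frame_contacts",
    "contact_series",
    "occupancy_map",
    "per_residue_contact_rate",
    "residue_type_propensity",
    "frame_clusters",
    "cluster_statistics",
    "occupancy_network",
    "write_network",
]

#: contact-count bands (contacts per snapshot); boundary values go up
BAND_EDGES = (0.5, 1.5, 2.0)
BAND_LABELS = ("low", "mid", "high", "very_high")


@dataclass
class ContactSeries:
    """Per-frame residue-pair contact sets (1-based ids, j >= i+3)."""

    frames: list[set[tuple[int, int]]]
    n_residues: int

    def __post_init__(self) -> None:
        for pairs in self.frames:
            for i, j in pairs:
                if j - i < 3:
                    raise ValidationError(f"pair ({i},{j}) is a near sequence neighbor")
                if i < 1 or j > self.n_residues:
                    raise ValidationError(f"pair ({i},{j}) outside 1..{self.n_residues}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class OccupancyMap:
    """Symmetric matrix of pair occupancies in [0, 1]."""

    matrix: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("occupancy matrix must be square")
        self.matrix = m

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ClusterStats:
    """Snapshot-graph cluster statistics pooled over frames.

    ``mean_edge_node_ratio`` is the per-cluster mean of n_edges/n_nodes
    (primary statistic); ``pooled_edge_node_slope`` is the zero-intercept
    regression slope of edges on nodes over all observed clusters, the
    alternative reading of an "average edge-to-node ratio".
    """

    clusters_per_frame: np.ndarray
    size_histogram: pd.DataFrame  # size, count, fraction
    node_edge_counts: pd.DataFrame  # n_nodes, n_edges per observed cluster
    mean_edge_node_ratio: float
    pooled_edge_node_slope: float


def _residue_pairs_from_atoms(atom_pairs: np.ndarray, residue_of: np.ndarray
                              ) -> set[tuple[int, int]]:
    ri = residue_of[atom_pairs[:, 0]]
    rj = residue_of[atom_pairs[:, 1]]
    lo = np.minimum(ri, rj)
    hi = np.maximum(ri, rj)
    keep = hi - lo >= 3
    return set(zip((lo[keep] + 1).tolist(), (hi[keep] + 1).tolist()))


def frame_contacts(
    frame: np.ndarray,
    topology: Topology,
    cutoff: float = 4.0,
    atom_mode: str = "all",
) -> set[tuple[int, int]]:
    """Residue pairs in contact in one frame (strict < cutoff).

    ``atom_mode`` restricts which atoms may form contacts: "all",
    "heavy", or "sidechain" (the side-chain-only variant of the
    analysis).  Pairs are returned 1-based with i < j and j >= i+3.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise ValidationError("frame shape does not match topology atom count")
    subset = select_atoms(topology, atom_mode)
    if subset.size == 0:
        return set()
    coords = frame[subset]
    residue_of = topology.atom_residue_index[subset]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return set()
    # enforce the strict inequality exactly (query_pairs includes r == cutoff)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    pairs = pairs[d < cutoff]
    return _residue_pairs_from_atoms(pairs, residue_of)


def contact_series(
    traj: Trajectory, cutoff: float = 4.0, atom_mode: str = "all"
) -> ContactSeries:
    """Per-frame contact sets for a whole trajectory."""
    frames = [frame_contacts(traj.coordinates[f], traj.topology, cutoff, atom_mode)
              for f in range(traj.n_frames)]
    return ContactSeries(frames=frames, n_residues=traj.topology.n_residues)


def occupancy_map(cs: ContactSeries) -> OccupancyMap:
    """Fraction of frames each pair is in contact, as a symmetric matrix."""
    if cs.n_frames < 1:
        raise ValidationError("need at least one frame")
    counts = np.zeros((cs.n_residues, cs.n_residues))
    for pairs in cs.frames:
        for i, j in pairs:
            counts[i - 1, j - 1] += 1
            counts[j - 1, i - 1] += 1
    return OccupancyMap(matrix=counts / cs.n_frames, n_frames=cs.n_frames)


def per_residue_contact_rate(cs: ContactSeries) -> pd.DataFrame:
    """Contacts per snapshot for each residue, with its occupancy band.

    rate_i = (total pair occurrences involving residue i over all frames)
    / n_frames; each contact counts once for both of its residues.  Bands
    follow the conventional color groups (<0.5, 0.5-1.5, 1.5-2, >=2) with
    boundary values assigned upward.
    """
    if cs.n_frames < 1:
        raise ValidationError("need at least one frame")
    counts = np.zeros(cs.n_residues)
    for pairs in cs.frames:
        for i, j in pairs:
            counts[i - 1] += 1
            counts[j - 1] += 1
    rates = counts / cs.n_frames
    bands = [BAND_LABELS[int(np.searchsorted(BAND_EDGES, r, side="right"))] for r in rates]
    return pd.DataFrame({
        "residue_id": np.arange(1, cs.n_residues + 1),
        "rate": rates,
        "band": bands,
    })


def residue_type_propensity(rates: pd.DataFrame, topology: Topology) -> pd.DataFrame:
    """Contact propensity per residue type: mean and population std over residues.

    Types with a single representative get std 0 and a ``singleton`` flag
    so they can be distinguished from genuinely uniform types.
    """
    if len(rates) != topology.n_residues:
        raise ValidationError("rates must cover every residue of the topology")
    df = rates.copy()
    df["residue_type"] = [topology.residue_names[rid - 1].upper()
                          for rid in df["residue_id"]]
    grouped = df.groupby("residue_type")["rate"]
    out = pd.DataFrame({
        "mean_rate": grouped.mean(),
        "std_rate": grouped.std(ddof=0).fillna(0.0),
        "n_residues": grouped.size(),
    }).reset_index()
    out["singleton"] = out["n_residues"] == 1
    return out.sort_values("residue_type").reset_index(drop=True)


def frame_clusters(
    pairs: set[tuple[int, int]], n_residues: int
) -> list[tuple[frozenset[int], int]]:
    """Connected components (size >= 2) of one snapshot's contact graph.

    Returns (node set, edge count) per cluster; residues touching no
    contact are singletons and are not clusters.
    """
    g = nx.Graph()
    g.add_edges_from(pairs)
    out = []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            out.append((frozenset(int(n) for n in comp),
                        int(g.subgraph(comp).number_of_edges())))
    out.sort(key=lambda c: (-len(c[0]), sorted(c[0])))
    return out


def cluster_statistics(cs: ContactSeries) -> ClusterStats:
    """Pooled cluster-size and edge-vs-node statistics over all frames."""
    if cs.n_frames < 1:
        raise ValidationError("need at least one frame")
    per_frame = []
    sizes: list[int] = []
    node_edge: list[tuple[int, int]] = []
    for pairs in cs.frames:
        clusters = frame_clusters(pairs, cs.n_residues)
        per_frame.append(len(clusters))
        for nodes, n_edges in clusters:
            sizes.append(len(nodes))
            node_edge.append((len(nodes), n_edges))
    size_arr = np.asarray(sizes, dtype=int)
    if size_arr.size:
        uniq, counts = np.unique(size_arr, return_counts=True)
        hist = pd.DataFrame({"size": uniq, "count": counts,
                             "fraction": counts / counts.sum()})
        ne = np.asarray(node_edge, dtype=float)
        ratio = float(np.mean(ne[:, 1] / ne[:, 0]))
        slope = float(np.sum(ne[:, 0] * ne[:, 1]) / np.sum(ne[:, 0] ** 2))
    else:
        hist = pd.DataFrame({"size": [], "count": [], "fraction": []})
        ratio = slope = float("nan")
    return ClusterStats(
        clusters_per_frame=np.asarray(per_frame, dtype=int),
        size_histogram=hist,
        node_edge_counts=pd.DataFrame(node_edge, columns=["n_nodes", "n_edges"]),
        mean_edge_node_ratio=ratio,
        pooled_edge_node_slope=slope,
    )


def occupancy_network(om: OccupancyMap, threshold: float = 0.2
                      ) -> list[tuple[int, int, float]]:
    """Weighted edges (i, j, occupancy) with occupancy strictly above threshold."""
    i_idx, j_idx = np.nonzero(np.triu(om.matrix, k=1) > threshold)
    return [(int(i + 1), int(j + 1), float(om.matrix[i, j]))
            for i, j in zip(i_idx, j_idx)]


def write_network(edges: list[tuple[int, int, float]], edge_list_path: str | Path,
                  graphml_path: str | Path | None = None) -> None:
    """Export a weighted contact network as plain edge list and GraphML."""
    with open(edge_list_path, "w") as fh:
        fh.write("# residue_i residue_j occupancy\n")
        for i, j, w in edges:
            fh.write(f"{i} {j} {w:.6f}\n")
    if graphml_path is not None:
        g = nx.Graph()
        for i, j, w in edges:
            g.add_edge(i, j, weight=w)
        nx.write_graphml(g, str(graphml_path))
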