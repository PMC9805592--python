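"""Residue-level interface graphs and their HDF5 serialization.

The interface of a two-chain complex is the set of residues having at
least one heavy atom within ``interface_cutoff`` (default 8.5 A) of any
heavy atom of the other chain.  Those contact residues are the nodes.
External edges connect cross-chain node pairs whose minimal heavy-atom
distance is within the interface cutoff; internal edges connect
same-chain node pairs within ``internal_cutoff`` (default 3 A).  All
cutoff comparisons are inclusive (<=).

Because the graph depends only on inter-atomic distances, it is exactly
invariant under rigid transforms of the input coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.spatial import cKDTree

from .errors import NoInterfaceError, SchemaError
from .structure import Structure

NodeKey = tuple[str, int, str, str]  # (chain_id, number, insertion_code, residue name)


@dataclass
class GraphBuildConfig:
    """Distance cutoffs and feature toggles for graph construction.

    interface_cutoff : A, node detection and external edges (default 8.5)
    internal_cutoff  : A, internal edges (default 3.0)
    node_features    : enabled node feature names, in canonical order
    """

    interface_cutoff: float = 8.5
    internal_cutoff: float = 3.0
    node_features: tuple[str, ...] = ("type", "charge", "polarity", "bsa")

    def __post_init__(self) -> None:
        if self.interface_cutoff <= 0 or self.internal_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.internal_cutoff > self.interface_cutoff:
            raise ValueError("internal_cutoff must not exceed interface_cutoff")


@dataclass
class InterfaceGraph:
    """A residue-level interface graph.

    Edges are undirected and stored once with i < j; the per-edge minimal
    heavy-atom distance is kept so the interaction-strength feature can be
    (re)computed without the coordinates.
    """

    id: str
    nodes: list[NodeKey]
    internal_edges: np.ndarray          # (n_int, 2) int, i < j, same chain
    external_edges: np.ndarray          # (n_ext, 2) int, i < j, cross chain
    internal_edge_dist: np.ndarray      # (n_int,) A
    external_edge_dist: np.ndarray      # (n_ext,) A
    node_features: np.ndarray | None = None
    internal_edge_feat: np.ndarray | None = None
    external_edge_feat: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self) -> dict[NodeKey, int]:
        return {k: i for i, k in enumerate(self.nodes)}

    def validate(self) -> None:
        n = self.n_nodes
        for edges, kind in ((self.internal_edges, "internal"), (self.external_edges, "external")):
            if len(edges) == 0:
                continue
            if edges.min() < 0 or edges.max() >= n:
                raise ValueError(f"{kind} edge index out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError(f"{kind} self-edge")
        if len(self.external_edges) == 0:
            raise ValueError("graph must have at least one external edge")


def _chain_arrays(structure: Structure):
    """Flattened heavy-atom coordinates with a residue index per atom."""
    out = {}
    for cid, residues in structure.chains.items():
        coords, res_idx = [], []
        for i, res in enumerate(residues):
            c = res.coords()
            coords.append(c)
            res_idx.extend([i] * len(c))
        out[cid] = (np.vstack(coords), np.array(res_idx), residues)
    return out


def detect_contact_residues(structure: Structure, config: GraphBuildConfig | None = None) -> set[NodeKey]:
    """Residues with a heavy atom within the interface cutoff of the other chain.

    Raises :class:`NoInterfaceError` if no cross-chain atom pair is within
    the cutoff — an empty interface is an error, not an empty graph.
    """
    config = config or GraphBuildConfig()
    if len(structure.chains) != 2:
        raise ValueError(f"{structure.id}: expected exactly two chains, got {len(structure.chains)}")
    (ca, ia, res_a), (cb, ib, res_b) = _chain_arrays(structure).values()
    tree_b = cKDTree(cb)
    pairs = tree_b.query_ball_point(ca, r=config.interface_cutoff)
    contact: set[NodeKey] = set()
    for atom_a, hits in enumerate(pairs):
        if not hits:
            continue
        ra = res_a[ia[atom_a]]
        contact.add((ra.chain_id, ra.number, ra.insertion_code, ra.name))
        for atom_b in hits:
            rb = res_b[ib[atom_b]]
            contact.add((rb.chain_id, rb.number, rb.insertion_code, rb.name))
    if not contact:
        raise NoInterfaceError(
            f"{structure.id}: no interface at {config.interface_cutoff} A cutoff")
    return contact


def min_residue_distance(res_a, res_b) -> float:
    """Minimal heavy-atom distance between two residues, in A."""
    ca, cb = res_a.coords(), res_b.coords()
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    return float(d.min())


def build_graph(structure: Structure, config: GraphBuildConfig | None = None) -> InterfaceGraph:
    """Build the interface graph of a two-chain Structure (features unfilled).

    Nodes are the contact residues in deterministic order (chain id, then
    residue number, then insertion code).  A graph with zero internal
    edges is legal; zero external edges is impossible by construction
    (node detection and external edges use the same cutoff).
    """
    config = config or GraphBuildConfig()
    contact = detect_contact_residues(structure, config)
    nodes = sorted(contact, key=lambda k: (k[0], k[1], k[2]))
    res_by_key = {}
    for res in structure.residues():
        res_by_key[(res.chain_id, res.number, res.insertion_code, res.name)] = res

    internal, external = [], []
    internal_d, external_d = [], []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            d = min_residue_distance(res_by_key[nodes[i]], res_by_key[nodes[j]])
            same_chain = nodes[i][0] == nodes[j][0]
            if same_chain and d <= config.internal_cutoff:
                internal.append((i, j))
                internal_d.append(d)
            elif not same_chain and d <= config.interface_cutoff:
                external.append((i, j))
                external_d.append(d)

    graph = InterfaceGraph(
        id=structure.id,
        nodes=nodes,
        internal_edges=np.array(internal, dtype=np.int64).reshape(-1, 2),
        external_edges=np.array(external, dtype=np.int64).reshape(-1, 2),
        internal_edge_dist=np.array(internal_d, dtype=float),
        external_edge_dist=np.array(external_d, dtype=float),
        metadata={
            "chain_ids": list(structure.chain_ids),
            "interface_cutoff": config.interface_cutoff,
            "internal_cutoff": config.internal_cutoff,
        },
    )
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# HDF5 storage.  One group per graph named by id:
#   node_keys            (n, 4) string
#   node_features        (n, F) float
#   internal_edge_index  (n_int, 2) int      external_edge_index (n_ext, 2)
#   internal_edge_dist   (n_int,) float      external_edge_dist  (n_ext,)
#   internal_edge_feat   (n_int,) float      external_edge_feat  (n_ext,)
#   target/<name>        scalar
# Attributes: feature_names, chain_ids, cutoffs.
# ---------------------------------------------------------------------------

def write_hdf5(graphs, path, targets: dict | None = None) -> None:
    """Serialize graphs (and optional per-graph targets) to an HDF5 file."""
    ids = [g.id for g in graphs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate graph ids")
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as fh:
        for g in graphs:
            grp = fh.create_group(g.id)
            grp.create_dataset("node_keys",
                               data=np.array([[k[0], str(k[1]), k[2], k[3]] for k in g.nodes],
                                             dtype=object), dtype=str_dt)
            grp.create_dataset("internal_edge_index", data=g.internal_edges)
            grp.create_dataset("external_edge_index", data=g.external_edges)
            grp.create_dataset("internal_edge_dist", data=g.internal_edge_dist)
            grp.create_dataset("external_edge_dist", data=g.external_edge_dist)
            if g.node_features is not None:
                grp.create_dataset("node_features", data=g.node_features)
            if g.internal_edge_feat is not None:
                grp.create_dataset("internal_edge_feat", data=g.internal_edge_feat)
            if g.external_edge_feat is not None:
                grp.create_dataset("external_edge_feat", data=g.external_edge_feat)
            grp.attrs["feature_names"] = [str(s) for s in g.feature_names]
            grp.attrs["chain_ids"] = [str(s) for s in g.metadata.get("chain_ids", [])]
            grp.attrs["interface_cutoff"] = g.metadata.get("interface_cutoff", np.nan)
            grp.attrs["internal_cutoff"] = g.metadata.get("internal_cutoff", np.nan)
            tgt = grp.create_group("target")
            record = (targets or {}).get(g.id)
            if record is not None:
                for name, value in _target_scalars(record).items():
                    tgt.create_dataset(name, data=value)


def _target_scalars(record) -> dict[str, float]:
    if isinstance(record, dict):
        return {k: float(v) for k, v in record.items()}
    return {k: float(v) for k, v in record.as_scalars().items()}


def _read_group(grp, gid: str) -> tuple[InterfaceGraph, dict]:
    required = {"node_keys", "internal_edge_index", "external_edge_index",
                "internal_edge_dist", "external_edge_dist"}
    missing = required - set(grp)
    if missing:
        raise SchemaError(f"group {gid!r}: missing datasets {sorted(missing)}")
    keys_raw = grp["node_keys"].asstr()[()]
    nodes = [(str(c), int(n), str(i), str(r)) for c, n, i, r in keys_raw]
    feats = grp["node_features"][()] if "node_features" in grp else None
    if feats is not None and feats.ndim != 2:
        raise SchemaError(f"group {gid!r}: node_features must be 2-D")
    if feats is not None and feats.shape[0] != len(nodes):
        raise SchemaError(f"group {gid!r}: node_features rows != node count")
    graph = InterfaceGraph(
        id=gid,
        nodes=nodes,
        internal_edges=grp["internal_edge_index"][()].reshape(-1, 2),
        external_edges=grp["external_edge_index"][()].reshape(-1, 2),
        internal_edge_dist=grp["internal_edge_dist"][()],
        external_edge_dist=grp["external_edge_dist"][()],
        node_features=feats,
        internal_edge_feat=grp["internal_edge_feat"][()] if "internal_edge_feat" in grp else None,
        external_edge_feat=grp["external_edge_feat"][()] if "external_edge_feat" in grp else None,
        feature_names=[str(s) for s in grp.attrs.get("feature_names", [])],
        metadata={
            "chain_ids": [str(s) for s in grp.attrs.get("chain_ids", [])],
            "interface_cutoff": float(grp.attrs.get("interface_cutoff", np.nan)),
            "internal_cutoff": float(grp.attrs.get("internal_cutoff", np.nan)),
        },
    )
    target = {name: float(grp["target"][name][()]) for name in grp.get("target", {})}
    return graph, target


def read_hdf5(path, ids=None) -> tuple[list[InterfaceGraph], dict[str, dict]]:
    """Read graphs back from HDF5; ``ids`` selects a subset (order kept)."""
    graphs, targets = [], {}
    with h5py.File(path, "r") as fh:
        wanted = list(fh) if ids is None else list(ids)
        for gid in wanted:
            if gid not in fh:
                raise KeyError(f"no such graph id in {path}: {gid!r}")
            g, t = _read_group(fh[gid], gid)
            graphs.append(g)
            targets[gid] = t
    return graphs, targets


def list_ids(path) -> list[str]:
    with h5py.File(path, "r") as fh:
        return list(fh)
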