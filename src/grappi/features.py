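"""Node and edge featurization for interface graphs.

Node features (residue level): one-hot residue type (20), formal side-chain
charge at pH 7 (1), one-hot polarity class (4), buried surface area (1);
optionally the 20 PSSM substitution scores, the PSSM information content
and a conservation score (the PSSM score of the residue's own amino acid).
The edge feature is an interaction strength obtained from the minimal
inter-residue heavy-atom distance x (A) as

    e(x) = tanh(-x/2 + 2) + 1

which decreases monotonically from tanh(2)+1 ~ 1.96 at contact to 0 at
long range.  All features depend only on residue identity, sequence
profiles and inter-atomic distances, hence are invariant under rigid
transforms of the coordinates (BSA up to point-sampling tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as bst

from .errors import PssmError
from .graph import GraphBuildConfig, InterfaceGraph, NodeKey
from .structure import CANONICAL_RESIDUES, THREE_TO_ONE, Structure

# --- residue vocabulary -----------------------------------------------------

POLARITY_CLASSES = ("apolar", "polar", "positive", "negative")

#: Polarity class per canonical residue (standard pH-7 chemistry).
RESIDUE_POLARITY: dict[str, str] = {
    "ALA": "apolar", "GLY": "apolar", "ILE": "apolar", "LEU": "apolar",
    "MET": "apolar", "PHE": "apolar", "PRO": "apolar", "TRP": "apolar",
    "VAL": "apolar",
    "ASN": "polar", "CYS": "polar", "GLN": "polar", "HIS": "polar",
    "SER": "polar", "THR": "polar", "TYR": "polar",
    "ARG": "positive", "LYS": "positive",
    "ASP": "negative", "GLU": "negative",
}

#: Formal side-chain charge at pH 7; HIS partially protonated (~+0.1).
RESIDUE_CHARGE: dict[str, float] = {
    **{r: 0.0 for r in CANONICAL_RESIDUES},
    "ARG": 1.0, "LYS": 1.0, "ASP": -1.0, "GLU": -1.0, "HIS": 0.1,
}

_RES_INDEX = {name: i for i, name in enumerate(CANONICAL_RESIDUES)}
_POL_INDEX = {name: i for i, name in enumerate(POLARITY_CLASSES)}

#: Feature blocks in canonical column order, with their widths.
FEATURE_BLOCKS: dict[str, int] = {
    "type": 20, "charge": 1, "polarity": 4, "bsa": 1,
    "pssm": 20, "ic": 1, "conservation": 1,
}


def feature_column_names(enabled: tuple[str, ...]) -> list[str]:
    """Expanded column names for the enabled feature blocks, in order."""
    names: list[str] = []
    for block in FEATURE_BLOCKS:
        if block not in enabled:
            continue
        width = FEATURE_BLOCKS[block]
        if width == 1:
            names.append(block)
        elif block == "type":
            names.extend(f"type_{r}" for r in CANONICAL_RESIDUES)
        elif block == "polarity":
            names.extend(f"polarity_{c}" for c in POLARITY_CLASSES)
        elif block == "pssm":
            names.extend(f"pssm_{r}" for r in CANONICAL_RESIDUES)
    return names


# --- edge feature -----------------------------------------------------------

def edge_strength(x):
    """Interaction strength of an inter-residue distance x (A).

    e(x) = tanh(-x/2 + 2) + 1; strictly decreasing, e(0) ~ 1.96,
    e(4) = 1 exactly, e -> 0 as x grows.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be non-negative")
    return np.tanh(-x / 2.0 + 2.0) + 1.0


# --- per-residue node features ----------------------------------------------

def residue_type_onehot(name: str) -> np.ndarray:
    """One-hot over the 20 canonical residues; all-zero for noncanonical."""
    vec = np.zeros(20)
    idx = _RES_INDEX.get(name)
    if idx is None:
        warnings.warn(f"noncanonical residue {name!r}: zero type vector")
    else:
        vec[idx] = 1.0
    return vec


def residue_charge(name: str) -> float:
    return RESIDUE_CHARGE.get(name, 0.0)


def residue_polarity_onehot(name: str) -> np.ndarray:
    vec = np.zeros(4)
    cls = RESIDUE_POLARITY.get(name)
    if cls is not None:
        vec[_POL_INDEX[cls]] = 1.0
    return vec


# --- buried surface area ----------------------------------------------------

_SASA_POINTS = 100
_SASA_PROBE = 1.4


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Rotate a coordinate set into a molecule-fixed principal-axis frame.

    The sampling grid of the SASA computation is fixed in space, so raw
    point sampling is slightly orientation-dependent.  Aligning the
    molecule to its principal axes first (with signs fixed by odd moments
    of the distribution, which are themselves rotation invariant) makes
    the computed areas invariant under rigid transforms up to float
    precision.
    """
    coords = np.asarray(coords, dtype=float)
    center = coords.mean(axis=0)
    x = coords - center
    _, vecs = np.linalg.eigh(x.T @ x)
    axes = vecs[:, ::-1].T  # descending variance
    for k in range(2):
        skew = np.sum((x @ axes[k]) ** 3)
        if abs(skew) < 1e-8:  # near-symmetric: fall back to another odd moment
            skew = np.sum((x @ axes[k]) * np.sum(x * x, axis=1))
        if skew < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])  # proper rotation by construction
    return x @ axes.T


def _to_atom_array(structure: Structure, chain_ids=None) -> bst.AtomArray:
    chain_ids = chain_ids or structure.chain_ids
    atoms = []
    for cid in chain_ids:
        for res in structure.chains[cid]:
            for a in res.atoms:
                atoms.append((cid, res.number, res.insertion_code, res.name, a))
    arr = bst.AtomArray(len(atoms))
    coords = np.array([a.coord for *_, a in atoms], dtype=float)
    arr.coord = _canonical_orientation(coords).astype(np.float32)
    arr.chain_id = np.array([c for c, *_ in atoms], dtype="U4")
    arr.res_id = np.array([n for _, n, *_ in atoms], dtype=int)
    arr.ins_code = np.array([i for _, _, i, *_ in atoms], dtype="U1")
    arr.res_name = np.array([r for _, _, _, r, _ in atoms], dtype="U5")
    arr.atom_name = np.array([a.name for *_, a in atoms], dtype="U6")
    arr.element = np.array([a.element for *_, a in atoms], dtype="U2")
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    return arr


def _residue_sasa(arr: bst.AtomArray) -> dict[tuple[str, int, str], float]:
    """Per-residue SASA (A^2) by Shrake-Rupley-style point sampling."""
    per_atom = bst.sasa(arr, probe_radius=_SASA_PROBE, point_number=_SASA_POINTS,
                        vdw_radii="Single")
    per_atom = np.nan_to_num(per_atom)
    out: dict[tuple[str, int, str], float] = {}
    for cid, rid, icode, a in zip(arr.chain_id, arr.res_id, arr.ins_code, per_atom):
        key = (str(cid), int(rid), str(icode))
        out[key] = out.get(key, 0.0) + float(a)
    return out


def buried_surface_area_map(structure: Structure) -> dict[tuple[str, int, str], float]:
    """BSA of every residue: isolated-chain SASA minus complex SASA, >= 0."""
    complex_sasa = _residue_sasa(_to_atom_array(structure))
    bsa: dict[tuple[str, int, str], float] = {}
    for cid in structure.chain_ids:
        chain_sasa = _residue_sasa(_to_atom_array(structure, chain_ids=(cid,)))
        for key, free in chain_sasa.items():
            bsa[key] = max(0.0, free - complex_sasa.get(key, 0.0))
    return bsa


def buried_surface_area(structure: Structure, node: NodeKey) -> float:
    """BSA (A^2) of one residue; see :func:`buried_surface_area_map`."""
    key = (node[0], node[1], node[2])
    bsa = buried_surface_area_map(structure)
    if key not in bsa:
        raise KeyError(f"residue {key} not in structure {structure.id}")
    return bsa[key]


# --- PSSM profiles ----------------------------------------------------------

@dataclass
class PssmProfile:
    """Sequence profile of one chain: 20 substitution scores + information
    content per residue, indexed by residue number."""

    chain_id: str
    residue_numbers: list[int]
    residue_codes: list[str]           # 1-letter
    scores: np.ndarray                 # (n, 20), vocabulary order
    information_content: np.ndarray    # (n,)

    def row(self, number: int) -> int:
        try:
            return self.residue_numbers.index(number)
        except ValueError:
            raise PssmError(f"chain {self.chain_id}: no PSSM row for residue {number}")


def parse_pssm(path: str | Path, chain_id: str) -> PssmProfile:
    """Parse a tab-separated per-chain PSSM file.

    Expected columns: residue number, 1-letter residue code, 20 scores in
    canonical vocabulary order, information content; one header line.
    """
    path = Path(path)
    numbers, codes, scores, ic = [], [], [], []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise PssmError(f"{path}: empty PSSM file")
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 23:
            raise PssmError(f"{path}:{lineno}: expected 23 fields, got {len(fields)}")
        try:
            numbers.append(int(fields[0]))
            codes.append(fields[1])
            scores.append([float(v) for v in fields[2:22]])
            ic.append(float(fields[22]))
        except ValueError as exc:
            raise PssmError(f"{path}:{lineno}: {exc}") from exc
    arr = np.array(scores, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise PssmError(f"{path}: non-finite PSSM score")
    return PssmProfile(chain_id, numbers, codes, arr, np.array(ic, dtype=float))


def align_profile(profile: PssmProfile, structure: Structure) -> None:
    """Check the profile covers the chain and residue codes agree."""
    for res in structure.chains[profile.chain_id]:
        idx = profile.row(res.number)
        expected = THREE_TO_ONE.get(res.name, "X")
        found = profile.residue_codes[idx]
        if expected != "X" and found != expected:
            raise PssmError(
                f"chain {profile.chain_id} residue {res.number}: "
                f"PSSM code {found!r} does not match structure {expected!r}")


def conservation_score(profile: PssmProfile, node: NodeKey) -> float:
    """PSSM score of the node's own residue type (diagonal read-out)."""
    idx = profile.row(node[1])
    col = _RES_INDEX.get(node[3])
    if col is None:
        warnings.warn(f"noncanonical residue {node[3]!r}: conservation 0")
        return 0.0
    return float(profile.scores[idx, col])


# --- assembly ---------------------------------------------------------------

def featurize(graph: InterfaceGraph, structure: Structure,
              profiles: dict[str, PssmProfile] | None = None,
              config: GraphBuildConfig | None = None) -> InterfaceGraph:
    """Fill node features and edge interaction strengths in place.

    Column order is fixed: type(20), charge(1), polarity(4), bsa(1),
    pssm(20), ic(1), conservation(1), restricted to the enabled blocks.
    """
    config = config or GraphBuildConfig()
    enabled = tuple(config.node_features)
    unknown = set(enabled) - set(FEATURE_BLOCKS)
    if unknown:
        raise ValueError(f"unknown feature blocks: {sorted(unknown)}")

    needs_pssm = {"pssm", "ic", "conservation"} & set(enabled)
    if needs_pssm:
        profiles = profiles or {}
        for cid in structure.chain_ids:
            if cid not in profiles:
                raise PssmError(f"PSSM features enabled but no profile for chain {cid!r}")
            align_profile(profiles[cid], structure)

    bsa = buried_surface_area_map(structure) if "bsa" in enabled else {}

    rows = []
    for node in graph.nodes:
        cid, number, icode, name = node
        parts = []
        if "type" in enabled:
            parts.append(residue_type_onehot(name))
        if "charge" in enabled:
            parts.append([residue_charge(name)])
        if "polarity" in enabled:
            parts.append(residue_polarity_onehot(name))
        if "bsa" in enabled:
            parts.append([bsa.get((cid, number, icode), 0.0)])
        if "pssm" in enabled:
            prof = profiles[cid]
            parts.append(prof.scores[prof.row(number)])
        if "ic" in enabled:
            prof = profiles[cid]
            parts.append([float(prof.information_content[prof.row(number)])])
        if "conservation" in enabled:
            parts.append([conservation_score(profiles[cid], node)])
        rows.append(np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])
                    if parts else np.zeros(0))

    graph.node_features = np.vstack(rows) if rows else np.zeros((0, 0))
    graph.feature_names = feature_column_names(enabled)
    graph.internal_edge_feat = edge_strength(graph.internal_edge_dist)
    graph.external_edge_feat = edge_strength(graph.external_edge_dist)
    return graph
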