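"""Synthetic two-chain complexes, decoy ensembles and PSSM profiles.

Everything the rest of the package consumes can be generated here, so no
external structure database is needed to exercise the full pipeline.

A reference complex is a pair of idealized extended chains (backbone
N, CA, C, O plus CB except for glycine) running antiparallel-free along
x and facing each other across a small gap in y, with seeded amino-acid
types and a small coordinate jitter.  Decoys are rigid perturbations of
the ligand chain with graded translation/rotation magnitudes, emulating
docking models of decreasing quality; the true transform of every decoy
is recorded.  Synthetic PSSM files bias the own-residue column upward,
as real profiles of conserved positions do.

What this generator does not emulate: side-chain packing, realistic
secondary structure, docking energetics, or sequence-family structure in
the profiles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Atom, CANONICAL_RESIDUES, Residue, Structure, THREE_TO_ONE

#: Per-level rigid perturbation magnitudes: (translation A, rotation deg).
DEFAULT_LEVELS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0), (1.0, 4.0), (2.0, 8.0), (4.0, 16.0), (8.0, 30.0),
)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic complex and its decoy ensemble."""

    n_residues: int = 9
    gap: float = 4.0                # A between facing chains
    jitter: float = 0.15            # A, per-coordinate Gaussian noise
    levels: tuple = DEFAULT_LEVELS
    decoys_per_level: int = 10
    seed: int = 0
    chain_ids: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues per chain")
        if self.gap <= 0 or self.gap > 8.0:
            raise ValueError("gap must keep the chains in interface range")


_CA_SPACING = 3.8  # A between consecutive CA atoms in the extended chain

# local heavy-atom offsets from CA (x along the chain, y toward the partner)
_BACKBONE_OFFSETS = {
    "N": (-1.2, 0.5, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, 0.5, 0.0),
    "O": (1.4, 1.7, 0.0),
    "CB": (0.0, -0.9, 1.2),
}


def _build_chain(chain_id: str, names: list[str], origin: np.ndarray,
                 flip_y: bool, rng: np.random.Generator, jitter: float) -> list[Residue]:
    residues = []
    for i, name in enumerate(names):
        ca = origin + np.array([_CA_SPACING * i, 0.0, 0.0])
        atoms = []
        for atom_name, off in _BACKBONE_OFFSETS.items():
            if atom_name == "CB" and name == "GLY":
                continue
            off = np.array(off)
            if flip_y:
                off = off * np.array([1.0, -1.0, 1.0])
            coord = ca + off + rng.normal(0.0, jitter, size=3)
            atoms.append(Atom(name=atom_name, element=atom_name[0], coord=coord))
        residues.append(Residue(chain_id, i + 1, "", name, atoms))
    return residues


def make_reference_complex(spec: FixtureSpec | None = None,
                           structure_id: str = "ref") -> Structure:
    """Deterministic synthetic two-chain complex with a guaranteed interface.

    The chains face each other CB-to-CB across ``spec.gap`` angstroms, so
    at the default geometry every facing residue pair is a 5 A contact
    and the default 8.5/3.0 A graph cutoffs yield a connected interface.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    cid_a, cid_b = spec.chain_ids
    names_a = [str(rng.choice(CANONICAL_RESIDUES)) for _ in range(spec.n_residues)]
    names_b = [str(rng.choice(CANONICAL_RESIDUES)) for _ in range(spec.n_residues)]
    # chain A CB points to -y/+z, chain B is mirrored so its CB faces back
    sep = spec.gap + 2 * abs(_BACKBONE_OFFSETS["CB"][1])
    chain_a = _build_chain(cid_a, names_a, np.zeros(3), flip_y=False,
                           rng=rng, jitter=spec.jitter)
    chain_b = _build_chain(cid_b, names_b, np.array([0.0, -sep, 0.0]),
                           flip_y=True, rng=rng, jitter=spec.jitter)
    structure = Structure(id=structure_id)
    structure.chains[cid_a] = chain_a
    structure.chains[cid_b] = chain_b
    return structure


@dataclass
class DecoyTransform:
    """Rigid perturbation applied to the ligand chain of one decoy:
    x' = R (x - center) + center + t."""

    decoy_id: str
    level: int
    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray


@dataclass
class DecoySet:
    reference: Structure
    decoys: list[Structure] = field(default_factory=list)
    transforms: list[DecoyTransform] = field(default_factory=list)


def make_decoys(reference: Structure, spec: FixtureSpec | None = None) -> DecoySet:
    """Rigid-perturbation decoy ensemble with graded interface quality.

    Level k applies a rotation of ``spec.levels[k][1]`` degrees about a
    random axis through the ligand centroid plus a ``spec.levels[k][0]`` A
    translation in a random direction.  Level (0, 0) reproduces the
    reference exactly.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed + 1)
    ligand = reference.chain_ids[1]
    lig_coords = np.vstack([r.coords() for r in reference.chains[ligand]])
    center = lig_coords.mean(axis=0)
    out = DecoySet(reference=reference)
    for level, (trans_mag, rot_deg) in enumerate(spec.levels):
        for k in range(spec.decoys_per_level):
            if trans_mag == 0 and rot_deg == 0:
                rot = np.eye(3)
                tvec = np.zeros(3)
            else:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                rot = Rotation.from_rotvec(np.deg2rad(rot_deg) * axis).as_matrix()
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                tvec = trans_mag * direction
            decoy = reference.transform(rot, center - rot @ center + tvec,
                                        chain_id=ligand)
            decoy.id = f"{reference.id}_l{level}_d{k}"
            out.decoys.append(decoy)
            out.transforms.append(DecoyTransform(
                decoy_id=decoy.id, level=level, rotation=rot,
                translation=tvec, center=center))
    return out


def make_pssm(structure: Structure, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write one synthetic PSSM file per chain (<id>.<chain>.pssm).

    Scores are integers in [-4, 4] with the own-residue column shifted by
    +6, so conserved self-substitution dominates the row as in real
    profiles; the information-content column is positive.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    header = ["resnum", "res"] + [THREE_TO_ONE[r] for r in CANONICAL_RESIDUES] + ["ic"]
    paths = {}
    for cid, residues in structure.chains.items():
        path = out_dir / f"{structure.id}.{cid}.pssm"
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for res in residues:
                scores = rng.integers(-4, 5, size=20)
                try:
                    own = CANONICAL_RESIDUES.index(res.name)
                    scores[own] += 6
                except ValueError:
                    pass
                ic = abs(rng.normal(1.5, 0.5)) + 0.1
                row = ([str(res.number), THREE_TO_ONE.get(res.name, "X")]
                       + [str(int(s)) for s in scores] + [f"{ic:.3f}"])
                fh.write("\t".join(row) + "\n")
        paths[cid] = path
    return paths


def write_manifest(decoy_set: DecoySet, path: str | Path) -> None:
    """CSV of the true rigid transform of every decoy."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["decoy_id", "level"]
                        + [f"r{i}{j}" for i in range(3) for j in range(3)]
                        + ["tx", "ty", "tz", "cx", "cy", "cz"])
        for t in decoy_set.transforms:
            writer.writerow([t.decoy_id, t.level]
                            + [f"{v:.6f}" for v in t.rotation.ravel()]
                            + [f"{v:.6f}" for v in t.translation]
                            + [f"{v:.6f}" for v in t.center])


def make_scoring_dataset(n_complexes: int = 16, spec: FixtureSpec | None = None,
                         seed: int = 0, features: tuple[str, ...] | None = None):
    """Featurized decoy graphs with fnat targets for desk-scale training.

    Generates ``n_complexes`` distinct reference complexes (seeded), a
    decoy ensemble per complex, builds and featurizes each decoy's
    interface graph and labels it with fnat against its own reference.
    Returns (samples, fnat_by_id, complex_by_id) where samples are
    network-ready :class:`~grappi.network.GraphSample` objects.
    """
    from .features import featurize
    from .graph import GraphBuildConfig, build_graph
    from .network import to_sample
    from .targets import fnat as fnat_fn

    base = spec or FixtureSpec()
    config = GraphBuildConfig(node_features=features or ("type", "charge", "polarity", "bsa"))
    samples, fnat_by_id, complex_by_id = [], {}, {}
    for c in range(n_complexes):
        cspec = FixtureSpec(
            n_residues=base.n_residues, gap=base.gap, jitter=base.jitter,
            levels=base.levels, decoys_per_level=base.decoys_per_level,
            seed=seed * 10007 + c, chain_ids=base.chain_ids)
        ref = make_reference_complex(cspec, structure_id=f"cplx{c}")
        decoy_set = make_decoys(ref, cspec)
        for decoy in decoy_set.decoys:
            try:
                graph = build_graph(decoy, config)
            except Exception:
                f = fnat_fn(decoy, ref)
                fnat_by_id[decoy.id] = f   # far decoys with no interface
                continue
            featurize(graph, decoy, config=config)
            f = fnat_fn(decoy, ref)
            fnat_by_id[decoy.id] = f
            complex_by_id[decoy.id] = ref.id
            samples.append(to_sample(graph, target=f))
    return samples, fnat_by_id, complex_by_id
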