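"""Docking-quality target values against a reference complex.

Implements the CAPRI-style quality measures used to label docking models:
the fraction of native contacts (fnat), the interface and ligand backbone
RMSDs after least-squares superposition, the four-level CAPRI quality
class, plus label binarization and inverse-frequency class weighting for
imbalanced classification.

Conventions (CAPRI): native contacts are cross-chain residue pairs with
minimal heavy-atom distance <= 5 A; iRMSD interface residues are defined
on the reference at 10 A; backbone atoms are N, CA, C, O; the receptor is
the longer chain (ties: first chain id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .structure import Structure

BACKBONE_ATOMS = ("N", "CA", "C", "O")

CAPRI_CLASSES = ("high", "medium", "acceptable", "incorrect")


@dataclass
class TargetRecord:
    """Ground-truth values of one docking model."""

    fnat: float
    irmsd: float
    lrmsd: float
    capri_class: str
    binary_label: int
    raw: float | None = None

    def as_scalars(self) -> dict[str, float]:
        out = {
            "fnat": self.fnat, "irmsd": self.irmsd, "lrmsd": self.lrmsd,
            "capri_class": float(CAPRI_CLASSES.index(self.capri_class)),
            "binary_label": float(self.binary_label),
        }
        if self.raw is not None:
            out["raw"] = float(self.raw)
        return out


def _residue_pairs_within(structure: Structure, cutoff: float):
    """Cross-chain residue-key pairs with min heavy-atom distance <= cutoff,
    ordered (first chain, second chain)."""
    cid_a, cid_b = structure.chain_ids
    pairs = set()
    for ra in structure.chains[cid_a]:
        ca = ra.coords()
        for rb in structure.chains[cid_b]:
            cb = rb.coords()
            d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=-1)
            if d2.min() <= cutoff * cutoff:
                pairs.add((ra.key, rb.key))
    return pairs


def contact_set(structure: Structure, cutoff: float = 5.0) -> set:
    """Cross-chain residue contacts at the native-contact cutoff (5 A)."""
    if len(structure.chains) != 2:
        raise ValueError("contact_set requires a two-chain structure")
    return _residue_pairs_within(structure, cutoff)


def fnat(model: Structure, reference: Structure, cutoff: float = 5.0) -> float:
    """Fraction of the reference's cross-chain contacts present in the model.

    Bounded in [0, 1]; equals 1 when the model reproduces every native
    contact (in particular for the reference against itself).
    """
    native = contact_set(reference, cutoff)
    if not native:
        raise ValueError(f"{reference.id}: reference has no contacts at {cutoff} A")
    model_contacts = contact_set(model, cutoff)
    return len(model_contacts & native) / len(native)


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of mobile onto target (Kabsch).

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1); apply as ``x @ rotation + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if len(mobile) < 3:
        raise ValueError("need at least 3 atom pairs to superpose")
    sup = SVDSuperimposer()
    sup.set(target, mobile)
    sup.run()
    rot, tran = sup.get_rotran()
    if np.linalg.det(rot) < 0:
        raise ValueError("degenerate geometry: improper rotation")
    return rot, tran, float(sup.get_rms())


def _matched_backbone(model: Structure, reference: Structure, keys):
    """Paired backbone coordinates for residues present in both structures."""
    m_coords, r_coords = [], []
    for key in keys:
        res_m = model.residue(key)
        res_r = reference.residue(key)
        if res_m is None:
            warnings.warn(f"residue {key} missing from model; dropped from RMSD set")
            continue
        for name in BACKBONE_ATOMS:
            cm, cr = res_m.atom_coord(name), res_r.atom_coord(name)
            if cm is not None and cr is not None:
                m_coords.append(cm)
                r_coords.append(cr)
    return np.array(m_coords), np.array(r_coords)


def interface_residues(reference: Structure, cutoff: float = 10.0) -> list:
    """Reference interface residue keys at the iRMSD cutoff (both chains)."""
    pairs = _residue_pairs_within(reference, cutoff)
    keys = {k for pair in pairs for k in pair}
    return sorted(keys)


def irmsd(model: Structure, reference: Structure, interface_cutoff: float = 10.0) -> float:
    """Backbone RMSD over reference-defined interface residues after
    superposing the model interface onto the reference interface."""
    keys = interface_residues(reference, interface_cutoff)
    if not keys:
        raise ValueError(f"{reference.id}: no interface residues at {interface_cutoff} A")
    m, r = _matched_backbone(model, reference, keys)
    if len(m) < 3:
        raise ValueError("interface residues absent from model")
    _, _, rms = superpose(m, r)
    return rms


def _receptor_ligand(structure: Structure) -> tuple[str, str]:
    """Longer chain is the receptor; ties go to the first chain id."""
    cids = structure.chain_ids
    sizes = {c: len(structure.chains[c]) for c in cids}
    receptor = max(cids, key=lambda c: (sizes[c], -cids.index(c)))
    ligand = cids[1] if receptor == cids[0] else cids[0]
    return receptor, ligand


def lrmsd(model: Structure, reference: Structure) -> float:
    """Ligand backbone RMSD after superposition on the receptor backbone.

    The receptor fit removes global rigid motion; the ligand RMSD is then
    computed without further fitting.
    """
    receptor, ligand = _receptor_ligand(reference)
    rec_keys = [r.key for r in reference.chains[receptor]]
    lig_keys = [r.key for r in reference.chains[ligand]]
    m_rec, r_rec = _matched_backbone(model, reference, rec_keys)
    if len(m_rec) < 3:
        raise ValueError("receptor backbone absent from model")
    rot, tran, _ = superpose(m_rec, r_rec)
    m_lig, r_lig = _matched_backbone(model, reference, lig_keys)
    if len(m_lig) == 0:
        raise ValueError("ligand backbone absent from model")
    m_fit = m_lig @ rot + tran
    return float(np.sqrt(np.mean(np.sum((m_fit - r_lig) ** 2, axis=1))))


def capri_class(fnat_value: float, irmsd_value: float, lrmsd_value: float) -> str:
    """CAPRI quality class from fnat and the two RMSDs.

    high:       fnat >= 0.5 and (lrmsd <= 1 or irmsd <= 1)
    medium:     fnat >= 0.3 and (lrmsd <= 5 or irmsd <= 2)
    acceptable: fnat >= 0.1 and (lrmsd <= 10 or irmsd <= 4)
    otherwise incorrect.
    """
    if fnat_value >= 0.5 and (lrmsd_value <= 1.0 or irmsd_value <= 1.0):
        return "high"
    if fnat_value >= 0.3 and (lrmsd_value <= 5.0 or irmsd_value <= 2.0):
        return "medium"
    if fnat_value >= 0.1 and (lrmsd_value <= 10.0 or irmsd_value <= 4.0):
        return "acceptable"
    return "incorrect"


def binarize_fnat(fnat_value: float, threshold: float = 0.3) -> int:
    """1 iff fnat >= threshold (inclusive); acceptable-quality label."""
    return int(fnat_value >= threshold)


def class_weights(labels) -> dict:
    """Weights inversely proportional to class counts, summing to 1."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("class weighting needs at least two classes")
    inv = {c: 1.0 / labels.count(c) for c in classes}
    total = sum(inv.values())
    return {c: w / total for c, w in inv.items()}


def score_model(model: Structure, reference: Structure,
                binarize_threshold: float = 0.3) -> TargetRecord:
    """All docking-quality targets of one model against its reference."""
    f = fnat(model, reference)
    i = irmsd(model, reference)
    l = lrmsd(model, reference)
    return TargetRecord(
        fnat=f, irmsd=i, lrmsd=l,
        capri_class=capri_class(f, i, l),
        binary_label=binarize_fnat(f, binarize_threshold),
    )
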