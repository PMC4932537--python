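"""Pharmacophore feature perception on 3D conformers.

Four feature types are perceived with fixed, documented rules:

* ``ARO`` — centroid of every aromatic ring (SSSR).
* ``HYD`` — centroid of every saturated ring with at most one
  heteroatom; centroid of every aromatic five-membered ring containing
  sulfur (thiazoles act as hydrophobes in this model, so they carry both
  an ARO and a HYD feature at the same centroid); centroid of every
  terminal alkyl chain of two or more carbons.
* ``DON_PROJ`` — a point 2.0 A beyond each N-H / O-H hydrogen along the
  X-H vector, approximating the H-bond acceptor partner's position.
* ``ACC_PROJ`` — a point 2.0 A from each acceptor atom (uncharged N with
  an available lone pair, carbonyl or ether O) along the idealized
  lone-pair bisector (opposite the mean of its bond vectors).

Same-type features closer than 0.5 A are merged at their centroid to
avoid double counting in fused systems.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem import Molecule
from .conformers import Conformer

PROJECTION_DISTANCE = 2.0  # A, inside the canonical 1.8-2.2 H-bond range
MERGE_DISTANCE = 0.5  # A


class FeatureType(str, enum.Enum):
    HYD = "HYD"
    ARO = "ARO"
    DON_PROJ = "DON_PROJ"
    ACC_PROJ = "ACC_PROJ"


PROJECTION_TYPES = (FeatureType.DON_PROJ, FeatureType.ACC_PROJ)


@dataclass(frozen=True)
class FeaturePoint:
    """A typed 3D point with the 0-based atom indices it derives from."""

    type: FeatureType
    position: np.ndarray
    source_atoms: tuple[int, ...]

    def __post_init__(self):
        pos = np.asarray(self.position, float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def is_projection(self) -> bool:
        return self.type in PROJECTION_TYPES


def perceive_rings(mol: Molecule) -> list[tuple[int, ...]]:
    """Smallest set of smallest rings, each an ordered atom cycle."""
    return [tuple(r) for r in Chem.GetSymmSSSR(mol.rdmol)]


def _ring_features(mol: Molecule, xyz: np.ndarray) -> list[FeaturePoint]:
    out = []
    rd = mol.rdmol
    for ring in perceive_rings(mol):
        atoms = [rd.GetAtomWithIdx(i) for i in ring]
        centroid = xyz[list(ring)].mean(axis=0)
        aromatic = all(a.GetIsAromatic() for a in atoms)
        if aromatic:
            out.append(FeaturePoint(FeatureType.ARO, centroid, tuple(ring)))
            if len(ring) == 5 and any(a.GetSymbol() == "S" for a in atoms):
                out.append(FeaturePoint(FeatureType.HYD, centroid, tuple(ring)))
        else:
            # saturated: every ring bond single (exocyclic conjugation,
            # e.g. an N-acyl nitrogen, does not disqualify the ring)
            ring_set = set(ring)
            saturated = all(
                b.GetBondTypeAsDouble() == 1.0
                for b in rd.GetBonds()
                if b.GetBeginAtomIdx() in ring_set
                and b.GetEndAtomIdx() in ring_set
            )
            n_hetero = sum(1 for a in atoms if a.GetSymbol() != "C")
            if saturated and n_hetero <= 1:
                out.append(FeaturePoint(FeatureType.HYD, centroid, tuple(ring)))
    return out


def _alkyl_chain_features(mol: Molecule, xyz: np.ndarray) -> list[FeaturePoint]:
    """HYD at the centroid of each acyclic sp3-carbon component that has a
    terminal carbon and spans >= 2 carbons."""
    rd = mol.rdmol
    is_chain = [
        a.GetSymbol() == "C"
        and not a.GetIsAromatic()
        and not a.IsInRing()
        and a.GetHybridization() == Chem.HybridizationType.SP3
        for a in rd.GetAtoms()
    ]
    seen: set[int] = set()
    out = []
    for start in range(rd.GetNumAtoms()):
        if not is_chain[start] or start in seen:
            continue
        component = []
        stack = [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            component.append(i)
            for nbr in rd.GetAtomWithIdx(i).GetNeighbors():
                j = nbr.GetIdx()
                if is_chain[j] and j not in seen:
                    seen.add(j)
                    stack.append(j)
        has_terminal = any(rd.GetAtomWithIdx(i).GetDegree() == 1 for i in component)
        if len(component) >= 2 and has_terminal:
            component.sort()
            out.append(
                FeaturePoint(FeatureType.HYD, xyz[component].mean(axis=0),
                             tuple(component))
            )
    return out


def _donor_projections(mol: Molecule, coords: np.ndarray) -> list[FeaturePoint]:
    rdh = mol.rdmol_h
    out = []
    for atom in rdh.GetAtoms():
        if atom.GetSymbol() not in ("N", "O"):
            continue
        x = atom.GetIdx()
        for nbr in atom.GetNeighbors():
            if nbr.GetSymbol() != "H":
                continue
            h = nbr.GetIdx()
            vec = coords[h] - coords[x]
            norm = np.linalg.norm(vec)
            if norm < 1e-9:
                continue
            pos = coords[h] + PROJECTION_DISTANCE * vec / norm
            out.append(FeaturePoint(FeatureType.DON_PROJ, pos, (x,)))
    return out


def _is_acceptor(atom: Chem.Atom) -> bool:
    sym = atom.GetSymbol()
    if atom.GetFormalCharge() > 0:
        return False
    if sym == "N":
        # pyrrole-type aromatic N-H/N-R (three connections) donates its
        # lone pair to the ring; trivalent N otherwise keeps one.
        if atom.GetIsAromatic():
            return atom.GetTotalDegree() == 2
        if atom.GetTotalDegree() > 3:
            return False
        # aniline- and amide-type N: lone pair delocalized, not accepting
        for nbr in atom.GetNeighbors():
            if nbr.GetIsAromatic():
                return False
            if nbr.GetSymbol() == "C" and any(
                b.GetBondTypeAsDouble() == 2.0 and
                b.GetOtherAtom(nbr).GetSymbol() in ("O", "N", "S")
                for b in nbr.GetBonds()
            ):
                return False
        return True
    if sym == "O":
        if atom.GetIsAromatic():
            return False
        heavy_nbrs = [n for n in atom.GetNeighbors() if n.GetSymbol() != "H"]
        double_bonded = any(
            b.GetBondTypeAsDouble() == 2.0 for b in atom.GetBonds()
        )
        # carbonyl O, or ether O bridging two heavy atoms
        return double_bonded or (len(heavy_nbrs) == 2 and atom.GetTotalNumHs() == 0)
    return False


def _acceptor_projections(mol: Molecule, coords: np.ndarray) -> list[FeaturePoint]:
    rdh = mol.rdmol_h
    out = []
    for atom in rdh.GetAtoms():
        if atom.GetIdx() >= mol.num_atoms or not _is_acceptor(atom):
            continue
        a = atom.GetIdx()
        vecs = []
        for nbr in atom.GetNeighbors():
            v = coords[nbr.GetIdx()] - coords[a]
            n = np.linalg.norm(v)
            if n > 1e-9:
                vecs.append(v / n)
        if not vecs:
            continue
        direction = -np.sum(vecs, axis=0)
        norm = np.linalg.norm(direction)
        if norm < 1e-6:  # degenerate (e.g. perfectly linear environment)
            continue
        pos = coords[a] + PROJECTION_DISTANCE * direction / norm
        out.append(FeaturePoint(FeatureType.ACC_PROJ, pos, (a,)))
    return out


def _merge_close(features: list[FeaturePoint]) -> list[FeaturePoint]:
    """Merge same-type features closer than MERGE_DISTANCE (centroid,
    union of sources), preserving first-appearance order."""
    merged: list[list[FeaturePoint]] = []
    for f in features:
        for group in merged:
            if group[0].type == f.type and np.linalg.norm(
                group[0].position - f.position
            ) < MERGE_DISTANCE:
                group.append(f)
                break
        else:
            merged.append([f])
    out = []
    for group in merged:
        if len(group) == 1:
            out.append(group[0])
        else:
            pos = np.mean([g.position for g in group], axis=0)
            sources = tuple(sorted({i for g in group for i in g.source_atoms}))
            out.append(FeaturePoint(group[0].type, pos, sources))
    return out


def perceive_features(conf: Conformer) -> list[FeaturePoint]:
    """All pharmacophore feature points of one conformer, rule order
    ARO+ring-HYD, chain-HYD, DON_PROJ, ACC_PROJ, then close-merge."""
    mol = conf.molecule
    coords = conf.coords
    xyz = conf.heavy_coords
    features = (
        _ring_features(mol, xyz)
        + _alkyl_chain_features(mol, xyz)
        + _donor_projections(mol, coords)
        + _acceptor_projections(mol, coords)
    )
    return _merge_close(features)


def planarity_rms(points, *, with_degeneracy: bool = False):
    """RMS distance (A) of four points to their least-squares plane.

    The plane is the principal-axis solution: the RMS equals the square
    root of the smallest eigenvalue of the point covariance.  Collinear
    sets have no unique plane; they return 0 with the degeneracy flag.
    """
    pts = np.asarray(points, float)
    if pts.shape != (4, 3):
        raise ValueError("planarity_rms expects exactly 4 points in 3D")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    eigvals = np.sort(np.linalg.eigvalsh(cov))
    degenerate = eigvals[1] < 1e-12
    rms = 0.0 if degenerate else float(np.sqrt(max(eigvals[0], 0.0)))
    if with_degeneracy:
        return rms, degenerate
    return rms


def features_to_tsv(rows, path: str) -> None:
    """Dump features as TSV: mol id, conformer idx, type, x, y, z,
    semicolon-joined 0-based source atom indices.

    ``rows`` iterates (mol_id, conformer_idx, features).
    """
    with open(path, "w") as fh:
        fh.write("mol_id\tconf_idx\ttype\tx\ty\tz\tsource_atoms\n")
        for mol_id, ci, feats in rows:
            for f in feats:
                src = ";".join(str(i) for i in f.source_atoms)
                x, y, z = f.position
                fh.write(
                    f"{mol_id}\t{ci}\t{f.type.value}\t"
                    f"{x:.4f}\t{y:.4f}\t{z:.4f}\t{src}\n"
                )
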