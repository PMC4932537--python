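"""Conformer ensembles: seeded 3D embedding, torsion-grid sampling,
clash filtering, RMSD deduplication and MMFF94 relaxation.

The ensemble generator is deliberately simple and fully deterministic:
one distance-geometry embedding (RDKit ETKDG, seeded) supplies bond
lengths, angles and ring puckers; diversity comes from enumerating a
torsion grid over the acyclic rotatable bonds.  Candidates with steric
clashes are discarded and the survivors deduplicated by best-fit
heavy-atom RMSD, keep-first in (clash score, enumeration index) order,
capped at the configured conformation limit.  The kept conformers are
then relaxed with MMFF94 under the configured gradient tolerance and
iteration cap, and re-deduplicated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms
from rdkit.Chem.Lipinski import RotatableBondSmarts

from .chem import Molecule
from .errors import EmbeddingError

#: Covalent radii in Angstrom (Cordero et al. consensus values).
COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "S": 1.05, "Cl": 1.02, "Br": 1.20,
}

#: Minimum allowed distance between heavy atoms more than 3 bonds apart.
CLASH_CUTOFF = 1.8  # Angstrom


@dataclass(frozen=True)
class EnsembleConfig:
    """Sampling limits for ensemble generation.

    The numeric defaults (conformation limit 500, rejection limit 100,
    iteration limit 1000, RMS gradient 0.005, MM iteration limit 500)
    mirror the conformational-search settings the model was built under;
    the RMSD deduplication limit defaults to 0.25 A.  ``rms_gradient``
    and ``mm_iteration_limit`` feed the MMFF94 relaxation step (force
    tolerance and iteration cap); set ``relax=False`` to keep raw
    torsion-grid geometries.
    """

    conformation_limit: int = 500
    rmsd_limit: float = 0.25
    iteration_limit: int = 1000
    rejection_limit: int = 100
    rms_gradient: float = 0.005
    mm_iteration_limit: int = 500
    torsion_step_deg: float = 60.0
    relax: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.conformation_limit < 1:
            raise ValueError("conformation_limit must be >= 1")
        for name in ("rmsd_limit", "iteration_limit", "rejection_limit",
                     "rms_gradient", "torsion_step_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Conformer:
    """One 3D geometry of a molecule.

    ``coords`` covers every atom of ``molecule.rdmol_h`` (heavy atoms
    first, hydrogens appended), in Angstrom.  ``clash_score`` sums the
    depth of sub-cutoff contacts between heavy atoms more than three
    bonds apart; 0 means clash-free.
    """

    molecule: Molecule
    coords: np.ndarray = field(compare=False)
    clash_score: float = 0.0

    @property
    def mol_id(self) -> str:
        return self.molecule.id

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[: self.molecule.num_atoms]


def _nonbonded_mask(rdmol_h: Chem.Mol, n_heavy: int) -> np.ndarray:
    """Boolean mask over heavy-atom pairs with path distance > 3 bonds."""
    top = Chem.GetDistanceMatrix(rdmol_h)[:n_heavy, :n_heavy]
    return top > 3


def clash_score(molecule: Molecule, coords: np.ndarray,
                mask: np.ndarray | None = None) -> float:
    """Summed penetration depth (A) of heavy-atom contacts below 1.8 A."""
    n = molecule.num_atoms
    if mask is None:
        mask = _nonbonded_mask(molecule.rdmol_h, n)
    xyz = coords[:n]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    viol = np.where(mask & (d < CLASH_CUTOFF), CLASH_CUTOFF - d, 0.0)
    return float(np.triu(viol, 1).sum())


def mmff_relax(mol: Molecule, coords: np.ndarray,
               max_iterations: int = 500,
               force_tolerance: float = 0.005) -> np.ndarray:
    """Relax one geometry with MMFF94 (UFF fallback when MMFF lacks
    parameters).  Returns the input unchanged on force-field failure."""
    rdmol = Chem.Mol(mol.rdmol_h)
    conf = Chem.Conformer(rdmol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, xyz.tolist())
    rdmol.RemoveAllConformers()
    cid = rdmol.AddConformer(conf, assignId=True)
    try:
        props = AllChem.MMFFGetMoleculeProperties(rdmol)
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(rdmol, props, confId=cid)
        else:
            ff = AllChem.UFFGetMoleculeForceField(rdmol, confId=cid)
        if ff is None:
            return coords
        ff.Initialize()
        ff.Minimize(maxIts=max_iterations, forceTol=force_tolerance)
        return rdmol.GetConformer(cid).GetPositions().copy()
    except Exception:
        return coords


def embed3d(mol: Molecule, seed: int = 0,
            rejection_limit: int = 100, relax: bool = True) -> Conformer:
    """Embed one clash-free 3D conformer (deterministic given seed).

    Runs seeded ETKDG distance-geometry embedding followed by an MMFF94
    relaxation, retrying with derived seeds up to ``rejection_limit``
    times before raising :class:`EmbeddingError`.
    """
    if mol.num_atoms > 200:
        raise EmbeddingError(f"{mol.id}: more than 200 atoms")
    rdmol = Chem.Mol(mol.rdmol_h)
    mask = _nonbonded_mask(mol.rdmol_h, mol.num_atoms)
    for attempt in range(max(1, rejection_limit)):
        params = AllChem.ETKDGv3()
        # randomSeed is int32 in RDKit
        params.randomSeed = int(((seed + 1) * 7919 + attempt) % (2**31 - 1))
        params.useRandomCoords = attempt > 0
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            continue
        coords = rdmol.GetConformer().GetPositions().copy()
        if relax:
            coords = mmff_relax(mol, coords)
        score = clash_score(mol, coords, mask)
        if score == 0.0:
            return Conformer(mol, coords, score)
    raise EmbeddingError(
        f"{mol.id}: embedding failed after {rejection_limit} restarts"
    )


def _rotatable_torsions(rdmol_h: Chem.Mol, n_heavy: int) -> list[tuple[int, int, int, int]]:
    """Dihedral (i,j,k,l) per acyclic rotatable heavy-atom bond.

    Reference atoms are the lowest-index heavy neighbours, so the
    torsion list is a pure function of the molecular graph.
    """
    torsions = []
    for j, k in rdmol_h.GetSubstructMatches(RotatableBondSmarts):
        if j >= n_heavy or k >= n_heavy:
            continue
        j_nbrs = sorted(
            a.GetIdx() for a in rdmol_h.GetAtomWithIdx(j).GetNeighbors()
            if a.GetIdx() != k and a.GetIdx() < n_heavy
        )
        k_nbrs = sorted(
            a.GetIdx() for a in rdmol_h.GetAtomWithIdx(k).GetNeighbors()
            if a.GetIdx() != j and a.GetIdx() < n_heavy
        )
        if not j_nbrs or not k_nbrs:
            continue
        torsions.append((j_nbrs[0], j, k, k_nbrs[0]))
    return torsions


def generate_ensemble(mol: Molecule, cfg: EnsembleConfig | None = None):
    """Build a diverse, clash-free conformer ensemble for one molecule.

    Deterministic given ``cfg.seed``.  The torsion grid is exhaustive
    when its size fits within ``cfg.iteration_limit``; otherwise
    ``iteration_limit`` torsion vectors are drawn from the grid with a
    seeded generator.  Raises :class:`EmbeddingError` if no clash-free
    conformer survives.
    """
    cfg = cfg or EnsembleConfig()
    base = embed3d(mol, cfg.seed, cfg.rejection_limit)
    rdmol = Chem.Mol(mol.rdmol_h)
    conf = Chem.Conformer(rdmol.GetNumAtoms())
    for i, xyz in enumerate(base.coords):
        conf.SetAtomPosition(i, xyz.tolist())
    rdmol.RemoveAllConformers()
    conf_id = rdmol.AddConformer(conf, assignId=True)
    work = rdmol.GetConformer(conf_id)

    mask = _nonbonded_mask(mol.rdmol_h, mol.num_atoms)
    torsions = _rotatable_torsions(mol.rdmol_h, mol.num_atoms)
    offsets = np.arange(0.0, 360.0, cfg.torsion_step_deg)
    # grid is relative to the embedded geometry's dihedrals, so the
    # staggered/planar minima of the embedding are preserved
    base_angles = [
        rdMolTransforms.GetDihedralDeg(work, i, j, k, l)
        for (i, j, k, l) in torsions
    ]
    grids = [a0 + offsets for a0 in base_angles]

    candidates: list[tuple[float, int, np.ndarray]] = [
        (base.clash_score, -1, base.coords)
    ]
    if torsions:
        n_grid = len(offsets) ** len(torsions)
        if n_grid <= cfg.iteration_limit:
            assignments = itertools.product(*grids)
        else:
            rng = np.random.default_rng(cfg.seed)
            draws = rng.integers(0, len(offsets),
                                 size=(cfg.iteration_limit, len(torsions)))
            assignments = (
                tuple(g[c] for g, c in zip(grids, row)) for row in draws
            )
        for idx, assignment in enumerate(assignments):
            for (i, j, k, l), deg in zip(torsions, assignment):
                rdMolTransforms.SetDihedralDeg(work, i, j, k, l, float(deg))
            coords = work.GetPositions().copy()
            score = clash_score(mol, coords, mask)
            if score == 0.0:
                candidates.append((score, idx, coords))

    if not candidates:
        raise EmbeddingError(f"{mol.id}: no clash-free conformer survived")

    candidates.sort(key=lambda c: (c[0], c[1]))
    n_heavy = mol.num_atoms

    def dedup(cands):
        kept_c: list[tuple[float, int, np.ndarray]] = []
        kept_h: list[np.ndarray] = []
        for score, idx, coords in cands:
            heavy = coords[:n_heavy]
            if all(kabsch_rmsd(heavy, prev) >= cfg.rmsd_limit for prev in kept_h):
                kept_c.append((score, idx, coords))
                kept_h.append(heavy)
                if len(kept_c) >= cfg.conformation_limit:
                    break
        return kept_c

    kept = dedup(candidates)
    if cfg.relax:
        relaxed = []
        for order, (score, idx, coords) in enumerate(kept):
            new_coords = mmff_relax(mol, coords, cfg.mm_iteration_limit,
                                    cfg.rms_gradient)
            new_score = clash_score(mol, new_coords, mask)
            if new_score == 0.0:
                relaxed.append((new_score, order, new_coords))
        # minimization can collapse nearby minima onto one another
        kept = dedup(relaxed) or kept

    return ConformerEnsemble(
        mol, tuple(Conformer(mol, coords, score) for score, _i, coords in kept)
    )


@dataclass(frozen=True)
class ConformerEnsemble:
    """Ordered, RMSD-deduplicated conformers of one molecule."""

    molecule: Molecule
    conformers: tuple[Conformer, ...]

    @property
    def mol_id(self) -> str:
        return self.molecule.id

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)


# ---------------------------------------------------------------------------
# Superposition


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Least-squares superposition residual (A) between two point sets.

    Optimal rotation by SVD of the cross-covariance (Kabsch), with the
    determinant correction restricting to proper rotations.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    resid = pc @ rot.T - qc
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return 0.0 if rmsd < 1e-12 else rmsd


def best_fit_rmsd(a, b, atom_map: Sequence[tuple[int, int]] | None = None) -> float:
    """Best-fit RMSD between two conformers (or raw coordinate arrays).

    ``atom_map`` pairs atom indices of ``a`` with atom indices of ``b``;
    by default heavy atoms are matched by index.
    """
    pa = a.heavy_coords if isinstance(a, Conformer) else np.asarray(a, float)
    pb = b.heavy_coords if isinstance(b, Conformer) else np.asarray(b, float)
    if atom_map is not None:
        ia = [i for i, _ in atom_map]
        ib = [j for _, j in atom_map]
        if max(ia, default=-1) >= len(pa) or max(ib, default=-1) >= len(pb):
            raise ValueError("atom map index out of range")
        pa, pb = pa[ia], pb[ib]
    if pa.shape != pb.shape:
        raise ValueError(f"atom count mismatch: {len(pa)} vs {len(pb)}")
    return kabsch_rmsd(pa, pb)


def write_ensemble_sdf(ensembles, path: str) -> None:
    """Write ensembles as a multi-record V2000 SDF, one conformer per
    record, titled ``<molecule id>:<conformer index>``."""
    with open(path, "w") as fh:
        for ens in ensembles:
            for ci, conformer in enumerate(ens):
                rdmol = Chem.Mol(ens.molecule.rdmol_h)
                conf = Chem.Conformer(rdmol.GetNumAtoms())
                for i, xyz in enumerate(conformer.coords):
                    conf.SetAtomPosition(i, xyz.tolist())
                rdmol.RemoveAllConformers()
                rdmol.AddConformer(conf, assignId=True)
                rdmol.SetProp("_Name", f"{ens.mol_id}:{ci}")
                fh.write(Chem.MolToMolBlock(rdmol, kekulize=True))
                fh.write("$$$$\n")
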