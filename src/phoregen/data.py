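"""Compound fixtures and synthetic libraries.

``PAPER_COMPOUNDS`` carries the 16 aminothiazole/aminopyrazole kinase-
inhibitor compounds of the series this package models, each transcribed
by hand from its published IUPAC name to SMILES and stored next to the
published HRMS formula text and calcd [M+H]+ value for auditability.
Two entries (2 and 14) have typos in their *printed formulas*; the
masses printed for them match the structures, and the structure is
treated as ground truth throughout.

``planted_geometry_library`` builds labelled synthetic screening
libraries: actives carry the four rhomb features at known geometry plus
Gaussian positional noise, decoys either lack one required feature or
have one side stretched well outside the model range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import Molecule, parse_smiles
from .features import FeaturePoint, FeatureType

# ---------------------------------------------------------------------------
# The 16-compound fixture series


@dataclass(frozen=True)
class FixtureCompound:
    paper_id: int
    name: str
    smiles: str
    hrms_formula: str  # formula text as printed (may carry a typo)
    hrms_calcd: float  # printed calcd [M+H]+ (Da)
    formula_is_cation: bool  # printed formula refers to the [M+H]+ ion
    printed_formula_typo: bool = False

    def molecule(self) -> Molecule:
        return parse_smiles(self.smiles, mol_id=f"cpd{self.paper_id}")


PAPER_COMPOUNDS: tuple[FixtureCompound, ...] = (
    FixtureCompound(
        1,
        "2-Amino-2-methyl-1-(4-(6-(5-propylthiazole-2-ylamino)pyridin-2-yl)"
        "piperidin-1-yl)propan-1-one hydrochloride",
        "CCCc1cnc(Nc2cccc(C3CCN(C(=O)C(C)(C)N)CC3)n2)s1",
        "C20H30N5OS+", 388.2166, True,
    ),
    FixtureCompound(
        2,
        "(3-Chloro-2-flurophenyl)(3-((4-methylthiazol-2-ylamino)pyrimidin-2-yl)"
        "methyl)pirrolidine-1-yl)methanone",
        "Cc1csc(Nc2ccnc(CC3CCN(C(=O)c4cccc(Cl)c4F)C3)n2)n1",
        "C20H30ClFN5OS+", 432.1056, True, printed_formula_typo=True,
    ),
    FixtureCompound(
        3,
        "2-(Dimethylamino)-1-(4-(6-(5-propylthiazol-2-ylamino)pyridin2-yl)"
        "piperidin-1-yl)ethanone",
        "CCCc1cnc(Nc2cccc(C3CCN(C(=O)CN(C)C)CC3)n2)s1",
        "C20H30N5OS+", 388.2166, True,
    ),
    FixtureCompound(
        4,
        "2-Amino-1-(4-(6-(5-propylthiazol-2-ylamino)pyridin-2-yl)piperidin-1-yl)"
        "ethanone",
        "CCCc1cnc(Nc2cccc(C3CCN(C(=O)CN)CC3)n2)s1",
        "C18H26N5OS+", 360.1853, True,
    ),
    FixtureCompound(
        5,
        "2-(Methylamino)-1-(4-(6-(5-propylthiazol-2-ylamino)pyridin-2-yl)"
        "piperidin-1-yl)ethanone",
        "CCCc1cnc(Nc2cccc(C3CCN(C(=O)CNC)CC3)n2)s1",
        "C19H28N5OS+", 374.2009, True,
    ),
    FixtureCompound(
        6,
        "(R)-2-Amino-1-(4-(6-(5-propylthiazol-2-ylamino)-pyridin-2-yl)"
        "piperidin-1-yl)propan-1-one",
        "CCCc1cnc(Nc2cccc(C3CCN(C(=O)[C@@H](C)N)CC3)n2)s1",
        "C19H28N5OS+", 374.2009, True,
    ),
    FixtureCompound(
        7,
        "2-Amino-1-(4-(4-isopropyl-6-(5-propylthiazol-2-ylamino)pyrimidin-2-yl)"
        "piperidin-1-yl)-2-methylpropan-1-one",
        "CCCc1cnc(Nc2cc(C(C)C)nc(C3CCN(C(=O)C(C)(C)N)CC3)n2)s1",
        "C22H35N6OS+", 431.2588, True,
    ),
    FixtureCompound(
        8,
        "2-Amino-1-(4-(4-ethyl-6-(5-propylthiazol-2-ylamino)pyrimidin-2-yl)"
        "piperidin-1-yl)-2-methylpropan-1-one",
        "CCCc1cnc(Nc2cc(CC)nc(C3CCN(C(=O)C(C)(C)N)CC3)n2)s1",
        "C21H33N6OS+", 417.2431, True,
    ),
    FixtureCompound(
        9,
        "2-Amino-2-methyl-1-(4-(6-(5-phenylthiazol-2-ylamino)pyridine-2-yl)"
        "propan-1-one hydrochloride",
        "NC(C)(C)C(=O)N1CCC(c2cccc(Nc3ncc(-c4ccccc4)s3)n2)CC1",
        "C23H28N5OS+", 422.2009, True,
    ),
    FixtureCompound(
        10,
        "Morpholin-2-yl(4-(6-(5-phenylthiazol-2-ylamino)pyridin-2-yl)"
        "piperidin-1-yl)methanone",
        "O=C(C1CNCCO1)N1CCC(c2cccc(Nc3ncc(-c4ccccc4)s3)n2)CC1",
        "C24H28N5O2S+", 450.1958, True,
    ),
    FixtureCompound(
        11,
        "(3-Chloro-2-fluoro-phenyl)-{4-[4-methyl-6-(5-methyl-thiazol-2-ylamino)-"
        "pyrimidin-2-ylmethyl]-piperidin-1-yl}-methanone",
        "O=C(c1cccc(Cl)c1F)N1CCC(Cc2nc(C)cc(Nc3ncc(C)s3)n2)CC1",
        "C22H23ClFN5OS", 460.1369, False,
    ),
    FixtureCompound(
        12,
        "(3-Chloro-2-fluoro-phenyl)-{4-[4-methyl-6-(thiazol-2-ylamino)-"
        "pyrimidin-2-ylmethyl]-piperidin-1-yl}-methanone",
        "O=C(c1cccc(Cl)c1F)N1CCC(Cc2nc(C)cc(Nc3nccs3)n2)CC1",
        "C21H21ClFN5OS", 446.1212, False,
    ),
    FixtureCompound(
        13,
        "(3-Chloro-2-fluoro-phenyl)-{4-[4-(5-chloro-thiazol-2-ylamino)-6-methyl-"
        "pyrimidin-2-ylmethyl]-piperidin-1-yl}-methanone",
        "O=C(c1cccc(Cl)c1F)N1CCC(Cc2nc(C)cc(Nc3ncc(Cl)s3)n2)CC1",
        "C21H20Cl2FN5OS", 480.0822, False,
    ),
    FixtureCompound(
        14,
        "(3-Chloro-2-fluoro-phenyl)-{4-[4-methyl-6-(2H-pyrazol-3-ylamino)-"
        "pyrimidin-2-ylmethyl]-piperidin-1-yl}-methanone",
        "O=C(c1cccc(Cl)c1F)N1CCC(Cc2nc(C)cc(Nc3cc[nH]n3)n2)CC1",
        "C21H21ClFN6O", 429.1600, False, printed_formula_typo=True,
    ),
    FixtureCompound(
        15,
        "(3-Chloro-2-fluoro-phenyl)-{4-[6-(5-methyl-2H-pyrazol-3-ylamino)-"
        "pyridin-2-ylmethyl]-piperidin-1-yl}-methanone",
        "O=C(c1cccc(Cl)c1F)N1CCC(Cc2cccc(Nc3cc(C)[nH]n3)n2)CC1",
        "C22H23ClFN5O", 428.1648, False,
    ),
    FixtureCompound(
        16,
        "(3-Chloro-2-fluoro-phenyl)-{4-[4-(5-methyl-2H-pyrazol-3-ylamino)-"
        "pyrimidin-2-ylmethyl]-piperidin-1-yl}-methanone",
        "O=C(c1cccc(Cl)c1F)N1CCC(Cc2nccc(Nc3cc(C)[nH]n3)n2)CC1",
        "C21H22ClFN6O", 429.1600, False,
    ),
)


def paper_compounds() -> list[FixtureCompound]:
    """The 16 fixture compounds (ids 1-16) of the inhibitor series."""
    return list(PAPER_COMPOUNDS)


def fixture_molecules() -> list[Molecule]:
    """The fixture compounds parsed into molecules (ids ``cpd1..cpd16``)."""
    return [c.molecule() for c in PAPER_COMPOUNDS]


# ---------------------------------------------------------------------------
# Planted pharmacophore libraries


@dataclass(frozen=True)
class PlantedLibrarySpec:
    """Geometry and composition of a planted screening library."""

    n_actives: int
    n_decoys: int
    side: float = 4.5  # A, rhomb side length
    sigma: float = 0.1  # A, isotropic Gaussian positional noise
    decoy_mode: str = "drop-feature"  # or "stretch-side"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.side <= 10:
            raise ValueError("side must be in (0, 10] A")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.decoy_mode not in ("drop-feature", "stretch-side"):
            raise ValueError(f"unknown decoy mode {self.decoy_mode!r}")


#: Slot-ordered corner types of the planted rhomb.
_CORNER_TYPES = (FeatureType.HYD, FeatureType.HYD,
                 FeatureType.ARO, FeatureType.DON_PROJ)


def rhomb_corners(side: float) -> np.ndarray:
    """A planar square rhomb of the given side: hydrophobes on opposite
    corners (+-x), aromatic at +y, projection at -y."""
    h = side / math.sqrt(2.0)
    return np.array([
        [h, 0.0, 0.0],
        [-h, 0.0, 0.0],
        [0.0, h, 0.0],
        [0.0, -h, 0.0],
    ])


def jitter(points: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Seeded i.i.d. Gaussian noise per coordinate; sigma=0 is identity."""
    points = np.asarray(points, float)
    if sigma == 0:
        return points.copy()
    rng = np.random.default_rng(seed)
    return points + rng.normal(0.0, sigma, size=points.shape)


def _random_rigid_motion(rng: np.random.Generator):
    """Uniform random rotation (QR of a Gaussian matrix) + translation."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return q, t


def _feature_set(points: np.ndarray,
                 types: Sequence[FeatureType]) -> list[FeaturePoint]:
    return [
        FeaturePoint(t, p, (i,)) for i, (t, p) in enumerate(zip(types, points))
    ]


def planted_geometry_library(spec: PlantedLibrarySpec):
    """Labelled synthetic feature-point library.

    Returns ``(entries, labels)`` where entries iterate
    (id, [feature list]) — one feature set per molecule, shaped for
    :func:`phoregen.screen.screen_library` — and ``labels`` maps id to
    True for actives.  Actives embed the four typed rhomb corners with
    noise ``sigma`` under a random rigid motion; decoys lack one
    randomly chosen required feature (``drop-feature``) or have the
    projection corner pulled out so two sides stretch to side+3 A
    (``stretch-side``).  Deterministic per (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    corners = rhomb_corners(spec.side)
    entries = []
    labels: dict[str, bool] = {}

    for i in range(spec.n_actives):
        pts = corners.copy()
        if spec.sigma > 0:
            pts = pts + rng.normal(0.0, spec.sigma, size=pts.shape)
        q, t = _random_rigid_motion(rng)
        pts = pts @ q.T + t
        mol_id = f"A{i:04d}"
        entries.append((mol_id, [_feature_set(pts, _CORNER_TYPES)]))
        labels[mol_id] = True

    for i in range(spec.n_decoys):
        pts = corners.copy()
        if spec.decoy_mode == "drop-feature":
            drop = int(rng.integers(0, 4))
            keep = [k for k in range(4) if k != drop]
            pts = pts[keep]
            types = [_CORNER_TYPES[k] for k in keep]
        else:  # stretch-side: move PROJ so sides 3-4 become side+3
            stretched = spec.side + 3.0
            h = spec.side / math.sqrt(2.0)
            y = math.sqrt(stretched**2 - h**2)
            pts[3] = [0.0, -y, 0.0]
            types = list(_CORNER_TYPES)
        if spec.sigma > 0:
            pts = pts + rng.normal(0.0, spec.sigma, size=pts.shape)
        q, t = _random_rigid_motion(rng)
        pts = pts @ q.T + t
        mol_id = f"D{i:04d}"
        entries.append((mol_id, [_feature_set(pts, types)]))
        labels[mol_id] = False

    return entries, labels
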