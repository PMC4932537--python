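"""Molecular graphs, elemental formulas and exact-mass arithmetic.

The molecular graph itself is an RDKit ``Mol`` wrapped in a thin
:class:`Molecule` that pins the conventions used throughout the package
(0-based atom indices, organic element subset, aromaticity perceived on
parse).  Formula derivation and monoisotopic/[M+H]+ mass arithmetic are
implemented here directly on top of an embedded isotope table, because
4-decimal agreement with published HRMS "Calcd" values is the validation
oracle for the compound fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit import RDLogger

from .errors import ParseError, UnsupportedChargeError, UnsupportedElementError

RDLogger.DisableLog("rdApp.*")

#: Elements the package supports (organic subset of the compound series).
SUPPORTED_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "F", "Cl", "Br"})

#: Monoisotopic masses in Da (IUPAC 2013 atomic-mass evaluation, most
#: abundant isotope of each element).
ISOTOPE_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Br": 78.9183371,
}

PROTON_MASS = 1.00727646688  # Da
ELECTRON_MASS = 0.00054857990  # Da

_SMILES_ALPHABET = set("BCNOSPFIbcnos0123456789[]()=#-+@/\\%Hlr")


@dataclass(frozen=True)
class Molecule:
    """A single-component molecular graph with aromaticity perceived.

    Wraps an RDKit ``Mol`` (implicit hydrogens, no coordinates).  The
    ``atoms``/``bonds`` views expose the plain graph used by reports and
    tests; all atom indices in the package are 0-based RDKit indices.
    """

    id: str
    rdmol: Chem.Mol = field(compare=False)

    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def atoms(self) -> list[tuple[str, int, int]]:
        """(element symbol, formal charge, total H count) per atom."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        """(i, j, order) per bond; aromatic bonds carry order 1.5."""
        out = []
        for b in self.rdmol.GetBonds():
            order = 1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble()
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return out

    @cached_property
    def rdmol_h(self) -> Chem.Mol:
        """Copy with explicit hydrogens appended after the heavy atoms.

        Heavy-atom indices are preserved, so conformer coordinates indexed
        against this molecule line up with ``rdmol`` for indices < num_atoms.
        """
        return Chem.AddHs(self.rdmol)

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


def _check_elements(rdmol: Chem.Mol) -> None:
    for atom in rdmol.GetAtoms():
        if atom.GetSymbol() not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"element {atom.GetSymbol()!r} (atom {atom.GetIdx()}) "
                "is outside the supported set "
                f"{sorted(SUPPORTED_ELEMENTS)}"
            )


def _first_bad_char(text: str) -> int | None:
    for i, ch in enumerate(text):
        if ch not in _SMILES_ALPHABET:
            return i
    return None


def parse_smiles(text: str, mol_id: str = "") -> Molecule:
    """Parse a single-component SMILES string into a :class:`Molecule`.

    Stereo markers are accepted and retained but nothing downstream reads
    them.  Raises :class:`ParseError` naming the offending position for a
    malformed string and :class:`UnsupportedElementError` for elements
    outside the organic subset.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty SMILES string (position 0)")
    if "." in text:
        raise ParseError(
            f"multi-component SMILES not supported (dot at position {text.index('.')})"
        )
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        pos = _first_bad_char(text)
        where = pos if pos is not None else len(text) - 1
        raise ParseError(f"malformed SMILES {text!r} (around position {where})")
    _check_elements(rdmol)
    return Molecule(id=mol_id or text, rdmol=rdmol)


def from_rdkit(rdmol: Chem.Mol, mol_id: str = "") -> Molecule:
    """Wrap a sanitized RDKit Mol (e.g. from an SDF record)."""
    _check_elements(rdmol)
    rdmol = Chem.RemoveHs(rdmol)
    return Molecule(id=mol_id, rdmol=rdmol)


# ---------------------------------------------------------------------------
# Formulas and masses


@dataclass(frozen=True)
class Formula:
    """Elemental composition with a net charge.

    Rendering follows the Hill convention (C, H, then the remaining
    elements alphabetically), which makes the text form unique per counts
    map.
    """

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "counts", {k: int(v) for k, v in self.counts.items() if v}
        )
        for el, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {el}")

    def hill(self) -> str:
        parts = []
        for el in ("C", "H"):
            if el in self.counts:
                n = self.counts[el]
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(k for k in self.counts if k not in ("C", "H")):
            n = self.counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        sign = ""
        if self.charge > 0:
            sign = "+" if self.charge == 1 else f"+{self.charge}"
        elif self.charge < 0:
            sign = "-" if self.charge == -1 else str(self.charge)
        return self.hill() + sign

    def merge(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts, self.charge + other.charge)

    def __add__(self, other: "Formula") -> "Formula":
        return self.merge(other)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string, optionally charge-suffixed (+/-)."""
    text = text.strip()
    charge = 0
    if text.endswith("+"):
        charge, text = 1, text[:-1]
    elif text.endswith("-"):
        charge, text = -1, text[:-1]
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ParseError(f"malformed formula {text!r} (position {pos})")
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPE_MASS:
            raise UnsupportedElementError(f"unknown element {el!r} in formula")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise ParseError(f"malformed formula {text!r} (position {pos})")
    return Formula(counts, charge)


def molecular_formula(mol: Molecule) -> Formula:
    """Elemental formula of a molecule, implicit hydrogens included."""
    counts: dict[str, int] = {}
    charge = 0
    for atom in mol.rdmol.GetAtoms():
        el = atom.GetSymbol()
        counts[el] = counts.get(el, 0) + 1
        nh = atom.GetTotalNumHs()
        if nh:
            counts["H"] = counts.get("H", 0) + nh
        charge += atom.GetFormalCharge()
    return Formula(counts, charge)


def monoisotopic_mass(f: Formula) -> float:
    """Exact mass in Da: sum of isotope masses minus charge * electron mass."""
    total = 0.0
    for el, n in f.counts.items():
        if el not in ISOTOPE_MASS:
            raise UnsupportedElementError(f"no isotope mass for element {el!r}")
        total += n * ISOTOPE_MASS[el]
    return total - f.charge * ELECTRON_MASS

def protonated_mz(f: Formula) -> float:
    """m/z of the [M+H]+ ion under the HRMS "Calcd" convention.

    A neutral formula is protonated (one H added, charge +1); a formula
    already printed as the +1 cation is taken as the ion itself.  Computed
    through the formula arithmetic so that protonating a neutral formula
    and merging an explicit H into a cation agree exactly.
    """
    if f.charge == 0:
        ion = Formula(dict(f.counts), 1).merge(Formula({"H": 1}, 0))
        return monoisotopic_mass(ion)
    if f.charge == 1:
        return monoisotopic_mass(f)
    raise UnsupportedChargeError(
        f"cannot form [M+H]+ for a formula of charge {f.charge:+d}"
    )


# ---------------------------------------------------------------------------
# Library I/O


def _parse_smiles_line(line: str, lineno: int) -> Molecule:
    parts = line.split("\t") if "\t" in line else line.split()
    smi = parts[0]
    mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
    return parse_smiles(smi, mol_id)


def read_library(path: str, fmt: str = "smiles") -> list[Molecule]:
    """Read a molecule library from a SMILES file or an SDF (V2000).

    SMILES files hold one record per line, optionally tab-separated id.
    A truncated or unparsable SDF record raises :class:`ParseError`
    naming the 1-based record index.
    """
    if fmt == "smiles":
        mols = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                mols.append(_parse_smiles_line(line, lineno))
        return mols
    if fmt == "sdf":
        mols = []
        supplier = Chem.SDMolSupplier(path, removeHs=True, sanitize=True)
        for idx, rdmol in enumerate(supplier, start=1):
            if rdmol is None:
                raise ParseError(f"malformed SDF record {idx} in {path}")
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
            mols.append(from_rdkit(rdmol, name or f"mol{idx}"))
        return mols
    raise ValueError(f"unknown library format {fmt!r} (expected smiles or sdf)")


def write_library(mols: Iterable[Molecule], path: str, fmt: str = "smiles") -> None:
    """Write molecules as a SMILES table or a V2000 SDF (2D/no coordinates)."""
    if fmt == "smiles":
        with open(path, "w") as fh:
            for m in mols:
                fh.write(f"{m.to_smiles()}\t{m.id}\n")
        return
    if fmt == "sdf":
        with open(path, "w") as fh:
            for m in mols:
                rdmol = Chem.Mol(m.rdmol)
                rdmol.SetProp("_Name", m.id)
                fh.write(Chem.MolToMolBlock(rdmol, kekulize=True))
                fh.write("$$$$\n")
        return
    raise ValueError(f"unknown library format {fmt!r} (expected smiles or sdf)")
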