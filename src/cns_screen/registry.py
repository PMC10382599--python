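"""Compound identity, formula arithmetic, and the built-in fixture library.

The registry owns three things:

* parsing SMILES into :class:`Compound` records with a canonical SMILES,
  an element-count formula and a molar mass computed from an embedded
  standard atomic-weight table (so the mass arithmetic does not depend on
  any cheminformatics toolkit's internal table);
* batch-scale arithmetic (moles x molar mass x isolated yield);
* the fixture library of benzoyl-phenoxy-acetamide (BPA) candidates
  HR66-HR90, the fenofibrate-family controls, and a reference panel of
  CNS chemotherapy agents.

Only HR67, HR80 and HR89 carry names printed verbatim in the synthesis
methods; the remaining HR structures are representative members of the
stated pyridine classes (regiochemistry inferred, ``provisional=True``)
and are excluded from mass-based checks.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

__all__ = [
    "ATOMIC_WEIGHTS",
    "Compound",
    "BatchSpec",
    "StructureError",
    "parse_structure",
    "parse_formula",
    "formula_mass",
    "molar_mass",
    "isolated_mass",
    "compound_library",
    "get_compound",
    "read_compounds_csv",
    "write_compounds_csv",
    "read_sdf",
    "write_sdf",
]

# IUPAC standard atomic weights (2021, conventional values), g/mol.
# Embedded so molar masses are independent of toolkit versions.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.098, "Ca": 40.078, "Fe": 55.845, "Cu": 63.546, "Zn": 65.38,
    "Se": 78.971, "Br": 79.904, "I": 126.90, "Pt": 195.08,
}


class StructureError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Compound:
    """A registered chemical entity.

    ``formula`` maps element symbol to a positive integer count and
    ``molar_mass`` is its atomic-weight sum in g/mol.  ``role_tag`` is one
    of ``candidate``, ``reference_drug`` or ``control``; ``provisional``
    marks structures inferred from class membership rather than a printed
    name.
    """

    id: str
    smiles: str
    formula: Mapping[str, int]
    molar_mass: float
    name: str = ""
    role_tag: str = "candidate"
    provisional: bool = False

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class BatchSpec:
    """Preparation scale: moles of limiting reagent and isolated yield."""

    compound_id: str
    scale_mol: float
    yield_fraction: float

    def __post_init__(self) -> None:
        if self.scale_mol <= 0:
            raise ValueError(f"scale_mol must be positive, got {self.scale_mol}")
        if not 0.0 <= self.yield_fraction <= 1.0:
            raise ValueError(
                f"yield_fraction must lie in [0, 1], got {self.yield_fraction}"
            )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse ``'C22H19ClN2O3'`` into an element-count dict."""
    counts: Counter[str] = Counter()
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r}")
        pos = m.end()
        counts[m.group(1)] += int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r}")
    return dict(counts)


def _formula_of_mol(mol: Chem.Mol) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for atom in Chem.AddHs(mol).GetAtoms():
        counts[atom.GetSymbol()] += 1
    return dict(counts)


def formula_mass(formula: Mapping[str, int]) -> float:
    """Molar mass of an element-count map from the embedded weight table."""
    if not formula:
        raise ValueError("empty formula")
    mass = 0.0
    for element, count in formula.items():
        try:
            weight = ATOMIC_WEIGHTS[element]
        except KeyError:
            raise KeyError(f"no atomic weight for element {element!r}") from None
        mass += count * weight
    return mass


def molar_mass(c: Compound) -> float:
    """Molar mass (g/mol) of a registered compound."""
    return formula_mass(c.formula)


def parse_structure(
    smiles: str,
    id: str,
    *,
    name: str = "",
    role_tag: str = "candidate",
    provisional: bool = False,
) -> Compound:
    """Parse a SMILES string into a :class:`Compound`.

    The SMILES is canonicalized, the molecular formula is derived by
    explicit atom counting (hydrogens added), and the molar mass is the
    atomic-weight sum of that formula.  Parsing the canonical output again
    yields an equal record.
    """
    if not smiles:
        raise StructureError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"could not parse SMILES {smiles!r} for {id!r}")
    canonical = Chem.MolToSmiles(mol)
    formula = _formula_of_mol(mol)
    return Compound(
        id=id,
        smiles=canonical,
        formula=formula,
        molar_mass=formula_mass(formula),
        name=name,
        role_tag=role_tag,
        provisional=provisional,
    )


def isolated_mass(b: BatchSpec, c: Compound) -> float:
    """Isolated product mass in grams for a batch at the given scale/yield."""
    return b.scale_mol * molar_mass(c) * b.yield_fraction


# ---------------------------------------------------------------------------
# Fixture library
# ---------------------------------------------------------------------------

# Shared BPA acyl fragment: 2-(4-(4-chlorobenzoyl)phenoxy)-2-methylpropanoyl.
_BPA = "CC(C)(Oc1ccc(cc1)C(=O)c1ccc(Cl)cc1)C(=O)"

# id, amide substituent SMILES (appended to the acyl carbonyl as N-R),
# IUPAC name (empty if not printed), expected formula, provisional flag.
# Grouping follows the five designed pyridine classes: direct pyridine,
# methylenepyridine, ethylenepyridine, benzopyridine (quinoline), and
# hydroxypyridine/pyridinone.  Regiochemistry is printed only for HR67,
# HR80 and HR89; all other candidates are representative class members.
_HR_TABLE: list[tuple[str, str, str, str, bool]] = [
    ("HR66", "Nc1ccccn1", "", "C22H19ClN2O3", True),
    ("HR67", "Nc1cccnc1",
     "2-[4-(4-chlorobenzoyl)phenoxy]-2-methyl-N-(pyridin-3-yl)propanamide",
     "C22H19ClN2O3", False),
    ("HR68", "Nc1ccncc1", "", "C22H19ClN2O3", True),
    ("HR69", "Nc1ccc(C)nc1", "", "C23H21ClN2O3", True),
    ("HR70", "Nc1ccc(cn1)C", "", "C23H21ClN2O3", True),
    ("HR71", "NCc1ccccn1", "", "C23H21ClN2O3", True),
    ("HR72", "NCc1cccnc1", "", "C23H21ClN2O3", True),
    ("HR73", "NCc1ccncc1", "", "C23H21ClN2O3", True),
    ("HR74", "NCc1ccc(C)nc1", "", "C24H23ClN2O3", True),
    ("HR75", "NCc1cc(C)ccn1", "", "C24H23ClN2O3", True),
    ("HR76", "NCc1cccc(C)n1", "", "C24H23ClN2O3", True),
    ("HR77", "N(C)Cc1ccncc1", "", "C24H23ClN2O3", True),
    ("HR78", "NCCc1ccccn1", "", "C24H23ClN2O3", True),
    ("HR79", "NCCc1cccnc1", "", "C24H23ClN2O3", True),
    ("HR80", "NCCc1ccncc1",
     "2-(4-(4-chlorobenzoyl)phenoxy)-2-methyl-N-(2-(pyridin-4-yl)ethyl)propanamide",
     "C24H23ClN2O3", False),
    ("HR81", "Nc1ccc2ccccc2n1", "", "C26H21ClN2O3", True),
    ("HR82", "Nc1cnc2ccccc2c1", "", "C26H21ClN2O3", True),
    ("HR83", "Nc1ccc2cccnc2c1", "", "C26H21ClN2O3", True),
    ("HR84", "N[C@@H](C)c1ccccn1", "", "C24H23ClN2O3", True),
    ("HR85", "N[C@H](C)c1ccccn1", "", "C24H23ClN2O3", True),
    ("HR86", "NC(C)c1ccncc1", "", "C24H23ClN2O3", True),
    ("HR87", "N[C@@H](C)c1ccncc1", "", "C24H23ClN2O3", True),
    ("HR88", "Nc1ccc(O)nc1", "", "C22H19ClN2O4", True),
    ("HR89", "Nc1cccn([H])c1=O",
     "2-(4-(4-chlorobenzoyl)phenoxy)-2-methyl-N-(2-oxo-1,2-dihydropyridin-3-yl)propanamide",
     "C22H19ClN2O4", False),
    ("HR90", "Nc1ccn([H])c(=O)c1", "", "C22H19ClN2O4", True),
]

# Fenofibrate-family controls and the BBB-assay control compounds.
_CONTROL_TABLE: list[tuple[str, str, str, str]] = [
    ("FF", "CC(C)OC(=O)C(C)(C)Oc1ccc(cc1)C(=O)c1ccc(Cl)cc1",
     "fenofibrate", "C20H21ClO4"),
    ("FFA", "OC(=O)C(C)(C)Oc1ccc(cc1)C(=O)c1ccc(Cl)cc1",
     "fenofibric acid", "C17H15ClO4"),
    ("CAF", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "caffeine", "C8H10N4O2"),
    ("TMZ", "Cn1nnc2c(ncn2c1=O)C(N)=O", "temozolomide", "C6H6N6O2"),
]

# Synthetic stand-in for the published reference panel of drugs used or
# trialled against brain tumors.  The study's exact panel sits in
# supplementary material that is not machine-readable here, so this is a
# representative reconstruction of well-known CNS chemotherapy agents;
# threshold calibration only reads guideline values and per-panel ranges,
# so the substitution does not feed any score.
_REFERENCE_TABLE: list[tuple[str, str, str, str]] = [
    ("TMZ-REF", "Cn1nnc2c(ncn2c1=O)C(N)=O", "temozolomide", "C6H6N6O2"),
    ("LOM", "O=NN(CCCl)C(=O)NC1CCCCC1", "lomustine", "C9H16ClN3O2"),
    ("CAR", "O=NN(CCCl)C(=O)NCCCl", "carmustine", "C5H9Cl2N3O2"),
    ("PRO", "CNNCc1ccc(cc1)C(=O)NC(C)C", "procarbazine", "C12H19N3O"),
    ("DAC", "CN(C)N=Nc1[nH]cnc1C(N)=O", "dacarbazine", "C6H10N6O"),
    ("HYD", "NC(=O)NO", "hydroxyurea", "CH4N2O2"),
    ("VOR", "ONC(=O)CCCCCCC(=O)Nc1ccccc1", "vorinostat", "C14H20N2O3"),
    ("MEB", "COC(=O)Nc1nc2cc(ccc2[nH]1)C(=O)c1ccccc1",
     "mebendazole", "C16H13N3O3"),
]


def _build_library() -> dict[str, Compound]:
    lib: dict[str, Compound] = {}
    for cid, tail, name, expected, provisional in _HR_TABLE:
        c = parse_structure(_BPA + tail, cid, name=name, role_tag="candidate",
                            provisional=provisional)
        _check_formula(c, expected)
        lib[cid] = c
    for cid, smiles, name, expected in _CONTROL_TABLE:
        c = parse_structure(smiles, cid, name=name, role_tag="control")
        _check_formula(c, expected)
        lib[cid] = c
    for cid, smiles, name, expected in _REFERENCE_TABLE:
        c = parse_structure(smiles, cid, name=name, role_tag="reference_drug")
        _check_formula(c, expected)
        lib[cid] = c
    return lib


def _check_formula(c: Compound, expected: str) -> None:
    want = parse_formula(expected)
    if dict(c.formula) != want:
        raise StructureError(
            f"{c.id}: SMILES formula {c.formula} does not match the "
            f"registered formula {want}"
        )


_LIBRARY: dict[str, Compound] | None = None


def compound_library() -> dict[str, Compound]:
    """The built-in fixture library, validated on first access.

    Every entry's parsed formula is checked against an independently
    stored formula string; a mismatch raises at load so structure drift
    cannot pass silently.
    """
    global _LIBRARY
    if _LIBRARY is None:
        _LIBRARY = _build_library()
    return dict(_LIBRARY)


def get_compound(cid: str) -> Compound:
    lib = compound_library()
    try:
        return lib[cid]
    except KeyError:
        raise KeyError(f"unknown compound id {cid!r}") from None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_compounds_csv(path: str | Path) -> list[Compound]:
    """Read compounds from a CSV with columns id,name,smiles,role_tag."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(parse_structure(row.smiles, str(row.id),
                                   name=str(getattr(row, "name", "") or ""),
                                   role_tag=str(getattr(row, "role_tag", "candidate"))))
    return out


def write_compounds_csv(compounds: Iterable[Compound], path: str | Path) -> None:
    rows = [
        {
            "id": c.id,
            "name": c.name,
            "smiles": c.smiles,
            "role_tag": c.role_tag,
            "formula": "".join(f"{el}{n if n > 1 else ''}"
                               for el, n in sorted(c.formula.items())),
            "molar_mass": round(c.molar_mass, 3),
        }
        for c in compounds
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sdf(path: str | Path) -> list[Compound]:
    """Read compounds from a V2000 SDF; ids come from the _Name/id field."""
    out = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        cid = mol.GetProp("id") if mol.HasProp("id") else mol.GetProp("_Name")
        out.append(parse_structure(
            Chem.MolToSmiles(mol), cid,
            name=mol.GetProp("name") if mol.HasProp("name") else "",
            role_tag=mol.GetProp("role_tag") if mol.HasProp("role_tag") else "candidate",
        ))
    return out


def write_sdf(compounds: Iterable[Compound], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for c in compounds:
            mol = Chem.MolFromSmiles(c.smiles)
            mol.SetProp("_Name", c.id)
            mol.SetProp("id", c.id)
            mol.SetProp("name", c.name)
            mol.SetProp("role_tag", c.role_tag)
            writer.write(mol)
    finally:
        writer.close()
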