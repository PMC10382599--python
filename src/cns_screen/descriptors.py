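"""Physicochemical descriptors feeding the CNS-MPO and BBB scores.

Calculated fields use open, published estimators: Crippen atomic
contributions for ClogP, the Ertl topological method for TPSA, Lipinski
donor counts for HBD and typed acceptor counts for HBA, and a
Henderson-Hasselbalch correction for ClogD at pH 7.4.  The study whose
compounds these fixtures reproduce used a commercial calculator
(MarvinSketch), so absolute values of the fitted-model descriptors
(ClogP, logS, pKa) differ engine-to-engine; scores built on them carry a
documented cross-engine tolerance.

pKa is not predicted here: it is an input column (override).  A crude
class-value heuristic for pyridine-type nitrogens exists solely so the
in-repo fixtures can be scored end-to-end; see :func:`estimate_basic_pka`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

from .registry import Compound, parse_structure

__all__ = [
    "DescriptorSet",
    "compute_descriptors",
    "clogd_from_logp",
    "mwhbn",
    "estimate_basic_pka",
    "esol_logs",
    "DescriptorCalculator",
]

PHYSIOLOGICAL_PH = 7.4


@dataclass(frozen=True)
class DescriptorSet:
    """The descriptor vector consumed by the two CNS scores.

    ``source_map`` records, per field, whether the value came from the
    built-in calculators (``computed``), an explicit override
    (``override``), a fixture heuristic (``heuristic``) or is ``absent``.
    """

    clogp: float
    clogd_74: float
    mw: float
    tpsa: float
    hbd: int
    hba: int
    aro_rings: int
    heavy_atoms: int
    mwhbn: float
    pka_basic: float | None = None
    pka_acidic: float | None = None
    logs: float | None = None
    source_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if min(self.hbd, self.hba, self.aro_rings, self.heavy_atoms) < 0:
            raise ValueError("counts must be non-negative")
        if self.tpsa < 0:
            raise ValueError("tpsa must be non-negative")
        if abs(self.mwhbn - (self.hbd + self.hba) / math.sqrt(self.mw)) > 1e-9:
            raise ValueError("mwhbn inconsistent with (hbd + hba)/sqrt(mw)")


def mwhbn(mw: float, hbd: int, hba: int) -> float:
    """Hydrogen-bonding-per-size descriptor (HBD + HBA) / sqrt(MW)."""
    if mw <= 0:
        raise ValueError("mw must be positive")
    return (hbd + hba) / math.sqrt(mw)


def clogd_from_logp(
    logp: float,
    pka_basic: float | None = None,
    pka_acidic: float | None = None,
    ph: float = PHYSIOLOGICAL_PH,
) -> float:
    """Distribution coefficient at ``ph`` via Henderson-Hasselbalch.

    Monoprotic treatment of the most basic and most acidic centers:

        logD = logP - log10(1 + 10^(pKa_b - pH)) - log10(1 + 10^(pH - pKa_a))

    Absent terms contribute nothing, so a neutral species has logD = logP
    and logD <= logP always.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError("ph must lie in [0, 14]")
    logd = logp
    if pka_basic is not None:
        logd -= math.log10(1.0 + 10.0 ** (pka_basic - ph))
    if pka_acidic is not None:
        logd -= math.log10(1.0 + 10.0 ** (ph - pka_acidic))
    return logd


def estimate_basic_pka(mol: Chem.Mol) -> float | None:
    """Crude class-value pKa for pyridine-type basic nitrogens.

    Returns a class constant, not a prediction: 4.5 for a pyridine ring
    deactivated by a directly attached carbonyl/amide substituent
    (cf. 3-acetamidopyridine, conjugate-acid pKa near 4.4), 4.9 for
    fused-ring azines (quinoline-like), otherwise 5.2 (pyridine itself);
    an sp3 amine nitrogen returns 9.5.  ``None`` when no basic nitrogen
    is present.  Used only to let in-repo fixtures run end-to-end;
    measured or externally predicted pKa overrides always win.
    """
    basic_aromatic = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N":
            continue
        if atom.GetIsAromatic() and atom.GetTotalNumHs() == 0 and atom.GetDegree() == 2:
            basic_aromatic.append(atom)
        elif not atom.GetIsAromatic() and atom.GetTotalNumHs() >= 1:
            # exclude amide N
            if not any(_is_carbonyl_carbon(nb) for nb in atom.GetNeighbors()):
                return 9.5
    if not basic_aromatic:
        return None
    best = None
    for atom in basic_aromatic:
        ring_atoms = _ring_of(mol, atom.GetIdx())
        fused = any(mol.GetRingInfo().NumAtomRings(i) > 1 for i in ring_atoms)
        deactivated = any(
            _has_exocyclic_carbonyl_or_amide(mol, i, ring_atoms) for i in ring_atoms
        )
        if deactivated:
            pka = 4.5
        elif fused:
            pka = 4.9
        else:
            pka = 5.2
        best = pka if best is None else max(best, pka)
    return best


def _is_carbonyl_carbon(atom: Chem.Atom) -> bool:
    return atom.GetSymbol() == "C" and any(
        b.GetBondTypeAsDouble() == 2.0 and b.GetOtherAtom(atom).GetSymbol() == "O"
        for b in atom.GetBonds()
    )


def _ring_of(mol: Chem.Mol, idx: int) -> tuple[int, ...]:
    for ring in mol.GetRingInfo().AtomRings():
        if idx in ring:
            return ring
    return (idx,)


def _has_exocyclic_carbonyl_or_amide(mol, idx: int, ring_atoms) -> bool:
    atom = mol.GetAtomWithIdx(idx)
    for nb in atom.GetNeighbors():
        if nb.GetIdx() in ring_atoms:
            continue
        if _is_carbonyl_carbon(nb):
            return True
        if nb.GetSymbol() == "N" and any(
            _is_carbonyl_carbon(n2) for n2 in nb.GetNeighbors()
        ):
            return True
    return False


def esol_logs(mol: Chem.Mol, clogp: float) -> float:
    """Delaney's ESOL estimate of aqueous solubility, log10(mol/L).

    logS = 0.16 - 0.63 ClogP - 0.0062 MW + 0.066 RB - 0.74 AP,
    with AP the aromatic-heavy-atom proportion.  A fallback for fixtures;
    measured logS overrides take precedence.
    """
    mw = rdMolDescriptors.CalcExactMolWt(mol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


_OVERRIDABLE = {
    "clogp", "clogd_74", "mw", "tpsa", "hbd", "hba",
    "aro_rings", "heavy_atoms", "pka_basic", "pka_acidic", "logs",
}


def compute_descriptors(
    c: Compound | str,
    overrides: Mapping[str, float] | None = None,
    *,
    use_pka_heuristic: bool = True,
) -> DescriptorSet:
    """Populate a :class:`DescriptorSet` for one compound.

    Every field comes either from the built-in calculators or from
    ``overrides`` (which never alter other fields); ``source_map`` records
    which.  Deterministic for fixed input.  Missing pKa with no override
    leaves the pKa fields absent — downstream scores apply their own
    missing-value policies.
    """
    if isinstance(c, str):
        c = parse_structure(c, c)
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDABLE
    if unknown:
        raise KeyError(f"unknown override fields: {sorted(unknown)}")

    mol = c.mol()
    values: dict[str, object] = {
        "clogp": Crippen.MolLogP(mol),
        "mw": c.molar_mass,
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "hbd": rdMolDescriptors.CalcNumLipinskiHBD(mol),
        "hba": rdMolDescriptors.CalcNumHBA(mol),
        "aro_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "heavy_atoms": mol.GetNumHeavyAtoms(),
    }
    source = {k: "computed" for k in values}

    pka_b = overrides.get("pka_basic")
    if pka_b is None and "pka_basic" not in overrides and use_pka_heuristic:
        pka_b = estimate_basic_pka(mol)
        source["pka_basic"] = "heuristic" if pka_b is not None else "absent"
    else:
        source["pka_basic"] = "override" if "pka_basic" in overrides else "absent"
    pka_a = overrides.get("pka_acidic")
    source["pka_acidic"] = "override" if "pka_acidic" in overrides else "absent"

    for key in ("clogp", "mw", "tpsa", "hbd", "hba", "aro_rings", "heavy_atoms"):
        if key in overrides:
            values[key] = overrides[key]
            source[key] = "override"

    if "clogd_74" in overrides:
        clogd = overrides["clogd_74"]
        source["clogd_74"] = "override"
    else:
        clogd = clogd_from_logp(float(values["clogp"]), pka_b, pka_a)
        source["clogd_74"] = "computed"

    if "logs" in overrides:
        logs = overrides["logs"]
        source["logs"] = "override"
    else:
        logs = esol_logs(mol, float(values["clogp"]))
        source["logs"] = "computed_esol"

    return DescriptorSet(
        clogp=float(values["clogp"]),
        clogd_74=float(clogd),
        mw=float(values["mw"]),
        tpsa=float(values["tpsa"]),
        hbd=int(values["hbd"]),
        hba=int(values["hba"]),
        aro_rings=int(values["aro_rings"]),
        heavy_atoms=int(values["heavy_atoms"]),
        mwhbn=mwhbn(float(values["mw"]), int(values["hbd"]), int(values["hba"])),
        pka_basic=pka_b,
        pka_acidic=pka_a,
        logs=None if logs is None else float(logs),
        source_map=source,
    )


class DescriptorCalculator(BaseEstimator, TransformerMixin):
    """Stateless transformer: compounds in, descriptor table out.

    ``transform`` accepts an iterable of :class:`Compound` or SMILES
    strings and returns one DataFrame row per compound (indexed by id)
    with all descriptor fields plus a provenance column.  An
    ``overrides`` frame indexed by compound id supplies per-compound
    external values (e.g. measured pKa or logS).
    """

    def __init__(self, use_pka_heuristic: bool = True):
        self.use_pka_heuristic = use_pka_heuristic

    def fit(self, X: Iterable, y=None) -> "DescriptorCalculator":
        return self

    def transform(
        self, X: Iterable[Compound | str],
        overrides: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        rows = []
        for c in X:
            cid = c if isinstance(c, str) else c.id
            row_over: dict[str, float] = {}
            if overrides is not None and cid in overrides.index:
                row_over = {
                    k: v for k, v in overrides.loc[cid].items()
                    if k in _OVERRIDABLE and pd.notna(v)
                }
            d = compute_descriptors(c, row_over,
                                    use_pka_heuristic=self.use_pka_heuristic)
            rows.append({
                "compound_id": cid,
                "clogp": d.clogp, "clogd_74": d.clogd_74, "mw": d.mw,
                "tpsa": d.tpsa, "hbd": d.hbd, "hba": d.hba,
                "aro_rings": d.aro_rings, "heavy_atoms": d.heavy_atoms,
                "mwhbn": d.mwhbn, "pka_basic": d.pka_basic,
                "pka_acidic": d.pka_acidic, "logs": d.logs,
                "provenance": ";".join(f"{k}={v}" for k, v in sorted(d.source_map.items())),
            })
        return pd.DataFrame(rows).set_index("compound_id")
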