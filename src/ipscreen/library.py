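"""Compound library: structures, physicochemical descriptors and rule-of-five verdicts.

The library members are 2-arylimidazo[1,2-a]pyridin-3-yl derivatives fused to a
dimedone-derived 3-hydroxycyclohex-2-enone ring.  For this chemistry the module
computes molecular weight (from a formula, with IUPAC standard atomic weights),
hydrogen-bond donor/acceptor counts, a fragment-contribution topological polar
surface area (TPSA), and the classic four-criterion Lipinski rule-of-five
violation count.  The octanol/water partition coefficient (logP) is consumed as
data from an external predictor, never computed here.

Two conventions are deliberately non-standard and calibrated to the published
descriptor set for this scaffold:

* ``count_hba`` counts N and O atoms but excludes the bridgehead aromatic
  nitrogen (three ring bonds) and the nitro nitrogen; nitro oxygens count.
* ``tpsa`` sums a closed fragment table covering the scaffold grammar
  (hydroxyl, carbonyl O, pyridine-type and bridgehead aromatic N, aromatic
  ether O, nitro group) and refuses — rather than silently zeroing — any polar
  fragment outside it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from ._util import round_half_up

__all__ = [
    "Compound",
    "PhyschemProfile",
    "FormulaError",
    "TpsaFragmentError",
    "parse_formula",
    "molecular_weight",
    "count_hbd",
    "count_hba",
    "tpsa",
    "lipinski_violations",
    "lipinski_verdict",
    "profile_compound",
    "profile_library",
    "read_compound_table",
]

# IUPAC 2021 standard atomic weights (conventional values), g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}


class FormulaError(ValueError):
    """Raised for an unparseable molecular formula or unknown element symbol."""


class TpsaFragmentError(ValueError):
    """Raised when a polar fragment falls outside the supported contribution table."""


@dataclass
class Compound:
    """A library member: short id, structure, and optional scaffold annotation."""

    id: str
    smiles: str | None = None
    name: str = ""
    formula: dict[str, int] | None = None
    substituents: dict[str, str] = field(default_factory=dict)

    def mol(self) -> Chem.Mol:
        if self.smiles is None:
            raise ValueError(f"compound {self.id!r} has no structure")
        return _mol_from_smiles(self.smiles)


@dataclass
class PhyschemProfile:
    """Descriptor row: MW (g/mol), HBA/HBD counts, TPSA (A^2), logP, violations."""

    compound_id: str
    mw: float
    n_hba: int
    n_hbd: int
    tpsa: float
    logp: float | None = None
    n_lipinski_violations: int | None = None


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into an element -> count map.

    >>> parse_formula("C21H20N2O2")
    {'C': 21, 'H': 20, 'N': 2, 'O': 2}
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula fragment {text[pos:m.start()]!r}")
        sym, num = m.group(1), m.group(2)
        if sym not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element symbol {sym!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unparseable formula fragment {text[pos:]!r}")
    return counts


def molecular_weight(formula: dict[str, int] | str) -> float:
    """Molecular weight in g/mol from standard atomic weights, 2-decimal half-up."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for sym, n in formula.items():
        try:
            total += n * ATOMIC_WEIGHTS[sym]
        except KeyError:
            raise FormulaError(f"no atomic weight tabulated for {sym!r}") from None
    return round_half_up(total, 2)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(f"SMILES is not a single connected molecule: {smiles!r}")
    return mol


def _as_mol(structure: str | Chem.Mol | Compound) -> Chem.Mol:
    if isinstance(structure, Compound):
        return structure.mol()
    if isinstance(structure, Chem.Mol):
        return structure
    return _mol_from_smiles(structure)


def count_hbd(structure: str | Chem.Mol | Compound) -> int:
    """Number of O-H / N-H hydrogen-bond donor groups."""
    return int(rdMolDescriptors.CalcNumHBD(_as_mol(structure)))


def _is_nitro_n(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "N":
        return False
    o_neighbors = [a for a in atom.GetNeighbors() if a.GetSymbol() == "O" and a.GetDegree() == 1]
    return len(o_neighbors) == 2


def _is_bridgehead_aromatic_n(atom: Chem.Atom) -> bool:
    return (
        atom.GetSymbol() == "N"
        and atom.GetIsAromatic()
        and sum(1 for b in atom.GetBonds() if b.IsInRing()) == 3
    )


def count_hba(structure: str | Chem.Mol | Compound) -> int:
    """Hydrogen-bond acceptor count under the calibrated N/O convention.

    Every nitrogen and oxygen accepts except the bridgehead aromatic nitrogen
    (the fused-ring junction, three ring bonds) and the nitro nitrogen; the two
    nitro oxygens count individually.
    """
    mol = _as_mol(structure)
    n = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ("N", "O"):
            continue
        if _is_bridgehead_aromatic_n(atom) or _is_nitro_n(atom):
            continue
        n += 1
    return n


# Fragment contributions (A^2) for the polar groups of the supported scaffold
# grammar.  The nitro group is treated as one fragment (N plus both oxygens).
TPSA_FRAGMENTS = {
    "hydroxyl O-H": 20.23,
    "carbonyl O": 17.07,
    "aromatic N (2 ring bonds)": 12.89,
    "aromatic N (3 ring bonds)": 4.41,
    "ether O (aromatic)": 9.23,
    "nitro group": 45.82,
}


def tpsa(structure: str | Chem.Mol | Compound) -> float:
    """Topological polar surface area by fragment contributions, 2-decimal half-up.

    Raises :class:`TpsaFragmentError` naming the fragment if a polar atom does
    not match the supported grammar — never a silent zero.
    """
    mol = _as_mol(structure)
    total = 0.0
    nitro_handled: set[int] = set()
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            continue
        idx = atom.GetIdx()
        if idx in nitro_handled:
            continue
        if sym == "N":
            if _is_nitro_n(atom):
                total += TPSA_FRAGMENTS["nitro group"]
                nitro_handled.add(idx)
                for nb in atom.GetNeighbors():
                    if nb.GetSymbol() == "O" and nb.GetDegree() == 1:
                        nitro_handled.add(nb.GetIdx())
            elif _is_bridgehead_aromatic_n(atom):
                total += TPSA_FRAGMENTS["aromatic N (3 ring bonds)"]
            elif atom.GetIsAromatic() and atom.GetDegree() == 2 and atom.GetTotalNumHs() == 0:
                total += TPSA_FRAGMENTS["aromatic N (2 ring bonds)"]
            else:
                raise TpsaFragmentError(
                    f"nitrogen fragment at atom {idx} outside the supported table"
                )
        else:  # oxygen
            if atom.GetTotalNumHs() >= 1:
                total += TPSA_FRAGMENTS["hydroxyl O-H"]
            elif any(b.GetBondTypeAsDouble() == 2.0 for b in atom.GetBonds()):
                total += TPSA_FRAGMENTS["carbonyl O"]
            elif atom.GetDegree() == 2 and any(a.GetIsAromatic() for a in atom.GetNeighbors()):
                total += TPSA_FRAGMENTS["ether O (aromatic)"]
            else:
                raise TpsaFragmentError(
                    f"oxygen fragment at atom {idx} outside the supported table"
                )
    return round_half_up(total, 2)


# Classic rule-of-five thresholds.  MW is a strict upper bound as printed;
# the others are inclusive, so a value exactly at the boundary does not violate.
LIPINSKI_THRESHOLDS = {"mw": 500.0, "logp": 5.0, "n_hbd": 5, "n_hba": 10}


def lipinski_violations(
    mw: float, logp: float, n_hbd: int, n_hba: int
) -> int:
    """Count of rule-of-five violations (MW < 500; logP <= 5; HBD <= 5; HBA <= 10).

    TPSA is reported alongside but is not a violation criterion.
    """
    if logp is None:
        raise ValueError("logp is required for a Lipinski verdict")
    return int(
        (mw >= LIPINSKI_THRESHOLDS["mw"])
        + (logp > LIPINSKI_THRESHOLDS["logp"])
        + (n_hbd > LIPINSKI_THRESHOLDS["n_hbd"])
        + (n_hba > LIPINSKI_THRESHOLDS["n_hba"])
    )


def lipinski_verdict(profile: PhyschemProfile) -> tuple[int, bool]:
    """(violation count, passes) — passes means at most one violation."""
    n = lipinski_violations(profile.mw, profile.logp, profile.n_hbd, profile.n_hba)
    return n, n <= 1


def profile_compound(compound: Compound, logp: float | None = None) -> PhyschemProfile:
    """Compute the full descriptor row for one compound.

    MW comes from the formula when given, else from the SMILES-derived formula.
    The violation count is filled only when logp is supplied.
    """
    mol = compound.mol()
    formula = compound.formula or _formula_from_mol(mol)
    prof = PhyschemProfile(
        compound_id=compound.id,
        mw=molecular_weight(formula),
        n_hba=count_hba(mol),
        n_hbd=count_hbd(mol),
        tpsa=tpsa(mol),
        logp=logp,
    )
    if logp is not None:
        prof.n_lipinski_violations = lipinski_violations(
            prof.mw, logp, prof.n_hbd, prof.n_hba
        )
    return prof


def _formula_from_mol(mol: Chem.Mol) -> dict[str, int]:
    molh = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for atom in molh.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    return counts


def profile_library(
    compounds: list[Compound], logp: dict[str, float] | None = None
) -> pd.DataFrame:
    """Descriptor table for a whole library (one row per compound)."""
    logp = logp or {}
    rows = [profile_compound(c, logp.get(c.id)) for c in compounds]
    df = pd.DataFrame(
        {
            "id": [p.compound_id for p in rows],
            "mw": [p.mw for p in rows],
            "n_hba": [p.n_hba for p in rows],
            "n_hbd": [p.n_hbd for p in rows],
            "tpsa": [p.tpsa for p in rows],
            "logp": [p.logp for p in rows],
            "n_lipinski_violations": [p.n_lipinski_violations for p in rows],
        }
    )
    return df


def read_compound_table(path) -> list[Compound]:
    """Read an (id, smiles[, ...]) or (id, formula) TSV into Compound records."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "id" not in df.columns:
        raise ValueError("compound table needs an 'id' column")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate compound ids: {dups}")
    out = []
    for _, row in df.iterrows():
        out.append(
            Compound(
                id=str(row["id"]),
                smiles=str(row["smiles"]) if "smiles" in df.columns else None,
                name=str(row.get("name", "") or ""),
                formula=parse_formula(row["formula"]) if "formula" in df.columns else None,
                substituents={
                    k: str(row[k]) for k in ("r1", "r2") if k in df.columns
                },
            )
        )
    return out
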