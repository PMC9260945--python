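"""Docking-score ranking, reference comparison and selectivity summaries.

Docking outputs are consumed as data: per (ligand, target) a row of five
metrics (MolDock score, rerank score, protein-ligand interaction energy,
steric score, H-bond score — energies in kJ/mol) where more negative means
stronger predicted binding, plus residue-level hydrogen-bond contact records
(bond energy in kJ/mol, bond length in angstroms).  Reference standards
(approved drugs docked against the same target) are flagged and excluded from
library rankings but drive the better/worse comparisons.

Scoring-function internals are out of scope by design; nothing here re-scores
poses.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._util import parse_number

__all__ = [
    "METRICS",
    "RankedLigands",
    "SelectivitySummary",
    "rank_ligands",
    "compare_to_reference",
    "hbond_report",
    "selectivity_matrix",
    "read_dock_scores",
    "read_hbond_contacts",
    "residue_key",
]

METRICS = ("moldock", "rerank", "interaction_energy", "steric", "hbond")

# Column-name aliases accepted at parse time (lowercased, stripped).
COLUMN_ALIASES = {
    "ligand_id": "ligand_id",
    "compound": "ligand_id",
    "compound name": "ligand_id",
    "target_id": "target_id",
    "target": "target_id",
    "moldock": "moldock",
    "moldock score": "moldock",
    "rerank": "rerank",
    "rerank score": "rerank",
    "rerank score (kj/mol)": "rerank",
    "interaction_energy": "interaction_energy",
    "interaction energy": "interaction_energy",
    "interaction energy (kj/mol)": "interaction_energy",
    "steric": "steric",
    "hbond": "hbond",
    "hbond score": "hbond",
    "hbond (kj/mol)": "hbond",
    "is_reference": "is_reference",
    "reference": "is_reference",
    "residue": "residue",
    "interaction": "residue",
    "ligand_atom": "ligand_atom",
    "bond_energy_kj_mol": "bond_energy_kj_mol",
    "bond energy(kj/mol)": "bond_energy_kj_mol",
    "bond_length_a": "bond_length_A",
    "bond_length_A".lower(): "bond_length_A",
    "bond length (a)": "bond_length_A",
}


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in COLUMN_ALIASES:
            renames[col] = COLUMN_ALIASES[key]
    return df.rename(columns=renames)


def read_dock_scores(path, target_id: str | None = None) -> pd.DataFrame:
    """Read a docking-score CSV; one row per (ligand, target), five metrics.

    ``target_id`` fills the column when the file is single-target.  Metric
    cells may carry typographic minus glyphs.
    """
    df = _normalize_columns(pd.read_csv(path, comment="#"))
    if target_id is not None:
        df["target_id"] = target_id
    for m in METRICS:
        if m not in df.columns:
            raise ValueError(f"docking table missing metric column {m!r}")
        df[m] = [parse_number(v) for v in df[m]]
    if "is_reference" not in df.columns:
        df["is_reference"] = False
    df["is_reference"] = df["is_reference"].astype(bool)
    if df.duplicated(subset=["ligand_id", "target_id"]).any():
        pairs = df.loc[
            df.duplicated(subset=["ligand_id", "target_id"]), ["ligand_id", "target_id"]
        ].values.tolist()
        raise ValueError(f"duplicate (ligand, target) records: {pairs}")
    return df


def read_hbond_contacts(path) -> pd.DataFrame:
    """Read a hydrogen-bond contact CSV and sanity-screen energies/lengths.

    Bond energies must be <= 0 and lengths > 0 (hard invariants); energies
    below -2.5 kJ/mol draw a warning (outside the usual MVD per-contact cap),
    not an error.
    """
    df = _normalize_columns(pd.read_csv(path, comment="#"))
    df["bond_energy_kj_mol"] = [parse_number(v) for v in df["bond_energy_kj_mol"]]
    df["bond_length_A"] = [
        parse_number(re.sub(r"[^0-9.\-]", "", str(v))) for v in df["bond_length_A"]
    ]
    if (df["bond_length_A"] <= 0).any():
        raise ValueError("hydrogen-bond lengths must be positive")
    if (df["bond_energy_kj_mol"] > 0).any():
        raise ValueError("hydrogen-bond energies must be non-positive")
    if (df["bond_energy_kj_mol"] < -2.5).any():
        warnings.warn("contact energies below -2.5 kJ/mol; check units", stacklevel=2)
    return df


@dataclass(frozen=True)
class RankedLigands:
    target_id: str
    key: str
    order: tuple[str, ...]  # best (most negative) first
    values: tuple[float, ...]

    @property
    def best(self) -> str:
        return self.order[0]

    @property
    def best_value(self) -> float:
        return self.values[0]


def _target_rows(scores: pd.DataFrame, target_id: str) -> pd.DataFrame:
    rows = scores[scores["target_id"] == target_id]
    if len(rows) == 0:
        raise ValueError(f"no docking records for target {target_id!r}")
    return rows


def rank_ligands(scores: pd.DataFrame, target_id: str, key: str = "moldock") -> RankedLigands:
    """Rank library ligands for one target, most negative metric first.

    References are excluded; ties break lexicographically by ligand id.
    """
    if key not in METRICS:
        raise ValueError(f"unknown metric {key!r}; expected one of {METRICS}")
    rows = _target_rows(scores, target_id)
    lib = rows[~rows["is_reference"]]
    if len(lib) == 0:
        raise ValueError(f"no non-reference ligands for target {target_id!r}")
    lib = lib.sort_values([key, "ligand_id"], kind="mergesort")
    return RankedLigands(
        target_id=target_id,
        key=key,
        order=tuple(lib["ligand_id"]),
        values=tuple(float(v) for v in lib[key]),
    )


def compare_to_reference(
    scores: pd.DataFrame, target_id: str, metric: str = "moldock"
) -> dict:
    """Flag each library ligand better/worse than the target's reference drug.

    'Better' means strictly more negative; equality is not better.  Exactly
    one reference record must exist for the target.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    rows = _target_rows(scores, target_id)
    refs = rows[rows["is_reference"]]
    if len(refs) != 1:
        raise ValueError(
            f"target {target_id!r} must have exactly one reference, found {len(refs)}"
        )
    lib = rows[~rows["is_reference"]]
    if len(lib) == 0:
        raise ValueError(f"no library ligands for target {target_id!r}")
    ref_value = float(refs[metric].iloc[0])
    flags = {
        str(r["ligand_id"]): bool(r[metric] < ref_value) for _, r in lib.iterrows()
    }
    return {
        "target_id": target_id,
        "metric": metric,
        "reference_id": str(refs["ligand_id"].iloc[0]),
        "reference_value": ref_value,
        "better": flags,
        "n_better": sum(flags.values()),
        "n_ligands": len(flags),
    }


_RESIDUE_RE = re.compile(r"([A-Za-z]{2,4})\s*(\d+)")


def residue_key(interaction: str) -> tuple[str, int]:
    """Extract (residue name, number) from an interaction label.

    'Ser 205 (O)-N (12)' -> ('Ser', 205); the contacting atoms are ignored for
    per-residue aggregation.
    """
    m = _RESIDUE_RE.search(str(interaction))
    if not m:
        raise ValueError(f"cannot parse residue from {interaction!r}")
    return m.group(1), int(m.group(2))


def hbond_report(contacts: pd.DataFrame, ligand_id: str, target_id: str | None = None) -> dict:
    """Summarize hydrogen-bond contacts for one (ligand, target) pair.

    Reports the contact count, per-residue counts, the strongest (most
    negative) contact, and the plain sum of bond energies.  The sum is
    reported alongside — not equated with — the docking table's H-bond score.
    """
    rows = contacts[contacts["ligand_id"] == ligand_id]
    if target_id is not None and "target_id" in contacts.columns:
        rows = rows[rows["target_id"] == target_id]
    if len(rows) == 0:
        return {
            "ligand_id": ligand_id,
            "target_id": target_id,
            "n_contacts": 0,
            "residues": {},
            "strongest": None,
            "total_energy": 0.0,
        }
    residues: dict[str, int] = {}
    for _, r in rows.iterrows():
        name, num = residue_key(r["residue"])
        key = f"{name} {num}"
        residues[key] = residues.get(key, 0) + 1
    strongest_row = rows.loc[rows["bond_energy_kj_mol"].idxmin()]
    return {
        "ligand_id": ligand_id,
        "target_id": target_id,
        "n_contacts": int(len(rows)),
        "residues": residues,
        "strongest": {
            "residue": str(strongest_row["residue"]),
            "bond_energy_kj_mol": float(strongest_row["bond_energy_kj_mol"]),
            "bond_length_A": float(strongest_row["bond_length_A"]),
        },
        "total_energy": float(rows["bond_energy_kj_mol"].sum()),
    }


@dataclass
class SelectivitySummary:
    """Cross-target view: per-target best ligand, MolDock rank matrix, comparisons."""

    targets: list[str]
    best_per_target: dict[str, dict]
    rank_matrix: pd.DataFrame  # index ligand_id, one integer-rank column per target
    reference_comparison: dict[str, dict] = field(default_factory=dict)
    best_target_per_ligand: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "targets": self.targets,
            "best_per_target": self.best_per_target,
            "best_target_per_ligand": self.best_target_per_ligand,
            "reference_comparison": self.reference_comparison,
            "rank_matrix": {
                lig: {t: int(self.rank_matrix.loc[lig, t]) for t in self.targets}
                for lig in self.rank_matrix.index
            },
        }


def selectivity_matrix(scores: pd.DataFrame, metric: str = "moldock") -> SelectivitySummary:
    """Build the cross-target selectivity summary over all targets in ``scores``.

    Requires the same library ligand set for every target (ragged sets are an
    error naming the missing pairs) and one reference per target.
    """
    targets = sorted(scores["target_id"].unique())
    lib = scores[~scores["is_reference"]]
    ligand_sets = {t: set(lib.loc[lib["target_id"] == t, "ligand_id"]) for t in targets}
    all_ligands = sorted(set().union(*ligand_sets.values()))
    missing = [
        (lig, t) for t in targets for lig in all_ligands if lig not in ligand_sets[t]
    ]
    if missing:
        raise ValueError(f"ragged ligand sets; missing (ligand, target) pairs: {missing}")

    rank_matrix = pd.DataFrame(index=all_ligands, columns=targets, dtype=int)
    best_per_target = {}
    best_value_per_ligand: dict[str, tuple[float, str]] = {}
    comparisons = {}
    for t in targets:
        ranked = rank_ligands(scores, t, metric)
        for pos, (lig, val) in enumerate(zip(ranked.order, ranked.values), start=1):
            rank_matrix.loc[lig, t] = pos
            cur = best_value_per_ligand.get(lig)
            if cur is None or val < cur[0]:
                best_value_per_ligand[lig] = (val, t)
        best_row = scores[
            (scores["target_id"] == t) & (scores["ligand_id"] == ranked.best)
        ].iloc[0]
        best_per_target[t] = {
            "ligand_id": ranked.best,
            **{m: float(best_row[m]) for m in METRICS},
        }
        comparisons[t] = compare_to_reference(scores, t, metric)
    return SelectivitySummary(
        targets=targets,
        best_per_target=best_per_target,
        rank_matrix=rank_matrix,
        reference_comparison=comparisons,
        best_target_per_ligand={lig: t for lig, (_, t) in best_value_per_ligand.items()},
    )
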