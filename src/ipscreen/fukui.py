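"""Condensed Fukui functions: per-atom site reactivity from charge differences.

Given per-atom charges q_k at three electron counts (the N-electron neutral
molecule, the N-1 cation and the N+1 anion), the condensed Fukui indices are
finite differences

    f+ (nucleophilic attack) = q_k(N)   - q_k(N+1)
    f- (electrophilic attack) = q_k(N-1) - q_k(N)
    f0 (radical attack)       = (f+ + f-) / 2

With this sign convention the highest positive value marks the most
susceptible site.  Because each pair of states differs by exactly one
electron, each index column sums to one over the molecule — a bookkeeping
identity used both to validate inputs and as a self-check on outputs.

Published per-atom tables can also be imported verbatim (provenance
``imported``); no conservation check is enforced on imported data, since
printed tables are rounded and not always internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import parse_number, round_half_up

__all__ = [
    "ChargeSet",
    "FukuiTable",
    "ChargeStateError",
    "fukui_indices",
    "import_fukui_table",
    "top_sites",
    "read_charge_set",
    "read_fukui_table",
]

ONE_ELECTRON_TOL = 1e-3  # e; loose enough for real population analyses

INDEX_KINDS = ("plus", "minus", "zero")


class ChargeStateError(ValueError):
    """Raised when charge vectors do not differ by exactly one electron."""


@dataclass
class ChargeSet:
    """Per-atom charges (e) for the N-1, N and N+1 electron states of one compound."""

    compound_id: str
    atoms: list[tuple[str, str]]  # (atom_label, element)
    charges_minus: np.ndarray  # cation, N-1 electrons
    charges_neutral: np.ndarray  # neutral, N electrons
    charges_plus: np.ndarray  # anion, N+1 electrons
    scheme: str = "NBO"

    def __post_init__(self) -> None:
        self.charges_minus = np.asarray(self.charges_minus, dtype=float)
        self.charges_neutral = np.asarray(self.charges_neutral, dtype=float)
        self.charges_plus = np.asarray(self.charges_plus, dtype=float)

    def validate(self, tol: float = ONE_ELECTRON_TOL) -> None:
        n = len(self.atoms)
        for name, vec in (
            ("charges_minus", self.charges_minus),
            ("charges_neutral", self.charges_neutral),
            ("charges_plus", self.charges_plus),
        ):
            if len(vec) != n:
                raise ChargeStateError(
                    f"{self.compound_id}: {name} has {len(vec)} entries for {n} atoms"
                )
        d_cation = self.charges_minus.sum() - self.charges_neutral.sum()
        d_anion = self.charges_neutral.sum() - self.charges_plus.sum()
        if abs(d_cation - 1.0) > tol:
            raise ChargeStateError(
                f"{self.compound_id}: (N-1, N) states differ by {d_cation:.6f} e, "
                "expected +1 (removing one electron raises total charge by one)"
            )
        if abs(d_anion - 1.0) > tol:
            raise ChargeStateError(
                f"{self.compound_id}: (N, N+1) states differ by {d_anion:.6f} e, expected +1"
            )


@dataclass
class FukuiTable:
    """Per-atom site-reactivity indices; columns may be absent on import."""

    compound_id: str
    atoms: list[str]
    f_plus: np.ndarray | None = None
    f_minus: np.ndarray | None = None
    f_zero: np.ndarray | None = None
    provenance: str = "computed"  # {"computed", "imported"}
    elements: list[str] = field(default_factory=list)

    def index(self, kind: str) -> np.ndarray:
        if kind not in INDEX_KINDS:
            raise ValueError(f"unknown Fukui index kind {kind!r}")
        vec = {"plus": self.f_plus, "minus": self.f_minus, "zero": self.f_zero}[kind]
        if vec is None:
            raise ValueError(f"f_{kind} is absent from this table")
        return vec

    def to_frame(self) -> pd.DataFrame:
        data = {"atom_label": self.atoms}
        for kind in INDEX_KINDS:
            vec = {"plus": self.f_plus, "minus": self.f_minus, "zero": self.f_zero}[kind]
            if vec is not None:
                data[f"f_{kind}"] = vec
        return pd.DataFrame(data)


def fukui_indices(cs: ChargeSet) -> FukuiTable:
    """Condensed Fukui indices from a validated three-state charge set."""
    cs.validate()
    f_plus = cs.charges_neutral - cs.charges_plus
    f_minus = cs.charges_minus - cs.charges_neutral
    return FukuiTable(
        compound_id=cs.compound_id,
        atoms=[label for label, _ in cs.atoms],
        elements=[el for _, el in cs.atoms],
        f_plus=f_plus,
        f_minus=f_minus,
        f_zero=(f_plus + f_minus) / 2.0,
        provenance="computed",
    )


def import_fukui_table(
    rows: pd.DataFrame, compound_id: str = "", warn: bool = True
) -> FukuiTable:
    """Import a published per-atom index table verbatim (no conservation check).

    ``rows`` needs an ``atom_label`` column plus at least one of ``f_plus``,
    ``f_minus``, ``f_zero``.  Missing index columns are marked absent.
    """
    if len(rows) == 0:
        raise ValueError("empty Fukui table")
    if "atom_label" not in rows.columns:
        raise ValueError("imported table needs an 'atom_label' column")
    labels = [str(x) for x in rows["atom_label"]]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate atom labels: {dupes}")
    cols = {}
    for kind in INDEX_KINDS:
        col = f"f_{kind}"
        if col in rows.columns:
            cols[col] = np.array([parse_number(v) for v in rows[col]])
    if not cols:
        raise ValueError("imported table carries none of f_plus/f_minus/f_zero")
    return FukuiTable(
        compound_id=compound_id,
        atoms=labels,
        elements=[str(x) for x in rows["element"]] if "element" in rows.columns else [],
        f_plus=cols.get("f_plus"),
        f_minus=cols.get("f_minus"),
        f_zero=cols.get("f_zero"),
        provenance="imported",
    )


def top_sites(ft: FukuiTable, index_kind: str, k: int) -> list[tuple[str, float]]:
    """Top-k atomic sites by descending index value (ties keep atom order).

    Values are reported at 4-decimal half-up rounding.  The highest positive
    f+ marks the preferred site of nucleophilic attack, the highest f- the
    electrophilic-attack site, the highest f0 the radical-attack site.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    values = ft.index(index_kind)
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    return [(ft.atoms[i], round_half_up(float(values[i]), 4)) for i in order[:k]]


def read_charge_set(path, compound_id: str = "", scheme: str = "NBO") -> ChargeSet:
    """Read a per-atom charge TSV: atom_label, element, q_nminus1, q_n, q_nplus1."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return ChargeSet(
        compound_id=compound_id,
        atoms=[(str(r["atom_label"]), str(r["element"])) for _, r in df.iterrows()],
        charges_minus=np.array([parse_number(v) for v in df["q_nminus1"]]),
        charges_neutral=np.array([parse_number(v) for v in df["q_n"]]),
        charges_plus=np.array([parse_number(v) for v in df["q_nplus1"]]),
        scheme=scheme,
    )


def read_fukui_table(path, compound_id: str = "") -> FukuiTable:
    """Read a published-style per-atom index TSV in import mode."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return import_fukui_table(df, compound_id=compound_id)
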