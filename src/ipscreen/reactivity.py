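"""Global conceptual-DFT reactivity descriptors from frontier orbital energies.

Within Koopmans' approximation the ionization potential is I = -E_HOMO and the
electron affinity A = -E_LUMO.  The derived global descriptors are

    gap          dE  = E_LUMO - E_HOMO = I - A
    hardness     eta = dE / 2
    potential    mu  = (E_HOMO + E_LUMO) / 2   (electronegativity chi = -mu)
    electrophilicity  omega = mu^2 / (2 eta)

The hardness convention carries the factor of two (eta = (I - A)/2); both
conventions exist in the literature, and this one is the package's fixed
contract.  A soft molecule (small gap) is the more reactive; a large omega
marks the stronger electrophile.  All descriptors are reported in eV at
4-decimal half-up rounding; internal arithmetic is full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import parse_number, round_half_up

__all__ = [
    "FrontierEnergies",
    "GlobalReactivity",
    "DegenerateGapError",
    "global_indices",
    "rank_library",
    "RankingResult",
    "reactivity_table",
    "read_frontier_energies",
]

RANK_KEYS = ("gap", "hardness", "electrophilicity")


class DegenerateGapError(ValueError):
    """Raised when E_LUMO <= E_HOMO (gap non-positive, omega undefined)."""


@dataclass(frozen=True)
class FrontierEnergies:
    compound_id: str
    e_homo: float  # eV
    e_lumo: float  # eV


@dataclass(frozen=True)
class GlobalReactivity:
    """Derived global descriptors, all in eV (full precision)."""

    compound_id: str
    e_homo: float
    e_lumo: float
    gap: float
    ionization_potential: float
    electron_affinity: float
    hardness: float
    chemical_potential: float
    electronegativity: float
    electrophilicity: float

    @property
    def softness(self) -> float:
        """S = 1/(2 eta), eV^-1.  Derived accessor; not part of the tabulated set."""
        return 1.0 / (2.0 * self.hardness)

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        return {
            k: round_half_up(getattr(self, k), ndigits)
            for k in (
                "e_homo",
                "e_lumo",
                "gap",
                "ionization_potential",
                "electron_affinity",
                "hardness",
                "chemical_potential",
                "electronegativity",
                "electrophilicity",
            )
        }


def global_indices(fe: FrontierEnergies) -> GlobalReactivity:
    """Compute all global descriptors for one frontier-energy record."""
    if fe.e_lumo <= fe.e_homo:
        raise DegenerateGapError(
            f"{fe.compound_id}: E_LUMO ({fe.e_lumo}) <= E_HOMO ({fe.e_homo}); "
            "gap is non-positive and omega is undefined"
        )
    gap = fe.e_lumo - fe.e_homo
    eta = gap / 2.0
    mu = (fe.e_homo + fe.e_lumo) / 2.0
    return GlobalReactivity(
        compound_id=fe.compound_id,
        e_homo=fe.e_homo,
        e_lumo=fe.e_lumo,
        gap=gap,
        ionization_potential=-fe.e_homo,
        electron_affinity=-fe.e_lumo,
        hardness=eta,
        chemical_potential=mu,
        electronegativity=-mu,
        electrophilicity=mu * mu / (2.0 * eta),
    )


@dataclass(frozen=True)
class RankingResult:
    key: str
    order: tuple[str, ...]  # ascending on the key value
    argmin: str
    argmax: str

    def to_json_dict(self) -> dict:
        return {
            "key": self.key,
            "order": list(self.order),
            "argmin": self.argmin,
            "argmax": self.argmax,
        }


def rank_library(records: list[GlobalReactivity], key: str) -> RankingResult:
    """Rank compounds ascending on a descriptor; ties break lexicographically by id.

    argmin under key='gap' is the softest (most reactive) compound; argmax
    under key='electrophilicity' the strongest electrophile.
    """
    if not records:
        raise ValueError("cannot rank an empty record list")
    if key not in RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of {RANK_KEYS}")
    ordered = sorted(records, key=lambda r: (getattr(r, key), r.compound_id))
    ids = tuple(r.compound_id for r in ordered)
    return RankingResult(key=key, order=ids, argmin=ids[0], argmax=ids[-1])


def reactivity_table(records: list[GlobalReactivity], ndigits: int = 4) -> pd.DataFrame:
    """Tabulate descriptors (rounded) in the published column order plus I, A, chi."""
    rows = []
    for r in records:
        d = r.rounded(ndigits)
        rows.append(
            {
                "compound_id": r.compound_id,
                "e_homo_ev": d["e_homo"],
                "e_lumo_ev": d["e_lumo"],
                "gap_ev": d["gap"],
                "hardness_ev": d["hardness"],
                "chemical_potential_ev": d["chemical_potential"],
                "electrophilicity_ev": d["electrophilicity"],
                "ionization_potential_ev": d["ionization_potential"],
                "electron_affinity_ev": d["electron_affinity"],
                "electronegativity_ev": d["electronegativity"],
            }
        )
    return pd.DataFrame(rows)


def read_frontier_energies(path) -> list[FrontierEnergies]:
    """Read a TSV with columns compound_id, e_homo_ev, e_lumo_ev."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        FrontierEnergies(
            compound_id=str(row["compound_id"]),
            e_homo=parse_number(row["e_homo_ev"]),
            e_lumo=parse_number(row["e_lumo_ev"]),
        )
        for _, row in df.iterrows()
    ]
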