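"""ADMET level semantics and toxicity-probability banding.

The predictive models behind the descriptor tables (BBB/absorption ellipse
models, CYP2D6/hepatotoxicity classifiers, TOPKAT QSAR probabilities) are not
reimplemented; this module applies only the published level and band
semantics:

* BBB level 0-4: very high / high / medium / low / undefined penetration.
* Absorption level 0-3: good / moderate / low / very low.
* Hepatotoxicity and CYP2D6: binary nontoxic-toxic / noninhibitor-inhibitor.
* PPB: binding / nonbinding (parsed from true/false).
* log solubility bands: [-6,-4) low, [-4,-2) good, [-2,0] optimal; values
  outside [-6,0] are labelled out_of_band rather than clamped.
* AlogP98 flag: exceeds 5 (boundary value 5.0 does not flag).
* Toxicity probabilities: [0,0.30) nontoxic, [0.30,0.70) intermediate,
  [0.70,1] toxic.

All bands are half-open with the lower endpoint included; each input maps to
exactly one label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from ._util import parse_number

__all__ = [
    "AdmetRecord",
    "ToxProfile",
    "BBB_LEVELS",
    "ABSORPTION_LEVELS",
    "decode_levels",
    "solubility_band",
    "alogp98_flag",
    "topkat_band",
    "parse_topkat_cell",
    "druglikeness_report",
    "read_admet_table",
    "read_topkat_table",
    "TOX_ENDPOINTS",
]

BBB_LEVELS = {0: "very high", 1: "high", 2: "medium", 3: "low", 4: "undefined"}
ABSORPTION_LEVELS = {0: "good", 1: "moderate", 2: "low", 3: "very low"}
HEPATOTOX = {0: "nontoxic", 1: "toxic"}
CYP2D6 = {0: "noninhibitor", 1: "inhibitor"}

TOX_ENDPOINTS = (
    "rat_male_ntp",
    "mouse_male_ntp",
    "ames_mutagenicity",
    "skin_irritation",
    "aerobic_biodegradability",
)


@dataclass
class AdmetRecord:
    compound_id: str
    bbb_level: int
    absorption_level: int
    hepatotoxicity: int
    cyp2d6: int
    ppb: str  # {"binding", "nonbinding"}
    log_solubility: float
    alogp98: float
    psa_2d: float


@dataclass
class ToxProfile:
    """Toxicity probabilities in [0,1] for the five predicted endpoints."""

    compound_id: str
    rat_male_ntp: float
    mouse_male_ntp: float
    ames_mutagenicity: float
    skin_irritation: float
    aerobic_biodegradability: float

    def probabilities(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in TOX_ENDPOINTS}

    def bands(self) -> dict[str, str]:
        return {k: topkat_band(v) for k, v in self.probabilities().items()}


def decode_levels(rec: AdmetRecord) -> dict[str, str]:
    """Human-readable labels for the leveled descriptors of one record."""
    try:
        return {
            "bbb": BBB_LEVELS[rec.bbb_level],
            "absorption": ABSORPTION_LEVELS[rec.absorption_level],
            "hepatotoxicity": HEPATOTOX[rec.hepatotoxicity],
            "cyp2d6": CYP2D6[rec.cyp2d6],
            "ppb": rec.ppb,
        }
    except KeyError as exc:
        raise ValueError(
            f"{rec.compound_id}: out-of-range level {exc.args[0]!r}"
        ) from None


def solubility_band(value: float) -> str:
    """Band a log-solubility level value: low / good / optimal / out_of_band."""
    if -6.0 <= value < -4.0:
        return "low"
    if -4.0 <= value < -2.0:
        return "good"
    if -2.0 <= value <= 0.0:
        return "optimal"
    return "out_of_band"


def alogp98_flag(value: float) -> bool:
    """True iff AlogP98 exceeds 5 (the boundary value 5.0 does not flag)."""
    return value > 5.0


def topkat_band(p: float) -> str:
    """Band a toxicity probability: nontoxic / intermediate / toxic."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p < 0.30:
        return "nontoxic"
    if p < 0.70:
        return "intermediate"
    return "toxic"


_TOPKAT_CELL = re.compile(r"\(([^)]+)\)\s*$")


def parse_topkat_cell(cell) -> float:
    """Extract the probability from 'label (p)' cells or bare numerics.

    >>> parse_topkat_cell("non-carcinogen (0.000)")
    0.0
    """
    if isinstance(cell, (int, float)):
        return float(cell)
    text = str(cell).strip()
    m = _TOPKAT_CELL.search(text)
    return parse_number(m.group(1)) if m else parse_number(text)


def _parse_ppb(value) -> str:
    text = str(value).strip().lower()
    if text in ("true", "binding", "1"):
        return "binding"
    if text in ("false", "nonbinding", "0"):
        return "nonbinding"
    raise ValueError(f"unrecognized PPB value {value!r}")


def read_admet_table(path) -> list[AdmetRecord]:
    """Read a descriptor CSV with the published column set."""
    df = pd.read_csv(path, comment="#")
    return [
        AdmetRecord(
            compound_id=str(r["compound_id"]),
            bbb_level=int(r["bbb_level"]),
            absorption_level=int(r["absorption_level"]),
            hepatotoxicity=int(r["hepatotoxicity"]),
            cyp2d6=int(r["cyp2d6"]),
            ppb=_parse_ppb(r["ppb"]),
            log_solubility=parse_number(r["log_solubility"]),
            alogp98=parse_number(r["alogp98"]),
            psa_2d=parse_number(r["psa_2d"]),
        )
        for _, r in df.iterrows()
    ]


def read_topkat_table(path) -> list[ToxProfile]:
    """Read a toxicity CSV; cells may be 'label (p)' strings or bare numbers."""
    df = pd.read_csv(path, comment="#")
    return [
        ToxProfile(
            compound_id=str(r["compound_id"]),
            **{k: parse_topkat_cell(r[k]) for k in TOX_ENDPOINTS},
        )
        for _, r in df.iterrows()
    ]


def druglikeness_report(
    admet: list[AdmetRecord],
    tox: list[ToxProfile],
    lipinski: dict[str, int] | None = None,
    library_ids: list[str] | None = None,
) -> dict:
    """Consolidated per-compound verdicts plus library-level summary counts.

    ``lipinski`` maps compound id -> violation count (optional).
    ``library_ids`` restricts the summary counts to the synthesized library
    (reference drugs are excluded from e.g. the BBB-level tally).
    """
    if not admet or not tox:
        raise ValueError("empty ADMET or toxicity input")
    admet_ids = {r.compound_id for r in admet}
    tox_ids = {t.compound_id for t in tox}
    lib = set(library_ids) if library_ids is not None else admet_ids
    orphans = sorted((admet_ids ^ tox_ids) & lib)
    if orphans:
        raise ValueError(f"compound ids missing from one input: {orphans}")

    tox_by_id = {t.compound_id: t for t in tox}
    per_compound = {}
    for rec in admet:
        entry = {
            "levels": decode_levels(rec),
            "solubility_band": solubility_band(rec.log_solubility),
            "alogp98_exceeds_5": alogp98_flag(rec.alogp98),
            "psa_2d": rec.psa_2d,
        }
        t = tox_by_id.get(rec.compound_id)
        if t is not None:
            bands = t.bands()
            entry["tox_bands"] = bands
            entry["any_toxic"] = any(b == "toxic" for b in bands.values())
        if lipinski is not None and rec.compound_id in lipinski:
            entry["n_lipinski_violations"] = lipinski[rec.compound_id]
        per_compound[rec.compound_id] = entry

    lib_records = [r for r in admet if r.compound_id in lib]
    bbb_counts: dict[int, int] = {}
    for r in lib_records:
        bbb_counts[r.bbb_level] = bbb_counts.get(r.bbb_level, 0) + 1
    summary = {
        "n_compounds": len(lib_records),
        "bbb_level_counts": {str(k): v for k, v in sorted(bbb_counts.items())},
        "cyp2d6_inhibitors": sorted(
            r.compound_id for r in lib_records if r.cyp2d6 == 1
        ),
        "n_alogp98_flags": sum(alogp98_flag(r.alogp98) for r in lib_records),
        "alogp98_flagged": sorted(
            r.compound_id for r in lib_records if alogp98_flag(r.alogp98)
        ),
        "any_toxic_compounds": sorted(
            cid
            for cid, e in per_compound.items()
            if cid in lib and e.get("any_toxic", False)
        ),
    }
    return {"per_compound": per_compound, "summary": summary}
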