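"""Accessors for the bundled screening tables (library + published inputs)."""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

_DATA = files("ipscreen") / "data"

LIBRARY_IDS = [f"4{c}" for c in "abcdefghijklmno"]

_FILES = {
    "compounds": "compounds.tsv",
    "physchem_reference": "physchem_reference.tsv",
    "frontier_energies": "frontier_energies.tsv",
    "reactivity_reference": "reactivity_reference.tsv",
    "fdps_dock_scores": "fdps_dock_scores.csv",
    "pde3b_dock_scores": "pde3b_dock_scores.csv",
    "fdps_hbond_contacts": "fdps_hbond_contacts.csv",
    "pde3b_hbond_contacts": "pde3b_hbond_contacts.csv",
    "admet_profiles": "admet_profiles.csv",
    "topkat_tox": "topkat_tox.csv",
    "fukui_4o": "fukui_4o.tsv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled table (see ``available()`` for names)."""
    try:
        return Path(str(_DATA / _FILES[name]))
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FILES)}") from None


def available() -> list[str]:
    return sorted(_FILES)
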