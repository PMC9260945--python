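"""End-to-end screening pipeline: configuration, orchestration, report output.

``run_pipeline`` executes the enabled stages in dependency order on the
configured input tables and produces a consolidated machine-readable report
(JSON plus a short markdown digest, and per-stage TSVs).  Re-running on
identical inputs yields byte-identical JSON: keys are sorted and every float
carries its stage's documented rounding (full precision behind ``raw``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import admet as admet_mod
from . import docking as dock_mod
from . import fukui as fukui_mod
from . import library as lib_mod
from . import reactivity as react_mod
from ._util import round_half_up

__all__ = ["RunConfig", "ScreeningReport", "ConfigError", "run_pipeline"]

log = logging.getLogger("ipscreen")

STAGES = ("descriptors", "reactivity", "fukui", "docking", "admet")


class ConfigError(ValueError):
    """Invalid run configuration (missing inputs for an enabled stage)."""


@dataclass
class RunConfig:
    """Flat pipeline configuration; file paths may be None for disabled stages."""

    stages: tuple[str, ...] = STAGES
    compounds: str | None = None
    logp_table: str | None = None  # TSV with compound_id + logp columns
    frontier_energies: str | None = None
    charges: str | None = None  # per-atom three-state charge TSV (computed mode)
    fukui_table: str | None = None  # published-style index TSV (import mode)
    dock_scores: tuple[str, ...] = ()
    hbond_contacts: tuple[str, ...] = ()
    admet: str | None = None
    topkat: str | None = None
    library_ids: tuple[str, ...] = ()  # restricts summary counts; default: all
    out_dir: str | None = None
    rounding: int = 4
    raw: bool = False  # emit full-precision floats instead of rounded

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "dock_scores", "hbond_contacts", "library_ids"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    _REQUIRES = {
        "descriptors": ("compounds",),
        "reactivity": ("frontier_energies",),
        "docking": ("dock_scores",),
        "admet": ("admet", "topkat"),
    }

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        missing: list[str] = []
        for stage in self.stages:
            for key in self._REQUIRES.get(stage, ()):
                value = getattr(self, key)
                if not value:
                    missing.append(f"{stage}: {key} not set")
                else:
                    paths = value if isinstance(value, tuple) else (value,)
                    missing += [
                        f"{stage}: {p} does not exist"
                        for p in paths
                        if not Path(p).exists()
                    ]
        if "fukui" in self.stages:
            if not (self.charges or self.fukui_table):
                missing.append("fukui: neither charges nor fukui_table set")
            for p in (self.charges, self.fukui_table):
                if p and not Path(p).exists():
                    missing.append(f"fukui: {p} does not exist")
        if missing:
            raise ConfigError("; ".join(missing))


@dataclass
class ScreeningReport:
    """Consolidated screening output: one section per executed stage."""

    sections: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"sections": self.sections, "summary": self.summary}

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=1, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Screening report", ""]
        for key, value in sorted(self.summary.items()):
            lines.append(f"- **{key}**: {value}")
        lines.append("")
        for name in sorted(self.sections):
            lines.append(f"## {name}")
            lines.append("```json")
            lines.append(json.dumps(self.sections[name], indent=1, sort_keys=True))
            lines.append("```")
            lines.append("")
        return "\n".join(lines)


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round_half_up(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig) -> ScreeningReport:
    """Execute the enabled stages in dependency order and build the report."""
    cfg.validate()
    report = ScreeningReport()
    lipinski_counts: dict[str, int] | None = None
    library_ids = list(cfg.library_ids)

    if "descriptors" in cfg.stages:
        compounds = lib_mod.read_compound_table(cfg.compounds)
        logp_map: dict[str, float] = {}
        if cfg.logp_table:
            lp = pd.read_csv(cfg.logp_table, sep="\t", comment="#")
            logp_map = dict(zip(lp["compound_id"].astype(str), lp["logp"].astype(float)))
        df = lib_mod.profile_library(compounds, logp_map)
        log.info("descriptors: %d compounds profiled", len(df))
        if not library_ids:
            library_ids = list(df["id"])
        if df["n_lipinski_violations"].notna().all():
            lipinski_counts = dict(zip(df["id"], df["n_lipinski_violations"].astype(int)))
        report.sections["descriptors"] = {
            "per_compound": {
                str(r["id"]): {
                    "mw": r["mw"],
                    "n_hba": int(r["n_hba"]),
                    "n_hbd": int(r["n_hbd"]),
                    "tpsa": r["tpsa"],
                    "logp": None if pd.isna(r["logp"]) else float(r["logp"]),
                    "n_lipinski_violations": None
                    if pd.isna(r["n_lipinski_violations"])
                    else int(r["n_lipinski_violations"]),
                }
                for _, r in df.iterrows()
            }
        }
        if lipinski_counts is not None:
            report.summary["n_lipinski_clean"] = sum(
                1 for v in lipinski_counts.values() if v == 0
            )
        _write_stage_tsv(cfg, "descriptors", df)

    if "reactivity" in cfg.stages:
        records = [
            react_mod.global_indices(fe)
            for fe in react_mod.read_frontier_energies(cfg.frontier_energies)
        ]
        table = react_mod.reactivity_table(records, cfg.rounding)
        gap_rank = react_mod.rank_library(records, "gap")
        omega_rank = react_mod.rank_library(records, "electrophilicity")
        log.info("reactivity: softest=%s", gap_rank.argmin)
        report.sections["reactivity"] = {
            "table": _round_floats(table.to_dict(orient="records"), cfg.rounding)
            if not cfg.raw
            else table.to_dict(orient="records"),
            "gap_ranking": gap_rank.to_json_dict(),
            "electrophilicity_ranking": omega_rank.to_json_dict(),
        }
        report.summary["softest_compound"] = gap_rank.argmin
        report.summary["strongest_electrophile"] = omega_rank.argmax
        _write_stage_tsv(cfg, "reactivity", table)

    if "fukui" in cfg.stages:
        if cfg.charges:
            cs = fukui_mod.read_charge_set(cfg.charges)
            ft = fukui_mod.fukui_indices(cs)
        else:
            ft = fukui_mod.read_fukui_table(cfg.fukui_table)
        calls = {}
        for kind in fukui_mod.INDEX_KINDS:
            try:
                calls[kind] = [
                    {"atom": a, "value": v} for a, v in fukui_mod.top_sites(ft, kind, 3)
                ]
            except ValueError:
                continue  # index column absent in import mode
        report.sections["fukui"] = {
            "provenance": ft.provenance,
            "compound_id": ft.compound_id,
            "top_sites": calls,
        }
        if "plus" in calls and calls["plus"]:
            report.summary["top_nucleophilic_attack_site"] = calls["plus"][0]["atom"]
        _write_stage_tsv(cfg, "fukui", ft.to_frame())

    if "docking" in cfg.stages:
        scores = pd.concat(
            [dock_mod.read_dock_scores(p) for p in cfg.dock_scores], ignore_index=True
        )
        summary = dock_mod.selectivity_matrix(scores)
        contacts = None
        if cfg.hbond_contacts:
            contacts = pd.concat(
                [dock_mod.read_hbond_contacts(p) for p in cfg.hbond_contacts],
                ignore_index=True,
            )
        section = summary.to_json_dict()
        if contacts is not None:
            section["hbond_reports"] = {
                t: dock_mod.hbond_report(contacts, summary.best_per_target[t]["ligand_id"], t)
                for t in summary.targets
            }
        report.sections["docking"] = _round_floats(section, cfg.rounding) if not cfg.raw else section
        for t in summary.targets:
            report.summary[f"best_ligand_{t}"] = summary.best_per_target[t]["ligand_id"]
        _write_stage_tsv(
            cfg, "docking_ranks", summary.rank_matrix.reset_index(names="ligand_id")
        )

    if "admet" in cfg.stages:
        records = admet_mod.read_admet_table(cfg.admet)
        tox = admet_mod.read_topkat_table(cfg.topkat)
        rep = admet_mod.druglikeness_report(
            records, tox, lipinski=lipinski_counts,
            library_ids=library_ids or None,
        )
        report.sections["admet"] = _round_floats(rep, cfg.rounding) if not cfg.raw else rep
        report.summary["n_cyp2d6_inhibitors"] = len(rep["summary"]["cyp2d6_inhibitors"])
        report.summary["n_any_toxic"] = len(rep["summary"]["any_toxic_compounds"])

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "report.md").write_text(report.to_markdown())
    return report


def _write_stage_tsv(cfg: RunConfig, name: str, df: pd.DataFrame) -> None:
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
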