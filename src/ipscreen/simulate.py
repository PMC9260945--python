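"""Seeded synthetic inputs with planted ground truths for every pipeline stage.

The generator emulates the statistical shape of the real screening inputs —
a ~15-member imidazo[1,2-a]pyridine library whose HOMO-LUMO gaps span roughly
3.3-4.1 eV with nitro-substituted (electron-withdrawing) members crowding the
soft end; docking-score columns around Normal(-120, 10) kJ/mol with one
reference drug per target near the library median; per-atom charge sets whose
electron states differ by exactly one electron; ADMET levels and toxicity
probabilities inside their documented bands.

Ground truths (softest compound, best ligand per target, Fukui hotspot atom,
toxicity band counts) are planted as strict extrema, not statistical
tendencies, so recovery tests are exact and non-flaky.  Identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .docking import read_dock_scores, read_hbond_contacts
from .fukui import ChargeSet
from .library import Compound
from .reactivity import FrontierEnergies

__all__ = ["GeneratorConfig", "generate_library", "generate_charge_sets",
           "generate_docking_tables", "generate_admet_tables", "write_fixtures"]

# Scaffold grammar: 2-aryl imidazo[1,2-a]pyridin-3-yl fused to the dimedone-
# derived enol ring; R1 methylates the pyridine ring, R2 decorates the aryl.
R1_CHOICES = ("H", "4-CH3")
R2_CHOICES = ("H", "4-Cl", "2-OH", "4-OH", "4-OMe", "4-Br", "4-NO2", "3-NO2")

_ARYL_SMILES = {
    "H": "c1ccccc1",
    "4-Cl": "c1ccc(Cl)cc1",
    "2-OH": "c1ccccc1O",
    "4-OH": "c1ccc(O)cc1",
    "4-OMe": "c1ccc(OC)cc1",
    "4-Br": "c1ccc(Br)cc1",
    "4-NO2": "c1ccc(cc1)N(=O)=O",
    "3-NO2": "c1cccc(c1)N(=O)=O",
}


def scaffold_smiles(r1: str, r2: str) -> str:
    """SMILES for the scaffold with the given R1 (pyridine) / R2 (aryl) choice."""
    if r1 not in R1_CHOICES:
        raise ValueError(f"unsupported R1 {r1!r}")
    if r2 not in _ARYL_SMILES:
        raise ValueError(f"unsupported R2 {r2!r}")
    pyr = "cc(C)cc" if r1 == "4-CH3" else "cccc"
    return f"OC1=C(C(=O)CC(C)(C)C1)c1n2{pyr}c2nc1-{_ARYL_SMILES[r2]}"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic inputs (defaults mirror the real library)."""

    seed: int = 0
    n_compounds: int = 15
    fraction_ewg: float = 4.0 / 15.0  # nitro-substituted share of the library
    gap_range: tuple[float, float] = (3.3, 4.1)  # eV
    docking_mean: float = -120.0  # kJ/mol-scale score columns
    docking_sd: float = 10.0
    targets: tuple[str, ...] = ("FDPS", "PDE3B", "CXCR4", "GABAa")
    fukui_hotspot_atom: int = 0  # index of the planted dominant acceptor atom
    softest_id: str | None = None  # default: first nitro compound
    best_ligand_per_target: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_ewg <= 1.0:
            raise ValueError("fraction_ewg must lie in [0, 1]")
        if self.gap_range[0] <= 0 or self.gap_range[1] <= self.gap_range[0]:
            raise ValueError("gap_range must satisfy 0 < min < max")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def ligand_ids(self) -> list[str]:
        return [f"c{i + 1:02d}" for i in range(self.n_compounds)]


def generate_library(cfg: GeneratorConfig):
    """Synthetic library + frontier energies with a planted softest compound.

    Nitro-substituted members (the first ``round(fraction_ewg * n)`` ids)
    occupy the smallest gaps; the planted softest gets the strict minimum.
    Returns (compounds, energies, truth).
    """
    if cfg.n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = cfg.rng(salt=1)
    ids = cfg.ligand_ids()
    n_ewg = round(cfg.fraction_ewg * cfg.n_compounds)

    compounds = []
    nitro_r2 = ("4-NO2", "3-NO2")
    plain_r2 = tuple(r for r in R2_CHOICES if "NO2" not in r)
    for i, cid in enumerate(ids):
        r1 = R1_CHOICES[i % 2]
        r2 = nitro_r2[i % 2] if i < n_ewg else plain_r2[i % len(plain_r2)]
        compounds.append(
            Compound(id=cid, smiles=scaffold_smiles(r1, r2),
                     substituents={"r1": r1, "r2": r2})
        )

    lo, hi = cfg.gap_range
    gaps = np.sort(rng.uniform(lo, hi, size=cfg.n_compounds))
    # nitro ids take the low (soft) end of the sorted gaps; the rest follow
    nitro_ids, other_ids = ids[:n_ewg], ids[n_ewg:]
    softest = cfg.softest_id or (nitro_ids[0] if nitro_ids else ids[0])
    assigned = dict(zip(nitro_ids + other_ids, gaps))
    # plant the strict minimum on the softest compound
    strict_min = gaps[0] - 0.5 * (gaps[1] - gaps[0]) if cfg.n_compounds > 1 else gaps[0]
    strict_min = max(strict_min, lo / 2.0)
    assigned[softest] = strict_min

    energies = []
    for cid in ids:
        e_homo = rng.uniform(-5.9, -5.1)
        energies.append(FrontierEnergies(cid, e_homo, e_homo + assigned[cid]))
    truth = {"softest_id": softest, "nitro_ids": nitro_ids,
             "gaps": {cid: float(assigned[cid]) for cid in ids}}
    return compounds, energies, truth


def generate_charge_sets(
    cfg: GeneratorConfig, n_atoms: int, n_sets: int = 1
) -> list[tuple[ChargeSet, int]]:
    """Charge sets with exact one-electron bookkeeping and a planted f+ hotspot.

    Per-atom shares of each one-electron transition are Dirichlet draws
    (non-negative, summing to one); the hotspot atom's share of the added
    electron is boosted above 0.5, making it the strict f+ maximum.  Returns
    (charge_set, hotspot_index) pairs.
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2")
    rng = cfg.rng(salt=2)
    hotspot = cfg.fukui_hotspot_atom % n_atoms
    out = []
    for i in range(n_sets):
        boost = rng.uniform(0.55, 0.9)  # hotspot's share of the added electron
        s_plus = rng.dirichlet(np.ones(n_atoms))
        rest = np.delete(np.arange(n_atoms), hotspot)
        s_plus[rest] *= (1.0 - boost) / s_plus[rest].sum()
        s_plus[hotspot] = boost  # strict dominant share (> 0.5 > any other)
        s_minus = rng.dirichlet(np.ones(n_atoms))
        q_neutral = rng.normal(0.0, 0.2, size=n_atoms)
        q_neutral -= q_neutral.mean()  # neutral molecule: charges sum to zero
        cs = ChargeSet(
            compound_id=f"syn{i:04d}",
            atoms=[(f"A{k + 1}", "C") for k in range(n_atoms)],
            charges_minus=q_neutral + s_minus,
            charges_neutral=q_neutral,
            charges_plus=q_neutral - s_plus,
            scheme="synthetic",
        )
        out.append((cs, hotspot))
    return out


_RESIDUE_POOL = ("Tyr 58", "Asn 59", "Arg 60", "Thr 63", "Glu 93",
                 "Arg 113", "Tyr 204", "Ser 205")


def generate_docking_tables(cfg: GeneratorConfig):
    """Score and contact tables per target with a planted strict-best ligand.

    Scores are Normal(docking_mean, docking_sd) truncated negative; the
    planted best ligand is forced to the strict minimum of every metric
    column; the single reference drug sits at the library median.  Contact
    energies lie in [-2.5, 0] kJ/mol, lengths in [2.0, 3.6] A.
    Returns (scores_df, contacts_df, truth).
    """
    if not cfg.targets:
        raise ValueError("no targets configured")
    if cfg.n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = cfg.rng(salt=3)
    ids = cfg.ligand_ids()
    metrics = ("moldock", "rerank", "interaction_energy", "steric", "hbond")
    score_rows, contact_rows, truth_best = [], [], {}
    for ti, target in enumerate(cfg.targets):
        planted = cfg.best_ligand_per_target.get(target, ids[ti % len(ids)])
        cols = {}
        for m in metrics:
            draw = rng.normal(cfg.docking_mean, cfg.docking_sd, size=cfg.n_compounds)
            cols[m] = np.minimum(draw, -1.0)  # truncate negative
        for i, lig in enumerate(ids):
            score_rows.append({"ligand_id": lig, "target_id": target,
                               **{m: cols[m][i] for m in metrics},
                               "is_reference": False})
        # force the planted ligand to the strict column minimum on every metric
        planted_idx = ids.index(planted)
        for m in metrics:
            col = cols[m]
            others_min = np.delete(col, planted_idx).min() if cfg.n_compounds > 1 else col[planted_idx]
            forced = others_min - max(1.0, cfg.docking_sd)
            score_rows[-cfg.n_compounds + planted_idx][m] = forced
        ref_row = {"ligand_id": f"ref_{target}", "target_id": target,
                   "is_reference": True}
        for m in metrics:
            vals = [score_rows[-cfg.n_compounds + i][m] for i in range(cfg.n_compounds)]
            ref_row[m] = float(np.median(vals))
        score_rows.append(ref_row)
        truth_best[target] = planted

        for lig in ids:
            n_contacts = int(rng.integers(1, 9))
            for _ in range(n_contacts):
                res = _RESIDUE_POOL[int(rng.integers(len(_RESIDUE_POOL)))]
                contact_rows.append({
                    "ligand_id": lig, "target_id": target,
                    "residue": f"{res} (N)",
                    "ligand_atom": f"O ({int(rng.integers(10, 30))})",
                    "bond_energy_kj_mol": float(rng.uniform(-2.5, 0.0)),
                    "bond_length_A": float(rng.uniform(2.0, 3.6)),
                })
    scores = pd.DataFrame(score_rows)
    contacts = pd.DataFrame(contact_rows)
    truth = {"best_ligand_per_target": truth_best}
    return scores, contacts, truth


def generate_admet_tables(cfg: GeneratorConfig):
    """ADMET descriptor and toxicity tables with recorded band ground truth.

    Levels are sampled inside their enumerated ranges, solubility in [-6, 0];
    each toxicity probability is assigned a band first (recorded as truth) and
    then drawn inside it.  Returns (admet_df, tox_df, truth).
    """
    from .admet import TOX_ENDPOINTS

    rng = cfg.rng(salt=4)
    ids = cfg.ligand_ids()
    admet_rows, tox_rows = [], []
    band_edges = {"nontoxic": (0.0, 0.30), "intermediate": (0.30, 0.70),
                  "toxic": (0.70, 1.0)}
    band_names = list(band_edges)
    band_counts = {k: 0 for k in band_names}
    tox_bands_truth = {}
    for cid in ids:
        admet_rows.append({
            "compound_id": cid,
            "bbb_level": int(rng.integers(0, 5)),
            "absorption_level": int(rng.integers(0, 4)),
            "hepatotoxicity": int(rng.integers(0, 2)),
            "cyp2d6": int(rng.integers(0, 2)),
            "ppb": bool(rng.integers(0, 2)),
            "log_solubility": float(rng.uniform(-6.0, 0.0)),
            "alogp98": float(rng.uniform(0.0, 6.0)),
            "psa_2d": float(rng.uniform(30.0, 160.0)),
        })
        bands = {}
        row = {"compound_id": cid}
        for endpoint in TOX_ENDPOINTS:
            band = band_names[int(rng.integers(3))]
            lo, hi = band_edges[band]
            # keep the draw strictly inside the half-open band
            row[endpoint] = float(rng.uniform(lo, hi - 1e-6))
            bands[endpoint] = band
            band_counts[band] += 1
        tox_rows.append(row)
        tox_bands_truth[cid] = bands
    truth = {"band_counts": band_counts, "tox_bands": tox_bands_truth}
    return pd.DataFrame(admet_rows), pd.DataFrame(tox_rows), truth


def write_fixtures(cfg: GeneratorConfig, outdir) -> dict:
    """Write the full synthetic fixture directory plus a ground-truth manifest.

    Produces the TSV/CSV schemas the consuming modules read, and returns the
    manifest (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds, energies, lib_truth = generate_library(cfg)
    pd.DataFrame({
        "id": [c.id for c in compounds],
        "smiles": [c.smiles for c in compounds],
        "r1": [c.substituents["r1"] for c in compounds],
        "r2": [c.substituents["r2"] for c in compounds],
    }).to_csv(outdir / "compounds.tsv", sep="\t", index=False)
    pd.DataFrame({
        "compound_id": [e.compound_id for e in energies],
        "e_homo_ev": [f"{e.e_homo:.6f}" for e in energies],
        "e_lumo_ev": [f"{e.e_lumo:.6f}" for e in energies],
    }).to_csv(outdir / "frontier_energies.tsv", sep="\t", index=False)

    (cs, hotspot), = generate_charge_sets(cfg, n_atoms=12, n_sets=1)
    pd.DataFrame({
        "atom_label": [a for a, _ in cs.atoms],
        "element": [e for _, e in cs.atoms],
        "q_nminus1": [f"{v:.8f}" for v in cs.charges_minus],
        "q_n": [f"{v:.8f}" for v in cs.charges_neutral],
        "q_nplus1": [f"{v:.8f}" for v in cs.charges_plus],
    }).to_csv(outdir / "charges.tsv", sep="\t", index=False)

    scores, contacts, dock_truth = generate_docking_tables(cfg)
    scores.to_csv(outdir / "dock_scores.csv", index=False, float_format="%.6f")
    contacts.to_csv(outdir / "hbond_contacts.csv", index=False, float_format="%.6f")
    admet_df, tox_df, admet_truth = generate_admet_tables(cfg)
    admet_df.to_csv(outdir / "admet.csv", index=False, float_format="%.6f")
    tox_df.to_csv(outdir / "topkat.csv", index=False, float_format="%.6f")

    manifest = {
        "seed": cfg.seed,
        "n_compounds": cfg.n_compounds,
        "library": lib_truth,
        "fukui_hotspot_atom": cs.atoms[hotspot][0],
        "docking": dock_truth,
        "admet": admet_truth,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    # every generated fixture must satisfy the consuming module's validation
    cs.validate()
    read_dock_scores(outdir / "dock_scores.csv")
    read_hbond_contacts(outdir / "hbond_contacts.csv")
    return manifest
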