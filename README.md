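# ipscreen

In-silico screening toolkit for a 15-member library of
2-arylimidazo[1,2-*a*]pyridin-3-yl cyclohexenone derivatives (`4a`–`4o`) —
drug-likeness profiling, conceptual-DFT reactivity analysis, docking-score
ranking and ADMET/toxicity rule banding, reproducible end to end from plain
tables.

It is written for computational medicinal chemists who receive heterogeneous
outputs from electronic-structure and docking engines (orbital energies,
population charges, score tables, descriptor predictions) and need a single
audited pipeline that turns them into ranked, comparable screening verdicts.

## What it computes

**Physicochemical descriptors & rule of five** (`ipscreen.library`): molecular
weight from IUPAC standard atomic weights; H-bond donor/acceptor counts (the
acceptor convention counts N and O, excluding the bridgehead aromatic nitrogen
and the nitro nitrogen); fragment-contribution topological polar surface area
(hydroxyl 20.23, carbonyl O 17.07, pyridine-type aromatic N 12.89, bridgehead
aromatic N 4.41, aromatic ether O 9.23, nitro group 45.82 Å²); and the classic
four-criterion Lipinski count (MW < 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10).

**Global reactivity** (`ipscreen.reactivity`): from frontier orbital energies,
via Koopmans' approximation (I = −E_HOMO, A = −E_LUMO),

- gap ΔE = E_LUMO − E_HOMO,
- chemical hardness η = ΔE/2,
- electronic chemical potential μ = (E_HOMO + E_LUMO)/2 (electronegativity χ = −μ),
- electrophilicity index ω = μ²/(2η),

with library rankings (softest = smallest gap = most reactive).

**Local reactivity** (`ipscreen.fukui`): condensed Fukui functions from
per-atom charges at N−1, N and N+1 electrons,
f⁺ₖ = qₖ(N) − qₖ(N+1), f⁻ₖ = qₖ(N−1) − qₖ(N), f⁰ₖ = (f⁺ₖ + f⁻ₖ)/2; each
index column sums to one (one-electron bookkeeping), and the highest positive
values call the sites of nucleophilic / electrophilic / radical attack.

**Docking summaries** (`ipscreen.docking`): ranking of MolDock / rerank /
interaction / steric / H-bond score columns (more negative = better),
strictly-better comparison against each target's reference drug,
residue-level hydrogen-bond reports, and a cross-target selectivity matrix.

**ADMET banding** (`ipscreen.admet`): published level semantics (BBB 0–4,
absorption 0–3, CYP2D6, PPB), solubility bands ([−6,−4) low, [−4,−2) good,
[−2,0] optimal), AlogP98 > 5 flag, and toxicity-probability bands
([0,0.30) nontoxic, [0.30,0.70) intermediate, [0.70,1] toxic).

**Synthetic inputs** (`ipscreen.simulate`): a seeded generator that emulates
every input's statistical shape with planted ground truths (strict extrema),
so the whole pipeline is testable without any external engine.

## Worked example

```python
from ipscreen import datasets, library, reactivity

compounds = library.read_compound_table(datasets.fixture_path("compounds"))
profile = library.profile_compound(
    next(c for c in compounds if c.id == "4a"), logp=3.56
)
print(profile.mw, profile.n_hba, profile.n_hbd, profile.tpsa,
      profile.n_lipinski_violations)
# 332.4 3 1 54.6 0

records = [reactivity.global_indices(fe)
           for fe in reactivity.read_frontier_energies(
               datasets.fixture_path("frontier_energies"))]
print(reactivity.rank_library(records, "gap").argmin)
# 4o
```

The first line is the parent compound's descriptor row: 332.40 g/mol, three
acceptors, the single enol O–H donor, 54.60 Å² of polar surface and a clean
rule-of-five verdict. The second is the softest (smallest-gap, most reactive)
member of the library — the *para*-nitro derivative `4o`.

The same analysis runs from a shell:

```bash
screen all --config config.json --out report/
screen simulate --seed 1 --out fixtures/
```

producing `report.json` / `report.md` plus per-stage TSVs, or a synthetic
fixture directory with its ground-truth manifest.

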