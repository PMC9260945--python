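# Methods

## Scope and data model

The package post-processes four families of screening inputs for a library of
2-arylimidazo[1,2-*a*]pyridin-3-yl cyclohexenone derivatives: structures
(SMILES), frontier orbital energies (eV), per-atom population charges at three
electron counts (e), docking score and hydrogen-bond contact tables (kJ/mol,
Å), and predicted ADMET/toxicity descriptor tables. It deliberately computes
nothing upstream of those inputs: no electronic-structure calculation, no
docking or rescoring, no predictive ADMET/QSAR modelling, and no logP
estimation (logP is consumed as data). What the package owns are the
descriptor conventions, the banding rules and the ranking/aggregation logic —
the parts that must be exact, auditable and reproducible.

## Physicochemical descriptors

Molecular weight is the plain sum of IUPAC 2021 standard atomic weights
(conventional values, ≥ 3 decimals), reported at 2-decimal half-up rounding.
Agreement with an independent toolkit (RDKit `MolWt`) is within 0.02 g/mol on
the whole library.

Hydrogen-bond donors are O–H/N–H groups (RDKit's donor count). Acceptors use
a calibrated pharmacophore convention: every N and O accepts **except** the
bridgehead aromatic nitrogen (the ring-fusion atom with three ring bonds,
whose lone pair is in the aromatic system) and the nitro nitrogen (formally
positive); the two nitro oxygens count individually. This is the only
convention consistent with the library's published acceptor counts (3 for the
parent, 5 for the nitro members).

TPSA is a fragment-contribution sum over a closed grammar covering this
scaffold chemistry: hydroxyl 20.23, carbonyl O 17.07, two-ring-bond aromatic
N 12.89, three-ring-bond (bridgehead) aromatic N 4.41, aromatic ether O 9.23,
nitro group 45.82 Å². A polar fragment outside the grammar raises an error
naming the atom — never a silent zero — so the supported chemistry boundary
is explicit. The nitro value is the neutral-group Ertl parameterization;
RDKit's implementation scores the charged resonance form at 43.14 Å², a
documented 2.68 Å² divergence per nitro group that the cross-check tests
account for. General-purpose TPSA for arbitrary chemistry is out of scope;
delegate to a standard toolkit for that.

The Lipinski count uses the four classic criteria — MW < 500 (strict, as
printed), logP ≤ 5, HBD ≤ 5, HBA ≤ 10 (inclusive; a value exactly at an
inclusive boundary does not violate) — and "passes" means at most one
violation. TPSA is reported alongside but is **not** a violation criterion:
the library's published zero-violation verdicts are only consistent with the
4-criterion rule, whatever threshold prose may accompany the table. A profile
like the heavy bisphosphonate reference drug (680.79 g/mol) therefore reports
one violation here even where a published table prints zero; the discrepancy
is documented, not emulated.

## Global reactivity descriptors

Within Koopmans' approximation I = −E_HOMO and A = −E_LUMO. The derived
descriptors are ΔE = E_LUMO − E_HOMO, η = ΔE/2, μ = (E_HOMO + E_LUMO)/2,
χ = −μ and ω = μ²/(2η). The factor-of-two hardness convention (η = (I−A)/2,
not I−A) is fixed by consistency with every row of the published descriptor
table; both conventions exist in the literature, so it is stated here as the
package contract. Softness S = 1/(2η) is exposed as a derived accessor though
never tabulated upstream. Internal arithmetic is full precision; reported
values use half-up rounding to 4 decimals. A non-positive gap is rejected
(ω undefined) rather than propagated. Rankings sort ascending with
lexicographic id tie-breaks, so they are total and deterministic.

## Condensed Fukui functions

The charge-difference (finite-difference) form is used with signs chosen so
positive values mark susceptible sites: f⁺ₖ = qₖ(N) − qₖ(N+1),
f⁻ₖ = qₖ(N−1) − qₖ(N), f⁰ₖ their mean. Because valid input states differ by
exactly one electron, each index column sums to 1; inputs are validated to
that bookkeeping at a tolerance of 1e-3 e (loose enough for real population
analyses, tight enough to catch wrong-state files), and computed outputs
satisfy it to 1e-6.

Published per-atom tables can be imported verbatim (provenance `imported`).
No conservation check is applied in import mode: printed tables are rounded,
and the bundled one for compound `4o` is internally inconsistent (its f
columns do not follow from its q columns under any sign convention). The
import path exists precisely to aggregate and rank what was printed without
pretending to re-derive it; site calls on it reproduce the published top
sites (f⁺: O25 1.4858 then C5 0.5879; f⁻: C21 0.7955) at 4-decimal half-up
rounding.

## Docking summaries

All five score columns are read as "more negative is better". "Better than
the reference" means strictly more negative; equality is not better. Residue
identity for per-contact aggregation is (name, number), ignoring the atom in
parentheses. The per-ligand H-bond report includes the plain sum of contact
energies; this is reported **alongside** the score table's H-bond column, not
equated with it — for some ligands they coincide to rounding, but the docking
engine's H-bond score is not defined as that sum. Contact energies below
−2.5 kJ/mol (outside the usual per-contact cap) draw a warning on user data
and are a hard sanity bound on the bundled tables. Column-name aliases and
typographic minus glyphs (−, –, —) are normalized at parse time.

## ADMET and toxicity banding

All bands are half-open with the lower endpoint included, chosen once because
the upstream sources print only the ranges: solubility [−6,−4) low, [−4,−2)
good, [−2,0] optimal, anything outside labelled `out_of_band` rather than
clamped (two reference drugs fall below −6); toxicity probabilities [0,0.30)
nontoxic, [0.30,0.70) intermediate, [0.70,1] toxic. The middle toxicity band
is labelled "intermediate" (the source's word for it appears to be a typo for
the same concept). The AlogP98 flag is implemented neutrally as
"exceeds 5" without pharmacological interpretation, since upstream prose and
footnotes disagree on its direction. Level semantics (BBB 0–4, absorption
0–3, binary hepatotoxicity/CYP2D6, PPB true/false → binding/nonbinding) are
decoded as published; the confidence-ellipse geometry behind the BBB levels
is not reimplemented — ellipse membership arrives only through the levels.

## Synthetic-data generator

`ipscreen.simulate` emulates the statistical shape of each input family under
the study conditions: a 15-compound library with 4/15 nitro-substituted
members, HOMO–LUMO gaps uniform on 3.3–4.1 eV with the nitro
(electron-withdrawing) members occupying the soft end, docking columns
Normal(−120, 10) truncated negative with one reference per target at the
library median, contact energies in [−2.5, 0] kJ/mol and lengths in
[2.0, 3.6] Å, ADMET levels inside their enumerated ranges and toxicity
probabilities spread across the three bands with recorded counts.

Ground truths are planted as **strict extrema** (the softest compound gets a
strictly minimal gap; the best ligand per target is forced below every column
minimum; the Fukui hotspot atom receives a dominant > 0.5 share of the added
electron), so recovery tests are exact rather than probabilistic.
Distributional realism is secondary to that determinism by design. What the
generator does *not* emulate: correlations between metrics, pose geometry,
any real engine's numerical model, or chemistry beyond the scaffold grammar —
so passing recovery tests demonstrates the pipeline's bookkeeping and ranking
logic, not predictive validity on real engine output. Identical seeds give
byte-identical fixture files; every generated fixture passes the consuming
module's validation.

## Pipeline and numerical choices

The `screen` CLI and `run_pipeline` execute enabled stages in dependency
order from a flat JSON config, failing on configuration (missing inputs)
before any computation. Reports serialize with sorted keys and the stage's
documented rounding (half-up; 2 decimals for mass/area descriptors, 4 for
reactivity and site indices), so re-runs on identical inputs are
byte-identical; full precision is available behind `--raw`. Ties anywhere
break lexicographically on identifiers. Degenerate inputs (empty tables,
non-positive gaps, ragged ligand sets, out-of-range levels or probabilities)
raise typed errors naming the offender.

Test and acceptance runs use the library's own published scale throughout —
15 compounds, 29-atom charge tables, two docking targets — plus bulk
synthetic checks (1,000 charge sets, 100 docking tables, 10⁵ energy pairs)
chosen as comfortable statistical evidence at interactive runtimes.

## Known limitations

- The descriptor conventions (HBA exclusions, TPSA grammar) are calibrated to
  this scaffold family; they are not general-purpose replacements for
  toolkit-wide implementations.
- Imported per-atom Fukui tables are trusted as printed; the package flags
  but cannot resolve internal inconsistencies in such tables.
- Selectivity statements are rank-based over the supplied score tables; no
  statistical uncertainty is attached to docking scores.
- The rule-banding stages implement published semantics only; they inherit
  whatever biases the upstream predictive models had.
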