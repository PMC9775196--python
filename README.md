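# aquaprof

Mechanistically grounded structural profiling of aquatic toxicants.

`aquaprof` screens chemical inventories against a knowledge base of SMARTS
structural alerts and assigns each compound to a three-tier mode-of-action
hierarchy anchored in molecular initiating events (MIEs):

* **Tier 1 — domains**: *narcosis* (nonspecific baseline toxicity from
  membrane partitioning), *reactive* (intrinsic, nontargeted chemical
  reactivity) and *specific* (targeted interaction at a defined biomolecule,
  receptor or pathway).
* **Tier 2 — mechanistic groups** (ten, e.g. `2.1` electrophilic,
  `3.3` cellular function disruption).
* **Tier 3 — mechanistic subgroups** (twenty-five, e.g. `3.3.1` amino acid
  biosynthesis disruption), each anchored in one or more MIEs, which in turn
  own the structural alerts.

It is intended for ecotoxicologists and risk assessors who need a
transparent, rule-based first-pass screen of large substance lists — e.g.
for read-across grouping, prioritization, or gap-filling where experimental
aquatic-toxicity data are absent.

## The classification procedure

An alert is an ordered conjunction of SMARTS patterns `s₁ ∧ s₂ ∧ …` (every
pattern must embed in the molecule), optionally vetoed by exclusion
patterns, and annotated with the taxonomic applicability of its MIE
("all taxa and species", *Eukaryota*, *Arthropoda*, *Daphnia magna*, …).

Profiling is **two-phase and sequential**. Phase 1 applies, concurrently,
every alert from the reactive and specific domains together with the
enhanced-narcosis rules (group `1.2`: polar narcotics, alkyl amines,
carboxylic acid esters, surfactants); a compound may accrue any number of
matches across these (multi-label output is deliberate — the profiler flags
every plausible MIE rather than electing a single verdict). Only compounds
with **no** phase-1 match proceed to phase 2, where the nonpolar-narcosis
rules (group `1.1`) are applied. A compound with a reactive, specific or
enhanced-narcosis assignment can therefore never additionally be labelled a
nonpolar narcotic. Compounds silent in both phases are *unclassified*
(outside the profiler's domain).

Before profiling, structures are standardized: SMILES parsing and
canonicalization, salt stripping (the dominant carbon-containing fragment
is kept), stereochemistry deletion, and removal of duplicates, inorganics
and mixtures — every rejection is logged with a reason.

The shipped core knowledge base registers the complete scheme skeleton
(3 domains / 10 groups / 25 subgroups) and 42 alerts spanning all three
domains, each validated against embedded positive and negative example
molecules. The YAML format (documented by `src/aquaprof/data/kb_schema.json`)
scales to arbitrarily large user-supplied rule sets.

## Worked example

```bash
cat > demo.smi <<'EOF'
CCCCCC hexane
C=CC(=O)OC methyl-acrylate
CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1 parathion
CC(C)C1(C)N=C(c2ncccc2C(=O)O)NC1=O imazapyr
OC(=O)CCC(=O)O succinic-acid
CCO.Cl ethanol-hydrochloride
EOF
aquaprof profile --input demo.smi --output results.csv --summary summary.json
```

prints `profiled 6 compounds: 5 classified, 1 unclassified, 0 rejected
during prep`, and `results.csv` holds one row per match:

```
            record_id       status  phase   alert_id subgroup_id domain_name                 taxa
               hexane   classified      2 1.1.1-SA01       1.1.1    narcosis all taxa and species
      methyl-acrylate   classified      1 1.2.3-SA01       1.2.3    narcosis all taxa and species
      methyl-acrylate   classified      1 2.1.1-SA01       2.1.1    reactive all taxa and species
            parathion   classified      1 1.2.1-SA03       1.2.1    narcosis all taxa and species
            parathion   classified      1 3.1.1-SA01       3.1.1    specific              Metazoa
             imazapyr   classified      1 3.3.1-SA02       3.3.1    specific        Viridiplantae
        succinic-acid unclassified                
ethanol-hydrochloride   classified      2 1.1.1-SA04       1.1.1    narcosis all taxa and species
```

Reading the output: hexane matches nothing in phase 1 and falls through to
the nonpolar-narcosis rules (phase 2). Methyl acrylate is simultaneously an
ester narcotic and a Michael-acceptor soft electrophile — and, having
phase-1 matches, is barred from the nonpolar-narcosis label. Parathion is
both a nitroaromatic polar narcotic and an organophosphorus
acetylcholinesterase inhibitor (a *specific* assignment applicable to
Metazoa). Imazapyr receives exactly one match: the imidazolinone
acetolactate-synthase alert under amino acid biosynthesis disruption.
Succinic acid lies outside the profiler's domain. The hydrochloride salt of
ethanol is stripped to its parent before profiling. `summary.json` reports
the aggregate: 16.7 % unclassified, alerts-per-compound histogram
`{1: 3, 2: 2, 3+: 0}`, and per-domain/group/subgroup compound counts.

Other subcommands: `aquaprof validate-kb`, `kb-summary`, `prep`,
`summarize`, `sankey` (inventory → domain → group → subgroup flow table),
`compare` (harmonize an external Verhaar/Russom/MechoA output onto the
three domains and cross-tabulate), and `fixtures` (deterministic test
inventories with expectation manifests). Every subcommand is a thin wrapper
over the library API (`aquaprof.profile_inventory`, `aquaprof.kb_summary`,
…).

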