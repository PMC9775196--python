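# Methods

## The classification model

`aquaprof` implements rule-based mode-of-action assignment for aquatic
toxicants. The organizing principle is the molecular initiating event
(MIE): the first chemical–biomolecule interaction of an adverse outcome
pathway. Every structural alert is owned by exactly one MIE, every MIE by
exactly one Tier 3 mechanistic subgroup, every subgroup by one Tier 2
group, and every group by one of the three Tier 1 domains (narcosis,
reactive, specific). The hierarchy is a strict tree; lineage is derivable
from the dotted ids (`3.3.1` sits in group `3.3`, domain `3`) and this
prefix consistency is validator-enforced.

An alert fires on a molecule when **all** SMARTS in its sequence embed at
least once and **no** exclusion pattern embeds. The sequence-as-conjunction
reading covers the stepwise multi-pattern rules needed for classes such as
surfactants (e.g. quaternary nitrogen ∧ C8 alkyl chain), while exclusions
express vetoes that SMARTS conjunctions cannot (e.g. "an ether, but not an
epoxide"). Duplicate embeddings of a pattern count once; the reported atom
indices are the first embedding of the first pattern and are a reporting
detail only.

### The two-phase sequential workflow

Phase 1 evaluates, concurrently, every alert whose domain is reactive or
specific, plus the enhanced-narcosis group `1.2`. All matches are
collected; there is no short-circuiting and no ranking, because the tool's
contract is to flag every alert associated with an MIE, not to elect a
single mechanism. Phase 2 (nonpolar narcosis, group `1.1`) is evaluated
only for compounds with zero phase-1 matches. Consequences that the test
suite asserts as invariants:

* no result ever combines a group-`1.1` match with any other match;
* a compound whose only would-be matches are exclusion-vetoed proceeds to
  phase 2 exactly like an unmatched compound;
* batch profiling is stateless: results are independent of batch
  composition and order.

## Structure standardization

Standardization is deterministic: parse → collapse repeated identical
fragments → drop carbon-free fragments (salt stripping) → mixture check →
keep the dominant organic fragment → delete stereochemistry →
canonicalize (RDKit canonical SMILES). Recorded transformations are drawn
from `{salt_stripped, stereo_removed, canonicalized}`; re-standardizing a
parent is the identity apart from `canonicalized`.

Choices made where the procedure was genuinely open:

* **Salt stripping** keeps the carbon-containing fragment with the most
  heavy atoms; ties break by molecular weight, then lexicographically
  smallest canonical SMILES.
* **Mixture rule**: if two or more distinct organic fragments remain and
  the largest holds ≤ 70 % of their heavy atoms (configurable), the record
  is a mixture, not a salt, and is rejected. SMILES alone cannot
  distinguish a formulation from a salt pair; the dominance threshold is an
  explicit artifact decision.
* **No charge neutralization, no tautomer canonicalization**: profiling
  operates on the stripped parent as-is. Alerts must therefore be written
  against the ionization state the inventory records (the shipped viologen
  and quaternary-ammonium alerts target the cationic forms they are
  invariably drawn in).
* **Polymers** are undetectable from a single SMILES; an optional input
  flag rejects them as `undefined_structure`.
* Deduplication is on canonical parent SMILES, first occurrence kept, so
  permuting an inventory changes which copy survives but never the retained
  structure set.

## The core knowledge base

The shipped KB registers the complete scheme skeleton — 3 domains, 10
groups, 25 subgroups — and encodes 42 alerts across 24 MIEs. Subgroups with
no core alerts (e.g. the fatty-acid/nucleic-acid/steroid biosynthesis
subgroups of group `3.3`) are registered so that user-supplied rule sets
slot into a complete hierarchy; subgroup `2.2.1` deliberately carries one
MIE and zero alerts. The format reserves a `property_constraints` field for
rule sets that carry numeric bounds (e.g. logP windows); the core KB uses
purely structural conditions.

All SMARTS are authored against RDKit's default aromaticity perception,
applied after standardization — a KB written for another toolkit's
aromaticity model would need review, which is why the convention is stated
in the KB header.

Every alert embeds positive and negative example molecules, and the
validator enforces that each positive matches and each negative does not:
the KB carries its own per-alert oracle suite. Positive examples are
additionally **cross-annotated**: a molecule listed under one alert is also
listed under every other alert it matches, so the union of listings is the
molecule's complete expected match set. A brute-force sweep in the test
suite keeps this annotation honest.

Alert scope notes (the deliberate narrowings that keep the hand-verified
fixture expectations unambiguous):

* The nonpolar-narcosis rules are conservative class definitions
  (hydrocarbons, haloalkanes, simple ethers/alcohols/ketones, benzenoid
  hydrocarbons) with heteroatom/unsaturation exclusions, in the tradition
  of baseline-toxicity rule sets; known under-coverage of e.g. nitriles and
  aryl halides is inherited from that tradition.
* The aniline rule requires attachment to a carbocyclic aromatic ring, so
  amino-substituted heteroarenes (e.g. triazine herbicides) are not
  double-counted as polar narcotics.
* The simple-amine rule admits only C/H/N molecules; amino acids and
  phosphonic herbicides are excluded by construction.
* The organophosphorus acetylcholinesterase alert requires both O/S
  substituents esterified to carbon, separating inhibitors (parathion,
  dichlorvos, malathion) from free phosphonic acids (glyphosate,
  glufosinate), which belong to amino-acid-biosynthesis disruption.
* The carboxylic-ester narcosis rule excludes anhydrides and carbamate
  esters; carbamates are screened as acetylcholinesterase inhibitors.

## Fixtures and what passing them shows

`build_fixture_inventory(seed, n_decoys)` emits, deterministically: every
cross-annotated positive example (expected match set = union of listings,
reduced by the phase rule), four preprocessing probes (a sodium salt, an
inorganic, a respelled duplicate, a stereo centre), and `n_decoys` unique
linear alkanes/primary alcohols whose only possible label is the
corresponding nonpolar-narcosis alert in phase 2. The decoy chain-length
range scales with the requested count so the unique pool never exhausts.

The fixture screen exercises rule logic, not chemical-space realism: the
molecules are small, single-intent exemplars, and the decoys are trivially
inert chemistry. Passing it demonstrates that the engine applies alerts and
the sequential rule exactly as specified on structures whose ground truth
is hand-derivable; it says nothing about coverage or alert quality on real
inventories, which depend on the completeness of the rule set in use (the
core KB is a representative subset, not the full published rule set, which
the format is designed to host).

Problem sizes used throughout (tests and the acceptance script) are
desk-scale by design — a few hundred compounds and 42 alerts — since every
expectation is hand-verified; the engine itself is linear in
|compounds| × |alerts|.

## Reporting and harmonization

* Coverage summaries count a compound once per domain/group/subgroup it
  touches; the alerts-per-compound histogram is binned 1 / 2 / 3+ with the
  full distribution also emitted.
* Flow tables preserve multi-membership (one unit per category incidence),
  so totals at finer tiers may exceed coarser-tier compound counts; this is
  a property of multi-label classification, not double-counting error.
* Domain proportions default to **exclusive mode** — the denominator is
  compound-domain incidences, so per-inventory proportions sum to exactly
  1 — with a multi-label mode (denominator = compounds, sums may exceed 1)
  available, since either convention is defensible for multi-domain
  compounds.
* Interscheme harmonization maps native class labels of external rule sets
  (Verhaar, Russom, MechoA) onto {narcotic, reactive, specific,
  unclassified_or_out_of_domain}. The shipped mapping covers the commonly
  exercised labels (Verhaar 1–5, Russom 6, MechoA 1.1–1.3) plus an identity
  mapping for already-harmonized labels (making harmonization idempotent);
  complete scheme-version-specific mappings are user-suppliable CSVs.
  Unknown labels are carried through with a null harmonized value and
  reported, never dropped. Concordance is a 4×4 contingency over the shared
  record space, one unit per label pair for multi-label records, with raw
  coverage (any non-unclassified label) reported per scheme. Russom-style
  "narcotic by default" outputs are comparable via an applicability-domain
  flag when the source provides one, since their narcotic class is not
  evidence of an alert hit.

## Known limitations

* The core KB is a 42-alert subset: absolute coverage numbers from it are
  not meaningful for real inventories.
* SMARTS-based rules cannot express molecule-level counting constraints
  (e.g. "mononitro only") except through explicit exclusions; some alerts
  are correspondingly broader than their narrowest literature definitions,
  which the multi-label design absorbs.
* No potency, no consensus mechanism call, no applicability-domain model of
  its own: an unclassified result means "no rule fired", not "nontoxic".
* InChI-based deduplication, charge/tautomer normalization and structure
  depiction are out of scope.
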