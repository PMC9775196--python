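"""Desk-scale fixture generation.

Builds small, fully hand-verifiable inventories for exercising the whole
pipeline: every positive example embedded in the knowledge base becomes a
manifest row whose expected match set is the union of the alerts listing
it (with the two-phase rule applied), plus preprocessing probes (a salt,
an inorganic, a duplicate spelling, a stereo centre) and randomized decoy
molecules drawn only from chemistry provably inert under the reactive and
specific alerts — linear saturated alkanes and primary alcohols — so the
expected nonpolar-narcosis label is derivable without ambiguity.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from rdkit import Chem

from .kb import AlertKB, NONPOLAR_NARCOSIS_GROUP
from .prep import RawRecord

__all__ = ["ManifestRow", "FixtureManifest", "positive_examples", "build_fixture_inventory"]


@dataclass(frozen=True)
class ManifestRow:
    record_id: str
    smiles: str
    expected_status: str  # classified | unclassified | rejected
    expected_alert_ids: frozenset[str]
    expected_phase: int | None
    expected_rejection_reason: str = ""
    notes: str = ""


@dataclass
class FixtureManifest:
    rows: list[ManifestRow] = field(default_factory=list)
    #: alerts with no positive example anywhere in the KB
    gap_alert_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.record_id,
                    r.smiles,
                    r.expected_status,
                    ";".join(sorted(r.expected_alert_ids)),
                    "" if r.expected_phase is None else r.expected_phase,
                    r.expected_rejection_reason,
                    r.notes,
                )
                for r in self.rows
            ],
            columns=[
                "record_id",
                "smiles",
                "expected_status",
                "expected_alert_ids",
                "expected_phase",
                "expected_rejection_reason",
                "notes",
            ],
        )


def _apply_phase_rule(kb: AlertKB, alert_ids: frozenset[str]) -> tuple[frozenset[str], int | None]:
    """Reduce a static match set to the sequential-workflow outcome."""
    phase1 = {a for a in alert_ids if kb.group_of_alert(a) != NONPOLAR_NARCOSIS_GROUP}
    if phase1:
        return frozenset(phase1), 1
    if alert_ids:
        return frozenset(alert_ids), 2
    return frozenset(), None


def positive_examples(kb: AlertKB) -> FixtureManifest:
    """Extract every positive example in the KB into a runnable manifest.

    The expected match set of a molecule is the union of all alerts that
    list it as a positive example (the KB is cross-annotated), reduced by
    the two-phase sequential rule.  Alerts lacking any positive example are
    reported in ``gap_alert_ids``.
    """
    by_canonical: dict[str, set[str]] = {}
    order: list[str] = []
    gaps = []
    for alert in kb.alerts.values():
        if not alert.positive_examples:
            gaps.append(alert.id)
        for smi in alert.positive_examples:
            mol = Chem.MolFromSmiles(smi)
            canonical = Chem.MolToSmiles(mol) if mol is not None else smi
            if canonical not in by_canonical:
                by_canonical[canonical] = set()
                order.append(canonical)
            by_canonical[canonical].add(alert.id)
    rows = []
    for i, canonical in enumerate(order, start=1):
        expected, phase = _apply_phase_rule(kb, frozenset(by_canonical[canonical]))
        rows.append(
            ManifestRow(
                record_id=f"FIX-{i:03d}",
                smiles=canonical,
                expected_status="classified",
                expected_alert_ids=expected,
                expected_phase=phase,
                notes="curated positive example",
            )
        )
    return FixtureManifest(rows=rows, gap_alert_ids=tuple(gaps))


#: Preprocessing probes: (suffix, smiles, status, reason, notes).  The
#: duplicate probe respells ethanol, a curated positive of the aliphatic
#: alcohol rule, and must come after the curated block.
_PROBES = [
    ("SALT", "CCCCCCCC(=O)O.[Na+]", "unclassified", "", "sodium salt; parent octanoic acid is alert-free"),
    ("INORGANIC", "[Na+].[Cl-]", "rejected", "inorganic", "no carbon-containing fragment"),
    ("DUPLICATE", "OCC", "rejected", "duplicate", "ethanol respelled; collapses onto curated record"),
    ("STEREO", "C[C@H](N)C(=O)O", "unclassified", "", "alanine; stereo centre removed during prep"),
]


def _decoy_pool_entry(kind: str, length: int) -> tuple[str, str]:
    """(smiles, expected alert id) for a decoy scaffold."""
    if kind == "alkane":
        return "C" * length, "1.1.1-SA01"
    return "C" * length + "O", "1.1.1-SA04"  # linear primary alcohol


def build_fixture_inventory(
    seed: int, n_decoys: int = 0, kb: AlertKB | None = None
) -> tuple[list[RawRecord], FixtureManifest]:
    """Curated manifest molecules + preprocessing probes + ``n_decoys`` decoys.

    Deterministic for a fixed seed.  Decoys are unique linear alkanes and
    primary alcohols (chain length from 3 up to a bound that scales with
    ``n_decoys``) not colliding with any curated parent, each expected to
    receive exactly its nonpolar-narcosis label in the second pass.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    if kb is None:
        from .kb import load_core_kb

        kb = load_core_kb()
    manifest = positive_examples(kb)
    records = [
        RawRecord(record_id=row.record_id, smiles=row.smiles, source="fixture")
        for row in manifest.rows
    ]
    rows = list(manifest.rows)
    for suffix, smiles, status, reason, notes in _PROBES:
        rid = f"PROBE-{suffix}"
        records.append(RawRecord(record_id=rid, smiles=smiles, source="fixture"))
        rows.append(
            ManifestRow(
                record_id=rid,
                smiles=smiles,
                expected_status=status,
                expected_alert_ids=frozenset(),
                expected_phase=None,
                expected_rejection_reason=reason,
                notes=notes,
            )
        )

    used = {Chem.MolToSmiles(Chem.MolFromSmiles(r.smiles)) for r in records if Chem.MolFromSmiles(r.smiles)}
    rng = random.Random(seed)
    max_length = 20 + 2 * n_decoys  # keeps the unique pool larger than the request
    n_emitted = 0
    while n_emitted < n_decoys:
        kind = rng.choice(["alkane", "alcohol"])
        length = rng.randint(3, max_length)
        smiles, alert_id = _decoy_pool_entry(kind, length)
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
        if canonical in used:
            continue
        used.add(canonical)
        n_emitted += 1
        rid = f"DEC-{n_emitted:03d}"
        records.append(RawRecord(record_id=rid, smiles=smiles, source="fixture"))
        rows.append(
            ManifestRow(
                record_id=rid,
                smiles=smiles,
                expected_status="classified",
                expected_alert_ids=frozenset({alert_id}),
                expected_phase=2,
                notes=f"decoy {kind}",
            )
        )
    return records, FixtureManifest(rows=rows, gap_alert_ids=manifest.gap_alert_ids)


def write_fixture_inventory(
    records: Sequence[RawRecord], manifest: FixtureManifest, outdir: str | Path
) -> tuple[Path, Path]:
    """Write inventory.smi and manifest.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inv = outdir / "inventory.smi"
    inv.write_text("".join(f"{r.smiles} {r.record_id}\n" for r in records))
    man = outdir / "manifest.csv"
    manifest.to_frame().to_csv(man, index=False)
    return inv, man
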