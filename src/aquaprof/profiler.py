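"""Two-phase sequential alert profiling.

Compounds are screened in two passes.  In the first pass every alert from
the reactive and specific domains is evaluated concurrently, together with
the enhanced-narcosis rules (group 1.2); a compound may accrue any number
of matches across these.  Only compounds left entirely unmatched proceed
to the second pass, where the nonpolar-narcosis rules (group 1.1) are
applied.  A compound with a reactive, specific or enhanced-narcosis
assignment therefore can never additionally be labelled a nonpolar
narcotic.

Within a pass, evaluation order is irrelevant and all matches are
collected — the profiler flags every alert associated with a molecular
initiating event rather than electing a single verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from rdkit import Chem

from .kb import AlertKB, StructuralAlert
from .prep import StandardizedCompound

__all__ = [
    "AlertMatch",
    "ProfileResult",
    "match_alert",
    "profile_compound",
    "profile_inventory",
    "results_to_frame",
]

RESULT_COLUMNS = [
    "record_id",
    "parent_smiles",
    "status",
    "phase",
    "alert_id",
    "alert_name",
    "mie_id",
    "mie_name",
    "subgroup_id",
    "subgroup_name",
    "group_id",
    "group_name",
    "domain_id",
    "domain_name",
    "taxa",
]


@dataclass(frozen=True)
class AlertMatch:
    """One fired alert with its full tier lineage and taxonomic scope."""

    alert_id: str
    alert_name: str
    mie_id: str
    mie_name: str
    subgroup_id: str
    subgroup_name: str
    group_id: str
    group_name: str
    domain_id: int
    domain_name: str
    taxa: tuple[str, ...]
    matched_atom_indices: tuple[int, ...]


@dataclass(frozen=True)
class ProfileResult:
    """Multi-label classification of one compound."""

    record_id: str
    parent_smiles: str
    matches: tuple[AlertMatch, ...]
    phase: int | None  # 1, 2, or None when unclassified

    @property
    def status(self) -> str:
        return "classified" if self.matches else "unclassified"

    @property
    def alert_ids(self) -> frozenset[str]:
        return frozenset(m.alert_id for m in self.matches)


def _mol_for(compound: StandardizedCompound) -> Chem.Mol:
    mol = Chem.MolFromSmiles(compound.parent_smiles)
    if mol is None:
        raise ValueError(
            f"record {compound.record_id!r}: parent SMILES "
            f"{compound.parent_smiles!r} is not parseable; was it standardized?"
        )
    return mol


def _evaluate(mol: Chem.Mol, alert: StructuralAlert) -> tuple[int, ...] | None:
    """First-embedding atom indices if the alert fires, else None."""
    patterns, exclusions = alert.compiled()
    first = mol.GetSubstructMatch(patterns[0])
    if not first:
        return None
    for pat in patterns[1:]:
        if not mol.HasSubstructMatch(pat):
            return None
    if any(mol.HasSubstructMatch(pat) for pat in exclusions):
        return None
    return tuple(first)


def match_alert(
    compound: StandardizedCompound, alert: StructuralAlert, kb: AlertKB
) -> AlertMatch | None:
    """Evaluate one alert against one compound, ignoring phase logic.

    The alert fires iff every SMARTS in its sequence embeds at least once
    in the molecule and no exclusion pattern matches.  Duplicate embeddings
    count once; the reported atom indices are the first embedding of the
    first pattern in canonical atom order.
    """
    return _match_alert_mol(_mol_for(compound), alert, kb)


def _match_alert_mol(mol: Chem.Mol, alert: StructuralAlert, kb: AlertKB) -> AlertMatch | None:
    atoms = _evaluate(mol, alert)
    if atoms is None:
        return None
    mie, sub, grp, dom = kb.lineage(alert.id)
    return AlertMatch(
        alert_id=alert.id,
        alert_name=alert.name,
        mie_id=mie.id,
        mie_name=mie.name,
        subgroup_id=sub.id,
        subgroup_name=sub.name,
        group_id=grp.id,
        group_name=grp.name,
        domain_id=dom.id,
        domain_name=dom.name,
        taxa=alert.taxa,
        matched_atom_indices=atoms,
    )


def profile_compound(compound: StandardizedCompound, kb: AlertKB) -> ProfileResult:
    """Profile one compound through the two-phase sequential workflow."""
    mol = _mol_for(compound)
    matches = [
        m
        for alert in kb.phase1_alerts()
        if (m := _match_alert_mol(mol, alert, kb)) is not None
    ]
    if matches:
        return ProfileResult(compound.record_id, compound.parent_smiles, tuple(matches), 1)
    matches = [
        m
        for alert in kb.phase2_alerts()
        if (m := _match_alert_mol(mol, alert, kb)) is not None
    ]
    if matches:
        return ProfileResult(compound.record_id, compound.parent_smiles, tuple(matches), 2)
    return ProfileResult(compound.record_id, compound.parent_smiles, (), None)


def profile_inventory(
    compounds: Sequence[StandardizedCompound], kb: AlertKB
) -> list[ProfileResult]:
    """Profile a batch; results are element-wise and order-preserving."""
    return [profile_compound(c, kb) for c in compounds]


def results_to_frame(results: Sequence[ProfileResult]) -> pd.DataFrame:
    """Long-form results table: one row per match, one row per unclassified compound."""
    rows = []
    for r in results:
        if not r.matches:
            rows.append(
                {
                    "record_id": r.record_id,
                    "parent_smiles": r.parent_smiles,
                    "status": r.status,
                    "phase": "",
                    "alert_id": "",
                    "alert_name": "",
                    "mie_id": "",
                    "mie_name": "",
                    "subgroup_id": "",
                    "subgroup_name": "",
                    "group_id": "",
                    "group_name": "",
                    "domain_id": "",
                    "domain_name": "",
                    "taxa": "",
                }
            )
            continue
        for m in r.matches:
            rows.append(
                {
                    "record_id": r.record_id,
                    "parent_smiles": r.parent_smiles,
                    "status": r.status,
                    "phase": r.phase,
                    "alert_id": m.alert_id,
                    "alert_name": m.alert_name,
                    "mie_id": m.mie_id,
                    "mie_name": m.mie_name,
                    "subgroup_id": m.subgroup_id,
                    "subgroup_name": m.subgroup_name,
                    "group_id": m.group_id,
                    "group_name": m.group_name,
                    "domain_id": m.domain_id,
                    "domain_name": m.domain_name,
                    "taxa": ";".join(m.taxa),
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
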