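"""Structure standardization for inventory screening.

Raw inventory records are reduced to profilable *parent* structures:
SMILES are parsed and canonicalized, salt/counter-ion fragments stripped,
and stereochemical information deleted.  Records that cannot yield a
single organic parent — unparseable SMILES, inorganics, genuine mixtures,
polymers flagged in the source — are rejected with an auditable reason,
and duplicate parents are collapsed to their first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "RawRecord",
    "StandardizedCompound",
    "Rejection",
    "RejectionLog",
    "REJECTION_REASONS",
    "standardize_structure",
    "preprocess_inventory",
    "DEFAULT_MIXTURE_THRESHOLD",
]

REJECTION_REASONS = (
    "unparseable",
    "inorganic",
    "mixture",
    "undefined_structure",
    "duplicate",
)

#: A record is a mixture (rather than a salt) when, after dropping
#: carbon-free fragments, two or more organic fragments remain and the
#: largest holds no more than this share of their heavy atoms.
DEFAULT_MIXTURE_THRESHOLD = 0.7


@dataclass(frozen=True)
class RawRecord:
    """One raw inventory entry as read from file."""

    record_id: str
    smiles: str
    source: str = ""
    polymer_flag: bool = False


@dataclass(frozen=True)
class StandardizedCompound:
    """A standardized parent structure with transformation provenance."""

    record_id: str
    parent_smiles: str
    transformations: tuple[str, ...]
    n_fragments_removed: int = 0
    source: str = ""


@dataclass(frozen=True)
class Rejection:
    record_id: str
    reason: str
    detail: str = ""


@dataclass
class RejectionLog:
    rows: list[Rejection] = field(default_factory=list)

    def add(self, record_id: str, reason: str, detail: str = "") -> None:
        assert reason in REJECTION_REASONS, reason
        self.rows.append(Rejection(record_id, reason, detail))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.record_id, r.reason, r.detail) for r in self.rows],
            columns=["record_id", "reason", "detail"],
        )


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(atom.GetAtomicNum() == 6 for atom in mol.GetAtoms())


def _has_stereo(mol: Chem.Mol) -> bool:
    if any(a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()):
        return True
    return any(b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds())


def _fragment_sort_key(mol: Chem.Mol) -> tuple:
    # largest heavy-atom count wins; ties by molecular weight, then by
    # lexicographically smallest canonical SMILES
    return (-mol.GetNumHeavyAtoms(), -Descriptors.MolWt(mol), Chem.MolToSmiles(mol))


def standardize_structure(
    raw: RawRecord, mixture_threshold: float = DEFAULT_MIXTURE_THRESHOLD
) -> Union[StandardizedCompound, Rejection]:
    """Standardize one raw record, or reject it with a reason code.

    The pipeline is deterministic: parse → drop carbon-free (salt)
    fragments → mixture check → keep the dominant organic fragment →
    delete stereochemistry → canonicalize.
    """
    if raw.polymer_flag:
        return Rejection(raw.record_id, "undefined_structure", "flagged as polymer")
    mol = Chem.MolFromSmiles(raw.smiles) if raw.smiles else None
    if mol is None:
        return Rejection(raw.record_id, "unparseable", f"SMILES {raw.smiles!r}")

    frags = list(Chem.GetMolFrags(mol, asMols=True))
    # collapse repeated identical fragments (e.g. doubled counter-ions or a
    # structure recorded twice) before the salt/mixture logic
    unique: dict[str, Chem.Mol] = {}
    for f in frags:
        unique.setdefault(Chem.MolToSmiles(f), f)
    frags = list(unique.values())
    organic = [f for f in frags if _has_carbon(f)]
    if not organic:
        return Rejection(raw.record_id, "inorganic", "no carbon-containing fragment")

    transformations: list[str] = []
    n_removed = len(frags) - 1
    if len(organic) >= 2:
        heavy = [f.GetNumHeavyAtoms() for f in organic]
        if max(heavy) <= mixture_threshold * sum(heavy):
            return Rejection(
                raw.record_id,
                "mixture",
                f"{len(organic)} organic fragments, largest holds "
                f"{max(heavy)}/{sum(heavy)} heavy atoms",
            )
    parent = sorted(organic, key=_fragment_sort_key)[0]
    if n_removed:
        transformations.append("salt_stripped")

    if _has_stereo(parent):
        Chem.RemoveStereochemistry(parent)
        transformations.append("stereo_removed")
    transformations.append("canonicalized")

    return StandardizedCompound(
        record_id=raw.record_id,
        parent_smiles=Chem.MolToSmiles(parent),
        transformations=tuple(transformations),
        n_fragments_removed=n_removed,
        source=raw.source,
    )


def preprocess_inventory(
    records: Sequence[RawRecord],
    mixture_threshold: float = DEFAULT_MIXTURE_THRESHOLD,
) -> tuple[list[StandardizedCompound], RejectionLog]:
    """Standardize an inventory and collapse duplicate parents.

    Every input record lands in exactly one of the two outputs, so
    ``len(standardized) + len(log) == len(records)``.  The first record
    producing a given parent SMILES is kept; later spellings of the same
    structure are rejected as duplicates.
    """
    standardized: list[StandardizedCompound] = []
    log = RejectionLog()
    seen: dict[str, str] = {}
    for raw in records:
        result = standardize_structure(raw, mixture_threshold=mixture_threshold)
        if isinstance(result, Rejection):
            log.rows.append(result)
            continue
        prior = seen.get(result.parent_smiles)
        if prior is not None:
            log.add(raw.record_id, "duplicate", f"same parent as record {prior!r}")
            continue
        seen[result.parent_smiles] = raw.record_id
        standardized.append(result)
    return standardized, log


def standardized_to_frame(compounds: Iterable[StandardizedCompound]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.record_id,
                c.parent_smiles,
                ";".join(c.transformations),
                c.n_fragments_removed,
                c.source,
            )
            for c in compounds
        ],
        columns=["record_id", "parent_smiles", "transformations", "n_fragments_removed", "source"],
    )
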