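"""Tiered structural-alert knowledge base.

The knowledge base (KB) organises aquatic-toxicity structural alerts in a
three-tier mechanistic hierarchy:

* **Tier 1 — domains**: narcosis (1), reactive (2), specific (3).
* **Tier 2 — mechanistic groups**: ten groups with dotted ids such as
  ``"3.3"`` (cellular function disruption).
* **Tier 3 — mechanistic subgroups**: twenty-five subgroups such as
  ``"3.3.1"`` (amino acid biosynthesis disruption).

Each subgroup anchors one or more molecular initiating events (MIEs), and
each MIE owns zero or more structural alerts.  An alert is an ordered
conjunction of SMARTS patterns (every pattern must match the molecule),
optionally vetoed by exclusion patterns, and carries a taxonomic
applicability annotation.

KB files are YAML (canonical) or JSON with top-level keys ``metadata``,
``domains``, ``groups``, ``subgroups``, ``mies`` and ``alerts``; a JSON
Schema describing the layout ships at :func:`schema_path`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from rdkit import Chem

__all__ = [
    "TierDomain",
    "MechanisticGroup",
    "MechanisticSubgroup",
    "MIE",
    "StructuralAlert",
    "AlertKB",
    "TierSummary",
    "ValidationIssue",
    "ValidationReport",
    "KBError",
    "KBParseError",
    "KBValidationError",
    "load_kb",
    "dump_kb",
    "validate_kb",
    "kb_summary",
    "core_kb_path",
    "load_core_kb",
    "schema_path",
]

DOMAIN_NAMES = {1: "narcosis", 2: "reactive", 3: "specific"}

#: Tier-2 group ids evaluated in the first (reactive / specific / enhanced
#: narcosis) pass of the sequential workflow; everything in domains 2 and 3
#: plus enhanced narcosis ("1.2").  Nonpolar narcosis ("1.1") is reserved for
#: the second pass.
NONPOLAR_NARCOSIS_GROUP = "1.1"
ENHANCED_NARCOSIS_GROUP = "1.2"


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBParseError(KBError):
    """The KB file could not be parsed or is missing required keys."""


class KBValidationError(KBError):
    """The KB content violates a structural invariant."""


@dataclass(frozen=True)
class TierDomain:
    """A Tier 1 domain: narcosis, reactive or specific."""

    id: int
    name: str


@dataclass(frozen=True)
class MechanisticGroup:
    """A Tier 2 mechanistic group, e.g. ``"2.1"`` (electrophilic)."""

    id: str
    name: str
    domain_id: int


@dataclass(frozen=True)
class MechanisticSubgroup:
    """A Tier 3 mechanistic subgroup, e.g. ``"3.3.1"``."""

    id: str
    name: str
    group_id: str


@dataclass(frozen=True)
class MIE:
    """A molecular initiating event anchored within one subgroup."""

    id: str
    name: str
    subgroup_id: str
    description: str = ""


@dataclass(frozen=True)
class StructuralAlert:
    """One structural alert.

    ``smarts_sequence`` is a conjunction: every pattern must embed in the
    molecule for the alert to fire.  ``exclusions`` are vetoes: any match
    suppresses the alert.  ``taxa`` records the taxonomic applicability of
    the underlying MIE (e.g. ``"all taxa and species"``, ``"Viridiplantae"``).
    """

    id: str
    name: str
    smarts_sequence: tuple[str, ...]
    mie_id: str
    taxa: tuple[str, ...]
    exclusions: tuple[str, ...] = ()
    notes: str = ""
    positive_examples: tuple[str, ...] = ()
    negative_examples: tuple[str, ...] = ()

    def compiled(self) -> tuple[list[Chem.Mol], list[Chem.Mol]]:
        """Compiled (patterns, exclusion patterns); cached per instance."""
        cached = getattr(self, "_compiled", None)
        if cached is None:
            pats = [_compile_smarts(self.id, s) for s in self.smarts_sequence]
            excl = [_compile_smarts(self.id, s) for s in self.exclusions]
            cached = (pats, excl)
            object.__setattr__(self, "_compiled", cached)
        return cached

    def __eq__(self, other):  # ignore the pattern cache
        if not isinstance(other, StructuralAlert):
            return NotImplemented
        return _alert_key(self) == _alert_key(other)

    def __hash__(self):
        return hash(_alert_key(self))


def _alert_key(a: StructuralAlert):
    return (
        a.id,
        a.name,
        a.smarts_sequence,
        a.mie_id,
        a.taxa,
        a.exclusions,
        a.notes,
        a.positive_examples,
        a.negative_examples,
    )


def _compile_smarts(alert_id: str, smarts: str) -> Chem.Mol:
    pat = Chem.MolFromSmarts(smarts)
    if pat is None:
        raise KBValidationError(
            f"alert {alert_id!r}: SMARTS pattern {smarts!r} does not compile"
        )
    return pat


@dataclass
class AlertKB:
    """A fully indexed alert knowledge base.

    All collections are mappings keyed by id, preserving file order.  The
    hierarchy is a tree: every alert resolves through its MIE to a subgroup,
    group and domain.
    """

    metadata: dict
    domains: dict[int, TierDomain]
    groups: dict[str, MechanisticGroup]
    subgroups: dict[str, MechanisticSubgroup]
    mies: dict[str, MIE]
    alerts: dict[str, StructuralAlert]
    duplicate_ids: tuple[str, ...] = ()

    # -- lineage helpers -------------------------------------------------
    def lineage(self, alert_id: str) -> tuple[MIE, MechanisticSubgroup, MechanisticGroup, TierDomain]:
        alert = self.alerts[alert_id]
        mie = self.mies[alert.mie_id]
        sub = self.subgroups[mie.subgroup_id]
        grp = self.groups[sub.group_id]
        dom = self.domains[grp.domain_id]
        return mie, sub, grp, dom

    def group_of_alert(self, alert_id: str) -> str:
        return self.lineage(alert_id)[2].id

    def alerts_in_subgroup(self, subgroup_id: str) -> list[StructuralAlert]:
        return [
            a
            for a in self.alerts.values()
            if self.mies[a.mie_id].subgroup_id == subgroup_id
        ]

    def mies_in_subgroup(self, subgroup_id: str) -> list[MIE]:
        return [m for m in self.mies.values() if m.subgroup_id == subgroup_id]

    def phase1_alerts(self) -> list[StructuralAlert]:
        """Alerts evaluated first: domains 2 and 3 plus enhanced narcosis."""
        out = []
        for a in self.alerts.values():
            _, _, grp, dom = self.lineage(a.id)
            if dom.id in (2, 3) or grp.id == ENHANCED_NARCOSIS_GROUP:
                out.append(a)
        return out

    def phase2_alerts(self) -> list[StructuralAlert]:
        """Nonpolar-narcosis alerts evaluated only when phase 1 is silent."""
        return [
            a
            for a in self.alerts.values()
            if self.group_of_alert(a.id) == NONPOLAR_NARCOSIS_GROUP
        ]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "metadata": dict(self.metadata),
            "domains": [{"id": d.id, "name": d.name} for d in self.domains.values()],
            "groups": [
                {"id": g.id, "name": g.name, "domain_id": g.domain_id}
                for g in self.groups.values()
            ],
            "subgroups": [
                {"id": s.id, "name": s.name, "group_id": s.group_id}
                for s in self.subgroups.values()
            ],
            "mies": [
                {
                    "id": m.id,
                    "name": m.name,
                    "subgroup_id": m.subgroup_id,
                    **({"description": m.description} if m.description else {}),
                }
                for m in self.mies.values()
            ],
            "alerts": [
                {
                    "id": a.id,
                    "name": a.name,
                    "smarts_sequence": list(a.smarts_sequence),
                    "mie_id": a.mie_id,
                    "taxa": list(a.taxa),
                    **({"exclusions": list(a.exclusions)} if a.exclusions else {}),
                    **({"notes": a.notes} if a.notes else {}),
                    **(
                        {"positive_examples": list(a.positive_examples)}
                        if a.positive_examples
                        else {}
                    ),
                    **(
                        {"negative_examples": list(a.negative_examples)}
                        if a.negative_examples
                        else {}
                    ),
                }
                for a in self.alerts.values()
            ],
        }


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("metadata", "domains", "groups", "subgroups", "mies", "alerts")


def _as_str_tuple(value, *, where: str) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, str) or not isinstance(value, Iterable):
        raise KBParseError(f"{where}: expected a list, got {value!r}")
    return tuple(str(v) for v in value)


def load_kb(path: str | Path) -> AlertKB:
    """Load and index a KB file (YAML or JSON).

    Raises :class:`KBParseError` for malformed files and
    :class:`KBValidationError` for dangling parent references or SMARTS
    patterns that do not compile.  Loading is deterministic and independent
    of record order within each section.
    """
    path = Path(path)
    if not path.exists():
        raise KBParseError(f"KB file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise KBParseError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise KBParseError(f"{path}: KB file must be a mapping at top level")
    for key in _REQUIRED_KEYS:
        if key not in raw:
            raise KBParseError(f"{path}: missing required top-level key {key!r}")
    return build_kb(raw)


def build_kb(raw: Mapping) -> AlertKB:
    """Construct an :class:`AlertKB` from an already-parsed mapping."""
    duplicates: list[str] = []

    def index(records, make, section):
        out = {}
        for i, rec in enumerate(records or []):
            if not isinstance(rec, Mapping) or "id" not in rec:
                raise KBParseError(f"{section}[{i}]: record lacks an 'id' key")
            try:
                obj = make(rec)
            except (KeyError, TypeError, ValueError) as exc:
                raise KBParseError(f"{section} id {rec.get('id')!r}: {exc}") from exc
            if obj.id in out:
                duplicates.append(str(obj.id))
            out[obj.id] = obj
        return out

    domains = index(
        raw["domains"], lambda r: TierDomain(id=int(r["id"]), name=str(r["name"])), "domains"
    )
    groups = index(
        raw["groups"],
        lambda r: MechanisticGroup(
            id=str(r["id"]), name=str(r["name"]), domain_id=int(r["domain_id"])
        ),
        "groups",
    )
    subgroups = index(
        raw["subgroups"],
        lambda r: MechanisticSubgroup(
            id=str(r["id"]), name=str(r["name"]), group_id=str(r["group_id"])
        ),
        "subgroups",
    )
    mies = index(
        raw["mies"],
        lambda r: MIE(
            id=str(r["id"]),
            name=str(r["name"]),
            subgroup_id=str(r["subgroup_id"]),
            description=str(r.get("description", "")),
        ),
        "mies",
    )
    alerts = index(
        raw["alerts"],
        lambda r: StructuralAlert(
            id=str(r["id"]),
            name=str(r["name"]),
            smarts_sequence=_as_str_tuple(r["smarts_sequence"], where=f"alert {r['id']}"),
            mie_id=str(r["mie_id"]),
            taxa=_as_str_tuple(r.get("taxa"), where=f"alert {r['id']}"),
            exclusions=_as_str_tuple(r.get("exclusions"), where=f"alert {r['id']}"),
            notes=str(r.get("notes", "")),
            positive_examples=_as_str_tuple(
                r.get("positive_examples"), where=f"alert {r['id']}"
            ),
            negative_examples=_as_str_tuple(
                r.get("negative_examples"), where=f"alert {r['id']}"
            ),
        ),
        "alerts",
    )

    # dangling parent references are hard errors
    for g in groups.values():
        if g.domain_id not in domains:
            raise KBValidationError(
                f"group {g.id!r} references unknown domain_id {g.domain_id!r}"
            )
    for s in subgroups.values():
        if s.group_id not in groups:
            raise KBValidationError(
                f"subgroup {s.id!r} references unknown group_id {s.group_id!r}"
            )
    for m in mies.values():
        if m.subgroup_id not in subgroups:
            raise KBValidationError(
                f"MIE {m.id!r} references unknown subgroup_id {m.subgroup_id!r}"
            )
    for a in alerts.values():
        if a.mie_id not in mies:
            raise KBValidationError(
                f"alert {a.id!r} references unknown mie_id {a.mie_id!r}"
            )
        if not a.smarts_sequence:
            raise KBValidationError(f"alert {a.id!r} has an empty smarts_sequence")
        a.compiled()  # raises on invalid SMARTS, names the alert

    meta = dict(raw.get("metadata") or {})
    return AlertKB(
        metadata=meta,
        domains=domains,
        groups=groups,
        subgroups=subgroups,
        mies=mies,
        alerts=alerts,
        duplicate_ids=tuple(duplicates),
    )


def dump_kb(kb: AlertKB, path: str | Path) -> None:
    """Serialize a KB back to YAML (or JSON when the suffix is ``.json``)."""
    path = Path(path)
    data = kb.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    entity_id: str
    kind: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    n_alerts_checked: int = 0
    n_examples_checked: int = 0

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.entity_id, i.kind, i.message) for i in self.issues],
            columns=["entity_id", "kind", "message"],
        )


def _molecule_matches(mol: Chem.Mol, alert: StructuralAlert) -> bool:
    pats, excl = alert.compiled()
    if not all(mol.HasSubstructMatch(p) for p in pats):
        return False
    return not any(mol.HasSubstructMatch(p) for p in excl)


def validate_kb(kb: AlertKB) -> ValidationReport:
    """Check KB invariants and the per-alert example oracle suite.

    Failures are reported, never raised: the report lists duplicate ids,
    hierarchy id-prefix violations, empty taxa, and every positive example
    that fails to match (or negative example that matches) its own alert.
    """
    report = ValidationReport()
    add = report.issues.append

    for dup in kb.duplicate_ids:
        add(ValidationIssue(dup, "duplicate_id", f"id {dup!r} defined more than once"))

    if set(kb.domains) != set(DOMAIN_NAMES):
        add(
            ValidationIssue(
                "domains",
                "domain_set",
                f"expected domain ids {sorted(DOMAIN_NAMES)}, found {sorted(kb.domains)}",
            )
        )
    for g in kb.groups.values():
        if not g.id.startswith(f"{g.domain_id}."):
            add(
                ValidationIssue(
                    g.id, "id_prefix", f"group id {g.id!r} does not extend domain {g.domain_id}"
                )
            )
    for s in kb.subgroups.values():
        if not s.id.startswith(f"{s.group_id}."):
            add(
                ValidationIssue(
                    s.id, "id_prefix", f"subgroup id {s.id!r} does not extend group {s.group_id!r}"
                )
            )

    for alert in kb.alerts.values():
        report.n_alerts_checked += 1
        if not alert.taxa:
            add(ValidationIssue(alert.id, "taxa_empty", "alert has no taxonomic applicability"))
        for smi in alert.positive_examples:
            report.n_examples_checked += 1
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                add(ValidationIssue(alert.id, "bad_example", f"positive example {smi!r} unparseable"))
            elif not _molecule_matches(mol, alert):
                add(
                    ValidationIssue(
                        alert.id,
                        "positive_example_mismatch",
                        f"positive example {smi!r} does not match",
                    )
                )
        for smi in alert.negative_examples:
            report.n_examples_checked += 1
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                add(ValidationIssue(alert.id, "bad_example", f"negative example {smi!r} unparseable"))
            elif _molecule_matches(mol, alert):
                add(
                    ValidationIssue(
                        alert.id,
                        "negative_example_match",
                        f"negative example {smi!r} matches",
                    )
                )
    return report


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass
class TierSummary:
    """Per-subgroup MIE and alert counts plus group/domain totals."""

    per_subgroup: pd.DataFrame  # subgroup_id, subgroup_name, group_id, domain_id, n_mie, n_sa
    per_group: pd.DataFrame  # group_id, group_name, n_mie, n_sa
    per_domain: pd.DataFrame  # domain_id, domain_name, n_mie, n_sa
    n_domains: int
    n_groups: int
    n_subgroups: int
    n_mie_total: int
    n_sa_total: int

    def subgroup_counts(self, subgroup_id: str) -> tuple[int, int]:
        row = self.per_subgroup.set_index("subgroup_id").loc[subgroup_id]
        return int(row["n_mie"]), int(row["n_sa"])


def kb_summary(kb: AlertKB) -> TierSummary:
    """Tabulate distinct MIEs and structural alerts beneath every subgroup."""
    rows = []
    for s in kb.subgroups.values():
        g = kb.groups[s.group_id]
        rows.append(
            {
                "subgroup_id": s.id,
                "subgroup_name": s.name,
                "group_id": g.id,
                "domain_id": g.domain_id,
                "n_mie": len(kb.mies_in_subgroup(s.id)),
                "n_sa": len(kb.alerts_in_subgroup(s.id)),
            }
        )
    per_subgroup = pd.DataFrame(
        rows,
        columns=["subgroup_id", "subgroup_name", "group_id", "domain_id", "n_mie", "n_sa"],
    )
    if len(per_subgroup):
        per_group = (
            per_subgroup.groupby("group_id", sort=True)[["n_mie", "n_sa"]].sum().reset_index()
        )
        per_group["group_name"] = per_group["group_id"].map(
            {g.id: g.name for g in kb.groups.values()}
        )
        per_domain = (
            per_subgroup.groupby("domain_id", sort=True)[["n_mie", "n_sa"]].sum().reset_index()
        )
        per_domain["domain_name"] = per_domain["domain_id"].map(
            {d.id: d.name for d in kb.domains.values()}
        )
    else:
        per_group = pd.DataFrame(columns=["group_id", "n_mie", "n_sa", "group_name"])
        per_domain = pd.DataFrame(columns=["domain_id", "n_mie", "n_sa", "domain_name"])
    return TierSummary(
        per_subgroup=per_subgroup,
        per_group=per_group,
        per_domain=per_domain,
        n_domains=len(kb.domains),
        n_groups=len(kb.groups),
        n_subgroups=len(kb.subgroups),
        n_mie_total=len(kb.mies),
        n_sa_total=len(kb.alerts),
    )


# ---------------------------------------------------------------------------
# Shipped core KB
# ---------------------------------------------------------------------------


def core_kb_path() -> Path:
    """Path to the core alert subset shipped with the package."""
    return Path(__file__).parent / "data" / "core_kb.yaml"


def schema_path() -> Path:
    """Path to the JSON Schema documenting the KB file layout."""
    return Path(__file__).parent / "data" / "kb_schema.json"


def load_core_kb() -> AlertKB:
    """Load the core alert subset shipped with the package."""
    return load_kb(core_kb_path())
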