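"""Harmonization of external classification-scheme outputs.

First- and second-generation mode-of-action schemes (Verhaar, Russom,
MechoA) use scheme-specific class labels.  To compare them with the
three-domain hierarchy, native labels are mapped onto the common
vocabulary {narcotic, reactive, specific, unclassified_or_out_of_domain},
after which raw coverage and pairwise concordance can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "HARMONIZED_LABELS",
    "DomainMapping",
    "HarmonizedTable",
    "ConcordanceTable",
    "load_mapping",
    "default_mapping",
    "harmonize_assignments",
    "concordance",
]

HARMONIZED_LABELS = (
    "narcotic",
    "reactive",
    "specific",
    "unclassified_or_out_of_domain",
)

#: Native-class → domain assignments shipped by default.  Covers the class
#: labels commonly exercised when comparing schemes; the full mapping for a
#: given scheme version is a user-suppliable CSV.  Harmonized labels map to
#: themselves so that harmonization is idempotent.
_DEFAULT_ROWS = [
    ("verhaar", "1", "narcotic"),
    ("verhaar", "2", "narcotic"),
    ("verhaar", "3", "reactive"),
    ("verhaar", "4", "specific"),
    ("verhaar", "5", "unclassified_or_out_of_domain"),
    ("russom", "6", "specific"),
    ("mechoa", "1.1", "narcotic"),
    ("mechoa", "1.2", "narcotic"),
    ("mechoa", "1.3", "narcotic"),
] + [("harmonized", label, label) for label in HARMONIZED_LABELS]


@dataclass
class DomainMapping:
    """(scheme, native class label) → harmonized domain label."""

    table: dict[tuple[str, str], str]

    def __post_init__(self):
        for (scheme, native), harmonized in self.table.items():
            if harmonized not in HARMONIZED_LABELS:
                raise ValueError(
                    f"mapping ({scheme!r}, {native!r}): harmonized label "
                    f"{harmonized!r} is not one of {HARMONIZED_LABELS}"
                )

    def lookup(self, scheme: str, native: str) -> str | None:
        return self.table.get((str(scheme).strip().lower(), str(native).strip()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, n, h) for (s, n), h in self.table.items()],
            columns=["scheme", "native_class", "harmonized"],
        )


def default_mapping() -> DomainMapping:
    return DomainMapping({(s, n): h for s, n, h in _DEFAULT_ROWS})


def load_mapping(path: str | Path) -> DomainMapping:
    """Load a mapping CSV with columns ``scheme,native_class,harmonized``."""
    df = pd.read_csv(path, dtype=str)
    required = {"scheme", "native_class", "harmonized"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: mapping CSV lacks columns {sorted(missing)}")
    table = {}
    for _, row in df.iterrows():
        key = (row["scheme"].strip().lower(), row["native_class"].strip())
        if key in table and table[key] != row["harmonized"].strip():
            raise ValueError(f"{path}: conflicting entries for {key}")
        table[key] = row["harmonized"].strip()
    return DomainMapping(table)


@dataclass
class HarmonizedTable:
    """External scheme output with native labels replaced by domain labels.

    ``table`` keeps one row per (record, native label); multi-assignment
    records therefore carry several harmonized labels.  Rows whose native
    label had no mapping entry are kept with a null harmonized label and
    echoed in ``unmapped`` — never silently dropped.
    """

    scheme_name: str
    table: pd.DataFrame  # record_id, scheme, native_class, harmonized
    unmapped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def labels_by_record(self) -> dict[str, frozenset[str]]:
        ok = self.table.dropna(subset=["harmonized"])
        return {
            rid: frozenset(grp["harmonized"])
            for rid, grp in ok.groupby("record_id", sort=False)
        }

    @property
    def n_records(self) -> int:
        return self.table["record_id"].nunique()

    def raw_coverage(self) -> int:
        """Records with at least one assignment other than unclassified/out-of-domain."""
        return sum(
            1
            for labels in self.labels_by_record().values()
            if labels - {"unclassified_or_out_of_domain"}
        )


def harmonize_assignments(
    external: pd.DataFrame,
    mapping: DomainMapping | None = None,
    scheme_col: str = "scheme",
    class_col: str = "native_class",
) -> HarmonizedTable:
    """Map an external scheme's output table onto the harmonized vocabulary.

    ``external`` needs columns ``record_id``, a scheme column and a native
    class column; one row per assignment (multi-assignment schemes emit
    several rows per record).
    """
    mapping = mapping or default_mapping()
    required = {"record_id", scheme_col, class_col}
    missing = required - set(external.columns)
    if missing:
        raise ValueError(f"external table lacks required columns {sorted(missing)}")
    out = external.copy()
    out["harmonized"] = [
        mapping.lookup(s, n) for s, n in zip(out[scheme_col], out[class_col])
    ]
    out = out.rename(columns={scheme_col: "scheme", class_col: "native_class"})[
        ["record_id", "scheme", "native_class", "harmonized"]
    ]
    unmapped = out[out["harmonized"].isna()].copy()
    schemes = out["scheme"].unique()
    scheme_name = schemes[0] if len(schemes) == 1 else "+".join(sorted(map(str, schemes)))
    return HarmonizedTable(scheme_name=str(scheme_name), table=out, unmapped=unmapped)


@dataclass
class ConcordanceTable:
    """Pairwise domain-level agreement between two harmonized tables."""

    contingency: pd.DataFrame  # 4x4, rows = scheme a labels, cols = scheme b labels
    scheme_a: str
    scheme_b: str
    n_overlap: int
    n_only_a: int
    n_only_b: int
    coverage_a: int
    coverage_b: int

    @property
    def grand_total(self) -> int:
        return int(self.contingency.to_numpy().sum())


def concordance(a: HarmonizedTable, b: HarmonizedTable) -> ConcordanceTable:
    """4x4 contingency of harmonized labels over the shared record space.

    Records are inner-joined on record_id; a record carrying several labels
    under either scheme contributes one unit per label pair.  Raw coverage
    is reported per scheme over the shared records.
    """
    la, lb = a.labels_by_record(), b.labels_by_record()
    shared = sorted(set(la) & set(lb))
    if not shared:
        raise ValueError(
            f"no shared record ids between {a.scheme_name!r} and {b.scheme_name!r}"
        )
    table = pd.DataFrame(
        0, index=list(HARMONIZED_LABELS), columns=list(HARMONIZED_LABELS), dtype=int
    )
    for rid in shared:
        for x in la[rid]:
            for y in lb[rid]:
                table.loc[x, y] += 1
    unk = {"unclassified_or_out_of_domain"}
    return ConcordanceTable(
        contingency=table,
        scheme_a=a.scheme_name,
        scheme_b=b.scheme_name,
        n_overlap=len(shared),
        n_only_a=len(set(la) - set(lb)),
        n_only_b=len(set(lb) - set(la)),
        coverage_a=sum(1 for rid in shared if la[rid] - unk),
        coverage_b=sum(1 for rid in shared if lb[rid] - unk),
    )
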