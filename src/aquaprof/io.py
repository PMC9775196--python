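"""Inventory readers: .smi line files, CSV with a SMILES column, and SDF."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from rdkit import Chem

from .prep import RawRecord

__all__ = ["read_smi", "read_csv_inventory", "read_sdf", "read_inventory"]


def read_smi(path: str | Path, source: str = "") -> list[RawRecord]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id."""
    path = Path(path)
    source = source or path.stem
    records = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        record_id = parts[1] if len(parts) > 1 else f"{path.stem}-{i}"
        records.append(RawRecord(record_id=record_id, smiles=smiles, source=source))
    return records


def read_csv_inventory(
    path: str | Path,
    smiles_col: str = "smiles",
    id_col: str | None = "record_id",
    polymer_col: str | None = None,
    source: str = "",
) -> list[RawRecord]:
    """Read an inventory CSV. ``polymer_col``, when given, marks polymeric records."""
    path = Path(path)
    source = source or path.stem
    df = pd.read_csv(path, dtype=str)
    if smiles_col not in df.columns:
        raise ValueError(f"{path}: no column named {smiles_col!r}")
    if id_col is not None and id_col not in df.columns:
        id_col = None
    records = []
    for i, row in df.iterrows():
        record_id = str(row[id_col]) if id_col else f"{path.stem}-{i + 1}"
        polymer = False
        if polymer_col and polymer_col in df.columns:
            polymer = str(row[polymer_col]).strip().lower() in {"1", "true", "yes", "y"}
        records.append(
            RawRecord(
                record_id=record_id,
                smiles="" if pd.isna(row[smiles_col]) else str(row[smiles_col]),
                source=source,
                polymer_flag=polymer,
            )
        )
    return records


def read_sdf(path: str | Path, source: str = "") -> list[RawRecord]:
    """Read an SDF; the title line (or a running index) becomes the record id."""
    path = Path(path)
    source = source or path.stem
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            # unreadable entry: keep a placeholder so the rejection log can
            # account for it downstream
            records.append(RawRecord(record_id=f"{path.stem}-{i}", smiles="", source=source))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name").strip() else f"{path.stem}-{i}"
        records.append(RawRecord(record_id=name, smiles=Chem.MolToSmiles(mol), source=source))
    return records


def read_inventory(path: str | Path, **kwargs) -> list[RawRecord]:
    """Dispatch on file extension: .smi, .csv or .sdf."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".smi":
        return read_smi(path, **kwargs)
    if suffix == ".csv":
        return read_csv_inventory(path, **kwargs)
    if suffix == ".sdf":
        return read_sdf(path, **kwargs)
    raise ValueError(f"unsupported inventory format: {path}")
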