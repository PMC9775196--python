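import pytest
from rdkit import Chem

from aquaprof.fixtures import build_fixture_inventory
from aquaprof.kb import load_core_kb
from aquaprof.prep import RawRecord, standardize_structure


@pytest.fixture(scope="session")
def core_kb():
    return load_core_kb()


@pytest.fixture(scope="session")
def fixture_inventory(core_kb):
    """Curated molecules + probes + 20 decoys, with expectation manifest."""
    return build_fixture_inventory(seed=1, n_decoys=20, kb=core_kb)


@pytest.fixture(scope="session")
def std():
    """Standardize a single SMILES into a profilable compound."""

    def _std(smiles, record_id="t"):
        result = standardize_structure(RawRecord(record_id=record_id, smiles=smiles))
        assert hasattr(result, "parent_smiles"), f"{smiles} was rejected: {result}"
        return result

    return _std


def brute_force_alert_ids(smiles, kb):
    """Independent oracle: evaluate every KB alert by raw RDKit substructure
    search, then apply the sequential rule post hoc.

    Kept free of the profiler's own evaluation code: patterns are recompiled
    here and all embeddings checked with HasSubstructMatch directly.
    """
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    hits = set()
    for alert in kb.alerts.values():
        ok = all(
            mol.HasSubstructMatch(Chem.MolFromSmarts(s)) for s in alert.smarts_sequence
        ) and not any(
            mol.HasSubstructMatch(Chem.MolFromSmarts(s)) for s in alert.exclusions
        )
        if ok:
            hits.add(alert.id)
    # sequential rule: any non-1.1 assignment suppresses nonpolar narcosis
    group = {a.id: kb.group_of_alert(a.id) for a in kb.alerts.values()}
    phase1 = {h for h in hits if group[h] != "1.1"}
    return phase1 if phase1 else hits
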