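import numpy as np
import pytest

from interpbench import chem_io


def record(smiles: str, mol_id: str = "m") -> chem_io.MoleculeRecord:
    return chem_io.MoleculeRecord.from_smiles(smiles, mol_id)


@pytest.fixture(scope="session")
def general_pool():
    return chem_io.generate_fixture_pool(100, seed=1, profile="general")


@pytest.fixture(scope="session")
def amide_pool():
    return chem_io.generate_fixture_pool(500, seed=1, profile="amide_rich")


def nitrogen_count_oracle(rec, masked):
    """Predict the number of unmasked nitrogen atoms."""
    return float(
        sum(
            1
            for a in rec.mol.GetAtoms()
            if a.GetAtomicNum() == 7 and a.GetIdx() not in masked
        )
    )


def n_minus_o_oracle(rec, masked):
    total = 0
    for a in rec.mol.GetAtoms():
        if a.GetIdx() in masked:
            continue
        if a.GetAtomicNum() == 7:
            total += 1
        elif a.GetAtomicNum() == 8:
            total -= 1
    return float(total)


def inject_conformers(rec, coord_sets):
    """Attach hand-built conformer coordinate arrays to a record."""
    return rec.with_conformers([np.asarray(c, dtype=float) for c in coord_sets])
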