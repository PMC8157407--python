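"""Molecule and dataset I/O, standardization, and fixture pool generation.

Atom indexing policy: every :class:`MoleculeRecord` stores the molecule
re-parsed from its canonical SMILES, so heavy-atom indices 0..A-1 are the
canonical-SMILES writing order and are stable across re-parsing with the
same toolkit version.  All per-atom quantities downstream (ground truth,
contributions) refer to these indices.  Hydrogens are implicit; "atoms"
always means heavy atoms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")


@dataclass
class MoleculeRecord:
    """One standardized molecule with frozen heavy-atom indexing.

    ``conformers`` is a list of (A, 3) float arrays of heavy-atom
    coordinates in Angstrom, aligned to the record's atom indices.
    """

    mol_id: str
    smiles: str
    mol: Chem.Mol
    conformers: list[np.ndarray] | None = None
    embed_failed: bool = False

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumAtoms()

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str) -> "MoleculeRecord":
        """Parse ``smiles``; raise ``ValueError`` if unparsable.

        The stored graph is re-parsed from the canonical SMILES so that
        atom indices follow the canonical output order.
        """
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {mol_id!r}: {smiles!r}")
        can = Chem.MolToSmiles(mol)
        frozen = Chem.MolFromSmiles(can)
        if frozen is None:  # pragma: no cover - canonical SMILES re-parse
            raise ValueError(f"canonical SMILES re-parse failed for {mol_id!r}")
        return cls(mol_id=mol_id, smiles=can, mol=frozen)

    def with_conformers(self, conformers: list[np.ndarray]) -> "MoleculeRecord":
        for c in conformers:
            if c.shape != (self.heavy_atom_count, 3):
                raise ValueError(
                    f"conformer shape {c.shape} does not cover {self.heavy_atom_count} atoms"
                )
        return replace(self, conformers=[np.asarray(c, dtype=float) for c in conformers])


@dataclass
class DatasetTable:
    """Molecules plus activity and train/test split assignments."""

    records: list[MoleculeRecord]
    activity: dict[str, object]
    split: dict[str, str] = field(default_factory=dict)
    task: str | None = None

    def __post_init__(self) -> None:
        ids = [r.mol_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mol_id in records")
        if set(self.activity) != set(ids):
            raise ValueError("activity mapping does not cover records exactly")
        if not self.split:
            self.split = {i: "train" for i in ids}
        elif set(self.split) != set(ids):
            raise ValueError("split mapping does not cover records exactly")

    def subset(self, which: str) -> list[MoleculeRecord]:
        return [r for r in self.records if self.split[r.mol_id] == which]

    def __len__(self) -> int:
        return len(self.records)


def _canonical_reorder(mol: Chem.Mol) -> tuple[Chem.Mol, list[int]]:
    """Return (re-parsed canonical mol, order) with order[i] = old index of new atom i."""
    can = Chem.MolToSmiles(mol)
    order = list(map(int, mol.GetProp("_smilesAtomOutputOrder").strip("[],").split(",")))
    frozen = Chem.MolFromSmiles(can)
    if frozen is None:
        raise ValueError("canonical SMILES re-parse failed")
    return frozen, order


def read_molecules(
    path: str | Path,
    fmt: str | None = None,
    smiles_col: str = "smiles",
    id_col: str | None = None,
) -> list[MoleculeRecord]:
    """Read molecules from a .smi, .csv or .sdf file.

    Unparsable entries are skipped with a logged warning; a file yielding
    zero molecules is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    records: list[MoleculeRecord] = []
    skipped = 0

    if fmt == "smi":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            try:
                records.append(MoleculeRecord.from_smiles(smi, mol_id))
            except ValueError:
                skipped += 1
                logger.warning("skipping unparsable SMILES %r (line %d of %s)", smi, i + 1, path)
    elif fmt == "csv":
        df = pd.read_csv(path)
        if smiles_col not in df.columns:
            raise ValueError(f"CSV {path} has no column {smiles_col!r}")
        for i, row in df.iterrows():
            mol_id = str(row[id_col]) if id_col and id_col in df.columns else f"mol{i}"
            try:
                records.append(MoleculeRecord.from_smiles(str(row[smiles_col]), mol_id))
            except ValueError:
                skipped += 1
                logger.warning("skipping unparsable SMILES at row %d of %s", i, path)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("skipping unparsable SDF record %d of %s", i, path)
                continue
            mol_id = mol.GetProp("_Name") if mol.GetProp("_Name") else f"mol{i}"
            conf_coords = [conf.GetPositions() for conf in mol.GetConformers()]
            frozen, order = _canonical_reorder(mol)
            rec = MoleculeRecord(mol_id=mol_id, smiles=Chem.MolToSmiles(frozen), mol=frozen)
            if conf_coords:
                rec = rec.with_conformers([c[order] for c in conf_coords])
            records.append(rec)
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    if not records:
        raise ValueError(f"no parsable molecules in {path}")
    if skipped:
        logger.warning("%d entries skipped while reading %s", skipped, path)
    return records


_LARGEST = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_pool(
    records: Sequence[MoleculeRecord], mw_max: float = 500.0
) -> list[MoleculeRecord]:
    """Largest-fragment + neutralize, drop MW > ``mw_max``, drop duplicates.

    Duplicate key is the canonical SMILES of the neutralized largest
    component.  Order of first occurrence is preserved; idempotent.
    """
    if not records:
        raise ValueError("standardize_pool: empty input")
    out: list[MoleculeRecord] = []
    seen: set[str] = set()
    for rec in records:
        mol = _LARGEST.choose(rec.mol)
        mol = _UNCHARGER.uncharge(mol)
        if Descriptors.MolWt(mol) > mw_max:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        if can == rec.smiles:
            out.append(rec)
        else:
            out.append(MoleculeRecord.from_smiles(can, rec.mol_id))
    if not out:
        raise ValueError("standardize_pool: all records filtered out")
    return out


# --- fixture pool grammar -------------------------------------------------
# Chainable drug-like building blocks.  Mid tokens start and end on carbon
# so any concatenation yields a valid SMILES; prefixes/suffixes may end on
# a heteroatom cap.  Weights are per profile.

_MID_TOKENS = [
    "C", "CC", "CCC", "C(C)C", "CCCC",
    "COC", "COCC", "CNC", "CN(C)C",
    "C(=O)NC", "CNC(=O)C", "CC(=O)NC",
    "C(=O)C", "C(O)C", "C(N)C", "C(F)C", "C(Cl)C",
    "c1ccccc1", "c1ccc(cc1)", "c1ccncc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1",
]
_PREFIX_TOKENS = ["C", "CC", "OC", "NC", "NC(=O)", "OC(=O)", "N#C", "OCC", "NCC"]
_SUFFIX_TOKENS = ["C", "CC", "CO", "CN", "C(=O)N", "C(=O)O", "C#N", "CCO", "CCN", "C(C)O"]

_AMIDE_MIDS = {"C(=O)NC", "CNC(=O)C", "CC(=O)NC"}
_AMIDE_CAPS = {"NC(=O)", "C(=O)N"}
_DA_MIDS = {"C(O)C", "C(N)C", "COC", "CNC", "c1ccccc1", "c1ccc(cc1)", "c1ccncc1", "CCCC", "CCC"}
_DA_CAPS = {"OC", "NC", "OCC", "NCC", "CO", "CN", "CCO", "CCN", "C(C)O"}

_PROFILES = ("general", "amide_rich", "donor_acceptor_rich")


def _token_weights(tokens: Sequence[str], boosted: set[str], factor: float) -> np.ndarray:
    w = np.ones(len(tokens))
    for i, t in enumerate(tokens):
        if t in boosted:
            w[i] *= factor
    return w / w.sum()


def generate_fixture_pool(
    n: int, seed: int, profile: str = "general"
) -> list[MoleculeRecord]:
    """Deterministically generate ``n`` standardized drug-like molecules.

    A pure function of (n, seed, profile): molecules are assembled from a
    fixed grammar of chainable building blocks, filtered to MW <= 500 and
    de-duplicated by canonical SMILES.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {_PROFILES}")
    rng = np.random.default_rng(seed)

    if profile == "amide_rich":
        w_mid = _token_weights(_MID_TOKENS, _AMIDE_MIDS, 5.0)
        w_pre = _token_weights(_PREFIX_TOKENS, _AMIDE_CAPS, 4.0)
        w_suf = _token_weights(_SUFFIX_TOKENS, _AMIDE_CAPS, 4.0)
        n_mid_lo, n_mid_hi = 1, 6
    elif profile == "donor_acceptor_rich":
        w_mid = _token_weights(_MID_TOKENS, _DA_MIDS, 4.0)
        w_pre = _token_weights(_PREFIX_TOKENS, _DA_CAPS, 4.0)
        w_suf = _token_weights(_SUFFIX_TOKENS, _DA_CAPS, 4.0)
        n_mid_lo, n_mid_hi = 2, 8
    else:
        w_mid = _token_weights(_MID_TOKENS, set(), 1.0)
        w_pre = _token_weights(_PREFIX_TOKENS, set(), 1.0)
        w_suf = _token_weights(_SUFFIX_TOKENS, set(), 1.0)
        n_mid_lo, n_mid_hi = 1, 6

    out: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 500 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:  # pragma: no cover - generation guard
            raise RuntimeError(f"fixture generation stalled after {attempts} attempts")
        k = int(rng.integers(n_mid_lo, n_mid_hi + 1))
        pre = _PREFIX_TOKENS[int(rng.choice(len(_PREFIX_TOKENS), p=w_pre))]
        suf = _SUFFIX_TOKENS[int(rng.choice(len(_SUFFIX_TOKENS), p=w_suf))]
        mids = [_MID_TOKENS[int(i)] for i in rng.choice(len(_MID_TOKENS), size=k, p=w_mid)]
        smi = pre + "".join(mids) + suf
        mol = Chem.MolFromSmiles(smi)
        if mol is None or Descriptors.MolWt(mol) > 500.0:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        rec = MoleculeRecord.from_smiles(can, f"fx{profile[:2]}{len(out):05d}")
        out.append(rec)
    return out


# --- dataset + truth persistence -----------------------------------------

def write_dataset(ds: DatasetTable, path: str | Path) -> None:
    """Write a dataset as CSV with columns mol_id, smiles, activity, split."""
    rows = [
        {
            "mol_id": r.mol_id,
            "smiles": r.smiles,
            "activity": ds.activity[r.mol_id],
            "split": ds.split[r.mol_id],
        }
        for r in ds.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset(path: str | Path, task: str | None = None) -> DatasetTable:
    df = pd.read_csv(path)
    records = [MoleculeRecord.from_smiles(s, str(i)) for i, s in zip(df["mol_id"], df["smiles"])]
    activity = {str(i): a for i, a in zip(df["mol_id"], df["activity"])}
    split = {str(i): s for i, s in zip(df["mol_id"], df["split"])}
    return DatasetTable(records=records, activity=activity, split=split, task=task)


def write_truths(truths: Iterable, path: str | Path) -> None:
    """Ground truth as JSON-lines: one object per molecule."""
    with open(path, "w") as fh:
        for t in truths:
            fh.write(
                json.dumps({"mol_id": t.mol_id, "expected": [float(x) for x in t.expected]})
                + "\n"
            )


def read_truths(path: str | Path) -> dict[str, "np.ndarray"]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        out[obj["mol_id"]] = np.asarray(obj["expected"], dtype=float)
    return out
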