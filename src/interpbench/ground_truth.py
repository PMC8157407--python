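"""Activity labeling rules and per-atom expected contributions.

Six benchmark tasks are supported: three additive atom-count tasks
(nitrogen count; nitrogen minus oxygen; half the nitrogen-plus-oxygen
count with #N == #O enforced), two amide tasks (regression on the number
of NC=O matches and the derived active/inactive classification) and a
3-D two-point pharmacophore task (H-bond donor and acceptor 9-10 A apart
in at least one conformer).
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import cdist

from .chem_io import MoleculeRecord

ATOM_COUNT_TASKS = ("N", "N_minus_O", "N_plus_O")
REGRESSION_TASKS = ("N", "N_minus_O", "N_plus_O", "amide_reg")
CLASSIFICATION_TASKS = ("amide_class", "pharmacophore")
ALL_TASKS = REGRESSION_TASKS + CLASSIFICATION_TASKS

AMIDE_SMARTS = "NC=O"
_AMIDE_QUERY = Chem.MolFromSmarts(AMIDE_SMARTS)


@dataclass
class AtomTruth:
    """Per-atom expected contributions for one molecule."""

    mol_id: str
    expected: np.ndarray
    positive_atoms: frozenset[int] = field(init=False)
    negative_atoms: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        self.expected = np.asarray(self.expected, dtype=float)
        self.positive_atoms = frozenset(np.flatnonzero(self.expected > 0).tolist())
        self.negative_atoms = frozenset(np.flatnonzero(self.expected < 0).tolist())


@dataclass
class PharmacophoreAssignment:
    """Donor/acceptor flags and the matched distance-window pairs.

    ``matching_pairs`` holds unordered atom pairs as sorted tuples; a pair
    matched in both (donor, acceptor) role orders counts once.  Self-pairs
    (one atom acting as both donor and acceptor) are disallowed.
    """

    donors: frozenset[int]
    acceptors: frozenset[int]
    matching_pairs: frozenset[tuple[int, int]]
    label: str  # active | inactive | excluded


def label_atom_count(record: MoleculeRecord, task: str) -> tuple[float | None, AtomTruth | None]:
    """Label one molecule under an atom-count rule.

    N: activity = #N, each nitrogen expected 1.  N_minus_O: activity =
    #N - #O, nitrogens expected 1, oxygens -1.  N_plus_O: eligible only
    when #N == #O; activity = (#N + #O) / 2, every N and O expected 0.5.
    Ineligible molecules return (None, None).
    """
    if task not in ATOM_COUNT_TASKS:
        raise ValueError(f"unknown atom-count task {task!r}")
    zs = np.array([a.GetAtomicNum() for a in record.mol.GetAtoms()])
    is_n = zs == 7
    is_o = zs == 8
    expected = np.zeros(len(zs))
    if task == "N":
        expected[is_n] = 1.0
        activity = float(is_n.sum())
    elif task == "N_minus_O":
        expected[is_n] = 1.0
        expected[is_o] = -1.0
        activity = float(is_n.sum() - is_o.sum())
    else:
        if is_n.sum() != is_o.sum():
            return None, None
        expected[is_n | is_o] = 0.5
        activity = float(is_n.sum() + is_o.sum()) / 2.0
    return activity, AtomTruth(record.mol_id, expected)


def count_amide_matches(record: MoleculeRecord) -> int:
    """Number of distinct-atom-set NC=O matches."""
    return len(record.mol.GetSubstructMatches(_AMIDE_QUERY, uniquify=True))


def label_amide(record: MoleculeRecord, mode: str = "regression") -> tuple[object, AtomTruth]:
    """Label one molecule under the amide rule.

    Regression activity is the number of NC=O matches; classification is
    "active" iff at least one match.  Every atom belonging to any match
    gets expected contribution 1.
    """
    if mode not in ("regression", "classification"):
        raise ValueError(f"unknown mode {mode!r}")
    matches = record.mol.GetSubstructMatches(_AMIDE_QUERY, uniquify=True)
    expected = np.zeros(record.heavy_atom_count)
    for match in matches:
        expected[list(match)] = 1.0
    if mode == "regression":
        activity: object = float(len(matches))
    else:
        activity = "active" if matches else "inactive"
    return activity, AtomTruth(record.mol_id, expected)


@functools.lru_cache(maxsize=1)
def _hbond_patterns() -> list[tuple[str, Chem.Mol]]:
    text = (
        importlib.resources.files("interpbench").joinpath("data/hbond_smarts.txt").read_text()
    )
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        role, smarts = line.split("\t")
        query = Chem.MolFromSmarts(smarts)
        if query is None:  # pragma: no cover - shipped table is valid
            raise ValueError(f"bad SMARTS in hbond table: {smarts!r}")
        patterns.append((role, query))
    return patterns


def assign_pharmacophore_features(record: MoleculeRecord) -> tuple[frozenset[int], frozenset[int]]:
    """Flag H-bond donor and acceptor atoms from the shipped SMARTS table."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    for role, query in _hbond_patterns():
        for match in record.mol.GetSubstructMatches(query):
            (donors if role == "donor" else acceptors).add(match[0])
    return frozenset(donors), frozenset(acceptors)


def generate_conformers(
    record: MoleculeRecord, max_conf: int = 25, seed: int = 0
) -> MoleculeRecord:
    """Embed up to ``max_conf`` 3-D conformers (ETKDGv3, fixed seed).

    Heavy-atom coordinates are stored aligned to the record's atom
    indices.  Embedding failure flags the record instead of raising.
    """
    mol = Chem.AddHs(Chem.Mol(record.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=max_conf, params=params)
    if len(cids) == 0:
        from dataclasses import replace

        return replace(record, conformers=None, embed_failed=True)
    a = record.heavy_atom_count
    coords = [mol.GetConformer(cid).GetPositions()[:a].copy() for cid in cids]
    return record.with_conformers(coords)


def label_pharmacophore(
    record: MoleculeRecord,
    d_min: float = 9.0,
    d_max: float = 10.0,
    donors: frozenset[int] | None = None,
    acceptors: frozenset[int] | None = None,
) -> tuple[PharmacophoreAssignment, AtomTruth | None]:
    """Two-point pharmacophore labeling over a record's conformers.

    A match is an unordered (donor, acceptor) atom pair at Euclidean
    distance in [d_min, d_max] in at least one conformer.  The union of
    matched pairs over all conformers must have size exactly 1 for an
    active (same pair everywhere); size 0 is inactive; > 1 is excluded.
    Actives get expected contribution 1 on the two pharmacophore atoms;
    excluded molecules get no truth (None).
    """
    if not record.conformers:
        raise ValueError(f"{record.mol_id}: pharmacophore labeling requires conformers")
    if donors is None or acceptors is None:
        donors, acceptors = assign_pharmacophore_features(record)
    d_idx = sorted(donors)
    a_idx = sorted(acceptors)
    pairs: set[tuple[int, int]] = set()
    if d_idx and a_idx:
        for coords in record.conformers:
            dist = cdist(coords[d_idx], coords[a_idx])
            for i, j in zip(*np.nonzero((dist >= d_min) & (dist <= d_max))):
                d_atom, a_atom = d_idx[i], a_idx[j]
                if d_atom == a_atom:
                    continue
                pairs.add(tuple(sorted((d_atom, a_atom))))
    if len(pairs) == 1:
        label = "active"
    elif len(pairs) == 0:
        label = "inactive"
    else:
        label = "excluded"
    assignment = PharmacophoreAssignment(
        donors=frozenset(donors),
        acceptors=frozenset(acceptors),
        matching_pairs=frozenset(pairs),
        label=label,
    )
    if label == "excluded":
        return assignment, None
    expected = np.zeros(record.heavy_atom_count)
    if label == "active":
        (pair,) = pairs
        expected[list(pair)] = 1.0
    return assignment, AtomTruth(record.mol_id, expected)


def label_pool(
    records: list[MoleculeRecord],
    task: str,
    seed: int = 0,
    max_conf: int = 25,
    d_min: float = 9.0,
    d_max: float = 10.0,
) -> tuple[list[MoleculeRecord], dict[str, object], dict[str, AtomTruth]]:
    """Label a pool for one task, dropping ineligible/excluded molecules.

    Returns (eligible records, activity by mol_id, truth by mol_id).  For
    the pharmacophore task conformers are generated here (per-molecule
    seeds derived from ``seed``) and embedding failures are dropped.
    """
    if task not in ALL_TASKS:
        raise ValueError(f"unknown task {task!r}")
    kept: list[MoleculeRecord] = []
    activity: dict[str, object] = {}
    truths: dict[str, AtomTruth] = {}
    for i, rec in enumerate(records):
        if task in ATOM_COUNT_TASKS:
            act, truth = label_atom_count(rec, task)
        elif task == "amide_reg":
            act, truth = label_amide(rec, "regression")
        elif task == "amide_class":
            act, truth = label_amide(rec, "classification")
        else:
            if not rec.conformers:
                rec = generate_conformers(rec, max_conf=max_conf, seed=seed + i)
            if rec.embed_failed:
                continue
            assignment, truth = label_pharmacophore(rec, d_min=d_min, d_max=d_max)
            if assignment.label == "excluded":
                continue
            act = assignment.label
        if act is None or truth is None:
            continue
        kept.append(rec)
        activity[rec.mol_id] = act
        truths[rec.mol_id] = truth
    return kept, activity, truths
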