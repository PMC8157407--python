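"""Atom/fragment contributions by virtual removal (dummy-atom masking).

The contribution of a removed part is the difference between the
prediction for the whole molecule and for the remainder, where removed
atoms are replaced by dummy atoms (atomic number 0) with bonds kept.
For classification the predicted quantity is the active-class
probability, so contributions lie in [-1, 1].

Any predictor can be plugged in through two contracts: a
:class:`~interpbench.descriptors_models.PredictorHandle` (fingerprint
models), or a plain callable ``f(record, masked_atoms) -> float`` where
``masked_atoms`` is a frozenset (empty for the full molecule).  The
graph-model row-removal variant fits the callable contract.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord
from .descriptors_models import PredictorHandle

logger = logging.getLogger(__name__)

# Heavy-heavy acyclic single bonds: the only bonds broken by fragment
# enumeration (no ring, double or triple bonds).
FRAGMENT_BOND_SMARTS = "[!#1]-!@[!#1]"
_BOND_QUERY = Chem.MolFromSmarts(FRAGMENT_BOND_SMARTS)


@dataclass
class ContributionVector:
    mol_id: str
    level: str  # atom | fragment
    targets: list[frozenset[int]]
    contributions: np.ndarray
    base_prediction: float

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)
        if len(self.targets) != len(self.contributions):
            raise ValueError("targets and contributions misaligned")


@dataclass(frozen=True)
class Fragment:
    atoms: frozenset[int]
    n_broken_bonds: int


def mask_atoms(record: MoleculeRecord, atoms: Iterable[int]) -> MoleculeRecord:
    """Replace the listed atoms with dummy atoms, preserving all indices.

    Aromaticity is re-perceived after substitution; if sanitization
    fails the kekulized form is masked instead.
    """
    atom_set = frozenset(int(a) for a in atoms)
    if not atom_set:
        raise ValueError("mask_atoms: empty atom set")
    n = record.heavy_atom_count
    if any(a < 0 or a >= n for a in atom_set):
        raise ValueError(f"mask_atoms: atom index out of range for {record.mol_id}")
    if len(atom_set) >= n:
        raise ValueError("mask_atoms: cannot mask all heavy atoms")

    def _apply(base: Chem.Mol) -> Chem.Mol:
        rw = Chem.RWMol(base)
        for i in atom_set:
            a = rw.GetAtomWithIdx(i)
            a.SetAtomicNum(0)
            a.SetFormalCharge(0)
            a.SetNumExplicitHs(0)
            a.SetNoImplicit(True)
        m = rw.GetMol()
        Chem.SanitizeMol(m)
        return m

    try:
        masked = _apply(record.mol)
    except Exception:  # kekulized fallback when aromatic perception fails
        kek = Chem.Mol(record.mol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        masked = _apply(kek)
    return replace(
        record,
        smiles=Chem.MolToSmiles(masked, canonical=False),
        mol=masked,
        conformers=None,
    )


MaskedPredictor = Callable[[MoleculeRecord, frozenset], float]


def _as_masked_predictor(predictor) -> MaskedPredictor:
    if isinstance(predictor, PredictorHandle):

        def f(record: MoleculeRecord, atoms: frozenset) -> float:
            rec = record if not atoms else mask_atoms(record, atoms)
            return float(predictor.predict([rec])[0])

        return f
    if callable(predictor):
        return predictor
    raise TypeError("predictor must be a PredictorHandle or a callable")


class _PredictionCache:
    """Masked-prediction cache keyed by (mol_id, masked atom set).

    For fingerprint models all masked variants of one molecule are
    predicted in a single batched call; failures fall back to per-item
    prediction so one bad masked form yields one NaN, not a lost batch.
    """

    def __init__(self, predictor) -> None:
        self._handle = predictor if isinstance(predictor, PredictorHandle) else None
        self._f = _as_masked_predictor(predictor)
        self._store: dict[tuple[str, frozenset], float] = {}

    def __call__(self, record: MoleculeRecord, atoms: frozenset) -> float:
        key = (record.mol_id, atoms)
        if key not in self._store:
            self._store[key] = self._f(record, atoms)
        return self._store[key]

    def prefetch(self, record: MoleculeRecord, atom_sets: Sequence[frozenset]) -> None:
        if self._handle is None:
            return
        pending: list[tuple[frozenset, MoleculeRecord]] = []
        for s in atom_sets:
            if (record.mol_id, s) in self._store:
                continue
            try:
                pending.append((s, record if not s else mask_atoms(record, s)))
            except Exception:
                continue  # per-set failure surfaces later as NaN
        if not pending:
            return
        try:
            values = self._handle.predict([rec for _, rec in pending])
        except Exception:
            return
        for (s, _), v in zip(pending, values):
            self._store[(record.mol_id, s)] = float(v)


def atom_contributions(
    record: MoleculeRecord, predictor, cache: _PredictionCache | None = None
) -> ContributionVector:
    """contribution(a) = predict(full) - predict(mask({a})) per heavy atom.

    A predictor failure on a masked form records NaN with a warning.
    """
    pred = cache if cache is not None else _PredictionCache(predictor)
    pred.prefetch(
        record, [frozenset()] + [frozenset({a}) for a in range(record.heavy_atom_count)]
    )
    base = pred(record, frozenset())
    contribs = np.full(record.heavy_atom_count, np.nan)
    for a in range(record.heavy_atom_count):
        try:
            contribs[a] = base - pred(record, frozenset({a}))
        except Exception as exc:
            logger.warning("prediction failed for %s atom %d: %s", record.mol_id, a, exc)
    return ContributionVector(
        mol_id=record.mol_id,
        level="atom",
        targets=[frozenset({a}) for a in range(record.heavy_atom_count)],
        contributions=contribs,
        base_prediction=base,
    )


def eligible_bonds(record: MoleculeRecord) -> list[tuple[int, int]]:
    """Bonds breakable during fragmentation, as (begin, end) index pairs."""
    return [tuple(m) for m in record.mol.GetSubstructMatches(_BOND_QUERY, uniquify=True)]


def enumerate_fragments(
    record: MoleculeRecord,
    max_bonds: int = 3,
    max_atoms: int = 7,
    max_frac: Fraction = Fraction(2, 5),
) -> list[Fragment]:
    """All connected fragments from deleting 1..max_bonds eligible bonds.

    Fragment size is capped at ``max_atoms`` heavy atoms and at
    ``max_frac`` of the molecule's heavy atoms (exact rational
    comparison).  Duplicate atom sets collapse, keeping the smallest
    broken-bond count.  Rings are never broken, so ring systems small
    enough to pass the size caps appear intact.
    """
    n = record.heavy_atom_count
    bonds = eligible_bonds(record)
    adj: list[set[int]] = [set() for _ in range(n)]
    for b in record.mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].add(j)
        adj[j].add(i)

    found: dict[frozenset[int], int] = {}
    size_cap = min(max_atoms, n - 1)
    for k in range(1, max_bonds + 1):
        for subset in itertools.combinations(bonds, k):
            removed = {frozenset(b) for b in subset}
            seen: set[int] = set()
            for start in range(n):
                if start in seen:
                    continue
                comp = {start}
                stack = [start]
                while stack:
                    u = stack.pop()
                    for v in adj[u]:
                        if v in comp or frozenset((u, v)) in removed:
                            continue
                        comp.add(v)
                        stack.append(v)
                seen |= comp
                if len(comp) == n or len(comp) > size_cap:
                    continue
                if Fraction(len(comp)) > max_frac * n:
                    continue
                boundary = sum(1 for b in removed if len(b & comp) == 1)
                if boundary == 0:
                    continue
                key = frozenset(comp)
                if key not in found or boundary < found[key]:
                    found[key] = boundary
    return [Fragment(atoms=a, n_broken_bonds=c) for a, c in sorted(found.items(), key=lambda kv: sorted(kv[0]))]


def fragment_contributions(
    record: MoleculeRecord,
    predictor,
    fragments: Sequence[Fragment],
    cache: _PredictionCache | None = None,
) -> ContributionVector:
    """contribution(F) = predict(full) - predict(mask(F.atoms))."""
    pred = cache if cache is not None else _PredictionCache(predictor)
    pred.prefetch(record, [frozenset()] + [frozenset(f.atoms) for f in fragments])
    base = pred(record, frozenset())
    contribs = np.full(len(fragments), np.nan)
    for i, frag in enumerate(fragments):
        try:
            contribs[i] = base - pred(record, frozenset(frag.atoms))
        except Exception as exc:
            logger.warning("prediction failed for %s fragment %d: %s", record.mol_id, i, exc)
    return ContributionVector(
        mol_id=record.mol_id,
        level="fragment",
        targets=[frozenset(f.atoms) for f in fragments],
        contributions=contribs,
        base_prediction=base,
    )


def interpret_dataset(
    records: Sequence[MoleculeRecord],
    predictor,
    level: str = "atom",
    **fragment_kwargs,
) -> list[ContributionVector]:
    """Atom- or fragment-level contributions for a set of molecules.

    By convention interpretation runs on the training split only; the
    caller passes the records accordingly.
    """
    cache = _PredictionCache(predictor)
    out = []
    for rec in records:
        if level == "atom":
            out.append(atom_contributions(rec, predictor, cache=cache))
        elif level == "fragment":
            frags = enumerate_fragments(rec, **fragment_kwargs)
            out.append(fragment_contributions(rec, predictor, frags, cache=cache))
        else:
            raise ValueError(f"unknown level {level!r}")
    return out


def write_contributions(contribs: Iterable[ContributionVector], path) -> None:
    import json

    with open(path, "w") as fh:
        for c in contribs:
            fh.write(
                json.dumps(
                    {
                        "mol_id": c.mol_id,
                        "level": c.level,
                        "targets": [sorted(t) for t in c.targets],
                        "contributions": [None if np.isnan(x) else float(x) for x in c.contributions],
                        "base_prediction": c.base_prediction,
                    }
                )
                + "\n"
            )


def read_contributions(path) -> list[ContributionVector]:
    import json
    from pathlib import Path

    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        out.append(
            ContributionVector(
                mol_id=obj["mol_id"],
                level=obj["level"],
                targets=[frozenset(t) for t in obj["targets"]],
                contributions=np.array(
                    [np.nan if x is None else x for x in obj["contributions"]], dtype=float
                ),
                base_prediction=obj["base_prediction"],
            )
        )
    return out
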