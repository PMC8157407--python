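"""Predictive-performance and interpretation-quality metrics.

Interpretation metrics are per-molecule ranking scores against the
benchmark's expected atom contributions: ROC AUC of contributions vs
rewritten binary labels (AUC+ / AUC-), top-n / bottom-n retrieval
scores, per-molecule contribution RMSE, top-k percentage of true
centers, and a fragment-level top-2 score.  Molecules lacking atoms of
the requested sign are excluded from AUC averaging; RMSE averages over
all molecules.

Tie handling: AUC uses midranks (tied pairs count 0.5); top-n uses a
deterministic ranking (contribution descending, atom index ascending),
with an optional "expected" mode returning the expectation over random
tie orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ground_truth import AtomTruth
from .interpretation import ContributionVector


@dataclass
class PredictionSet:
    y_obs: np.ndarray
    y_pred: np.ndarray
    task: str  # regression | classification

    def __post_init__(self) -> None:
        self.y_obs = np.asarray(self.y_obs)
        self.y_pred = np.asarray(self.y_pred)
        if len(self.y_obs) != len(self.y_pred) or len(self.y_obs) < 1:
            raise ValueError("y_obs and y_pred must have equal length >= 1")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class InterpretationReport:
    mean_auc_pos: float = float("nan")
    mean_auc_neg: float = float("nan")
    top_n: float = float("nan")
    bottom_n: float = float("nan")
    mean_rmse: float = float("nan")
    topk_pct: dict[int, float] = field(default_factory=dict)
    fragment_top2: float | None = None
    n_excluded_auc_pos: int = 0
    n_excluded_auc_neg: int = 0

    def to_dict(self) -> dict:
        d = {
            "mean_auc_pos": self.mean_auc_pos,
            "mean_auc_neg": self.mean_auc_neg,
            "top_n": self.top_n,
            "bottom_n": self.bottom_n,
            "mean_rmse": self.mean_rmse,
            "n_excluded_auc_pos": self.n_excluded_auc_pos,
            "n_excluded_auc_neg": self.n_excluded_auc_neg,
        }
        for k, v in self.topk_pct.items():
            d[f"top{k}_pct"] = v
        if self.fragment_top2 is not None:
            d["fragment_top2"] = self.fragment_top2
        return d


# --- predictive scores ----------------------------------------------------

def confusion_counts(y_obs: Sequence[str], y_pred: Sequence[str]) -> ConfusionCounts:
    obs = np.asarray(y_obs)
    pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(np.sum((obs == "active") & (pred == "active"))),
        TN=int(np.sum((obs == "inactive") & (pred == "inactive"))),
        FP=int(np.sum((obs == "inactive") & (pred == "active"))),
        FN=int(np.sum((obs == "active") & (pred == "inactive"))),
    )


def predictive_scores(p: PredictionSet) -> dict[str, float]:
    """Q^2/RMSE for regression; sensitivity/specificity/balanced accuracy
    for classification (labels "active"/"inactive")."""
    if p.task == "regression":
        obs = p.y_obs.astype(float)
        pred = p.y_pred.astype(float)
        ss_res = float(np.sum((pred - obs) ** 2))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        q2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
        rmse = float(np.sqrt(ss_res / len(obs)))
        return {"Q2": q2, "RMSE": rmse}
    c = confusion_counts(p.y_obs, p.y_pred)
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


# --- per-molecule ranking metrics ----------------------------------------

def _rewritten_labels(truth: AtomTruth, sign: str) -> np.ndarray:
    labels = np.zeros(len(truth.expected), dtype=int)
    atoms = truth.positive_atoms if sign == "positive" else truth.negative_atoms
    labels[sorted(atoms)] = 1
    return labels


def molecule_auc(contrib: ContributionVector, truth: AtomTruth, sign: str = "positive") -> float:
    """Ranking AUC of atom contributions vs rewritten binary labels.

    For ``sign="negative"`` atoms are ranked ascending (most negative on
    top).  NaN when the molecule has no atoms of the requested sign (or
    all atoms are of that sign) -- such molecules are excluded upstream.
    """
    if contrib.level != "atom":
        raise ValueError("molecule_auc needs atom-level contributions")
    labels = _rewritten_labels(truth, sign)
    scores = contrib.contributions if sign == "positive" else -contrib.contributions
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    # Mann-Whitney formulation with midrank tie correction
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def dataset_auc(
    contribs: Sequence[ContributionVector],
    truths: Mapping[str, AtomTruth],
    sign: str = "positive",
) -> tuple[float, int]:
    """Unweighted mean of defined per-molecule AUCs plus exclusion count."""
    vals = [molecule_auc(c, truths[c.mol_id], sign) for c in contribs]
    arr = np.asarray(vals, dtype=float)
    defined = arr[~np.isnan(arr)]
    n_excluded = int(np.isnan(arr).sum())
    mean = float(defined.mean()) if len(defined) else float("nan")
    return mean, n_excluded


def _ranked_atoms(contrib: ContributionVector, direction: str) -> np.ndarray:
    """Atom indices best-first: contribution desc (asc for bottom), then
    atom index asc."""
    c = contrib.contributions.copy()
    c = np.where(np.isnan(c), -np.inf if direction == "top" else np.inf, c)
    idx = np.arange(len(c))
    key = -c if direction == "top" else c
    return idx[np.lexsort((idx, key))]


def top_n_counts(
    contrib: ContributionVector, truth: AtomTruth, direction: str = "top", ties: str = "index"
) -> tuple[float, int]:
    """One molecule's (m, n) accumulator terms for the top-n score.

    n is the number of true atoms of the relevant sign; m counts how many
    of them land among the molecule's n best-ranked atoms.  With
    ``ties="expected"`` m is the expectation over random orders of atoms
    tied at the cutoff boundary.
    """
    atoms = truth.positive_atoms if direction == "top" else truth.negative_atoms
    n = len(atoms)
    if n == 0:
        return 0.0, 0
    if ties == "index":
        ranked = _ranked_atoms(contrib, direction)
        m = float(len(set(ranked[:n].tolist()) & atoms))
        return m, n
    if ties != "expected":
        raise ValueError(f"unknown tie mode {ties!r}")
    c = contrib.contributions
    c = np.where(np.isnan(c), -np.inf if direction == "top" else np.inf, c)
    scores = c if direction == "top" else -c
    order = np.argsort(-scores, kind="stable")
    cutoff_score = scores[order[n - 1]]
    strictly_better = scores > cutoff_score
    tied = scores == cutoff_score
    m = float(sum(1 for a in atoms if strictly_better[a]))
    slots = n - int(strictly_better.sum())
    n_tied = int(tied.sum())
    if n_tied and slots > 0:
        true_tied = sum(1 for a in atoms if tied[a])
        m += slots * true_tied / n_tied  # hypergeometric mean
    return m, n


def top_n_score(
    contribs: Sequence[ContributionVector],
    truths: Mapping[str, AtomTruth],
    direction: str = "top",
    ties: str = "index",
) -> float:
    """Sum(m_i) / Sum(n_i) over molecules with n_i > 0; NaN if none."""
    m_total = 0.0
    n_total = 0
    for c in contribs:
        m, n = top_n_counts(c, truths[c.mol_id], direction, ties)
        m_total += m
        n_total += n
    return m_total / n_total if n_total else float("nan")


def contribution_rmse(
    contribs: Sequence[ContributionVector], truths: Mapping[str, AtomTruth]
) -> tuple[np.ndarray, float]:
    """Per-molecule RMSE vs expected contributions and its plain mean."""
    per_mol = []
    for c in contribs:
        expected = truths[c.mol_id].expected
        if len(expected) != len(c.contributions):
            raise ValueError(f"length mismatch for {c.mol_id}")
        per_mol.append(float(np.sqrt(np.nanmean((c.contributions - expected) ** 2))))
    arr = np.asarray(per_mol)
    return arr, float(arr.mean())


def topk_percentage(
    contribs: Sequence[ContributionVector], truths: Mapping[str, AtomTruth], k: int
) -> float:
    """Mean per-molecule fraction of true positive atoms among the k
    highest contributions, as a percentage.  Molecules without positive
    atoms are skipped; k beyond the atom count uses all atoms."""
    fractions = []
    for c in contribs:
        truth = truths[c.mol_id]
        atoms = truth.positive_atoms
        if not atoms:
            continue
        kk = min(k, len(c.contributions))
        ranked = _ranked_atoms(c, "top")
        hit = len(set(ranked[:kk].tolist()) & atoms)
        fractions.append(hit / len(atoms))
    if not fractions:
        return float("nan")
    return 100.0 * float(np.mean(fractions))


def fragment_top2(
    frag_contribs: Sequence[ContributionVector], truths: Mapping[str, AtomTruth]
) -> float:
    """Mean per-molecule fragment-level top-2 score.

    The two highest-contribution fragments are pooled; the molecule
    scores 1 if their atoms cover both true centers, 0.5 for one, 0 for
    none.  Molecules with fewer than 2 fragments use what they have.
    """
    scores = []
    for c in frag_contribs:
        truth = truths[c.mol_id]
        centers = truth.positive_atoms
        if not centers:
            continue
        if len(c.targets) == 0:
            scores.append(0.0)
            continue
        vals = np.where(np.isnan(c.contributions), -np.inf, c.contributions)
        order = np.lexsort((np.arange(len(vals)), -vals))
        covered: set[int] = set()
        for i in order[:2]:
            covered |= set(c.targets[i])
        hit = len(covered & centers)
        scores.append({2: 1.0, 1: 0.5, 0: 0.0}[min(hit, 2)])
    return float(np.mean(scores)) if scores else float("nan")


def breakdown_by_pattern_count(
    contribs: Sequence[ContributionVector],
    truths: Mapping[str, AtomTruth],
    pattern_counts: Mapping[str, int],
    max_count: int = 6,
) -> dict[str, dict[str, float]]:
    """Mean AUC+, top-n and mean RMSE per subset of molecules with exactly
    c true patterns (c = 1..max_count) plus an "All" row."""

    def _row(subset: Sequence[ContributionVector]) -> dict[str, float]:
        if not subset:
            return {"mean_auc_pos": float("nan"), "top_n": float("nan"), "mean_rmse": float("nan"), "n": 0}
        auc, _ = dataset_auc(subset, truths, "positive")
        _, rmse = contribution_rmse(subset, truths)
        return {
            "mean_auc_pos": auc,
            "top_n": top_n_score(subset, truths),
            "mean_rmse": rmse,
            "n": len(subset),
        }

    table = {"All": _row(list(contribs))}
    for c in range(0, max_count + 1):
        subset = [cv for cv in contribs if pattern_counts[cv.mol_id] == c]
        table[str(c)] = _row(subset)
    return table


def interpretation_report(
    contribs: Sequence[ContributionVector],
    truths: Mapping[str, AtomTruth],
    topk: Sequence[int] = (2, 3, 5),
    frag_contribs: Sequence[ContributionVector] | None = None,
) -> InterpretationReport:
    """Aggregate all atom-level metrics (and optional fragment top-2)."""
    auc_pos, nex_pos = dataset_auc(contribs, truths, "positive")
    auc_neg, nex_neg = dataset_auc(contribs, truths, "negative")
    _, mean_rmse = contribution_rmse(contribs, truths)
    return InterpretationReport(
        mean_auc_pos=auc_pos,
        mean_auc_neg=auc_neg,
        top_n=top_n_score(contribs, truths, "top"),
        bottom_n=top_n_score(contribs, truths, "bottom"),
        mean_rmse=mean_rmse,
        topk_pct={k: topk_percentage(contribs, truths, k) for k in topk},
        fragment_top2=fragment_top2(frag_contribs, truths) if frag_contribs else None,
        n_excluded_auc_pos=nex_pos,
        n_excluded_auc_neg=nex_neg,
    )
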