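"""Masking-aware fingerprints and the conventional model harness.

Fingerprint families: AP (atom pairs, topological distance 1-30), MG2
(Morgan radius 2), RDK (paths of 2-4 atoms) and TT (topological torsions
of 4 atoms).  Counted fingerprints are kept unfolded as sparse key ->
count mappings so features introduced by dummy atoms of masked molecules
can be dropped exactly at vectorization time (they are out of the frozen
training vocabulary, which is how models come to ignore masked atoms).
Binary variants are folded to 2048 bits; hash collisions between dummy
features and real bits are a known, accepted artifact of folding.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import joblib
import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.model_selection import GridSearchCV, KFold, ParameterGrid, StratifiedKFold
from sklearn.svm import SVC, SVR

from .chem_io import MoleculeRecord

FAMILIES = ("AP", "MG2", "RDK", "TT")
ALGORITHMS = ("RF", "PLS", "GBM", "SVM")
BINARY_LENGTH = 2048

DEFAULT_PARAMS = {
    "AP": {"minDistance": 1, "maxDistance": 30},
    "MG2": {"radius": 2},
    "RDK": {"minPath": 1, "maxPath": 3},  # paths of 2..4 atoms
    "TT": {"torsionAtomCount": 4},
}


@dataclass(frozen=True)
class FingerprintSpec:
    family: str
    counted: bool = True
    folded_length: int = BINARY_LENGTH

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported fingerprint family {self.family!r}")
        if not self.counted and self.folded_length != BINARY_LENGTH:
            raise ValueError("binary fingerprints are folded to 2048 bits")

    @property
    def name(self) -> str:
        return self.family if self.counted else f"b{self.family}"


@functools.lru_cache(maxsize=None)
def _generator(spec: FingerprintSpec):
    p = DEFAULT_PARAMS[spec.family]
    if spec.family == "AP":
        return rdFingerprintGenerator.GetAtomPairGenerator(
            minDistance=p["minDistance"], maxDistance=p["maxDistance"], fpSize=spec.folded_length
        )
    if spec.family == "MG2":
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=p["radius"], fpSize=spec.folded_length
        )
    if spec.family == "RDK":
        return rdFingerprintGenerator.GetRDKitFPGenerator(
            minPath=p["minPath"], maxPath=p["maxPath"], fpSize=spec.folded_length
        )
    return rdFingerprintGenerator.GetTopologicalTorsionGenerator(
        torsionAtomCount=p["torsionAtomCount"], fpSize=spec.folded_length
    )


@dataclass
class Vocabulary:
    """Frozen training-set feature-key universe for counted fingerprints."""

    index: dict[int, int]

    def __len__(self) -> int:
        return len(self.index)

    @classmethod
    def from_feature_maps(cls, maps: Sequence[dict[int, int]]) -> "Vocabulary":
        keys = sorted(set().union(*maps)) if maps else []
        return cls(index={k: i for i, k in enumerate(keys)})


@dataclass
class FeatureVector:
    spec: FingerprintSpec
    counts: dict[int, int] | None  # unfolded key -> count (counted mode)
    bits: frozenset[int] | None  # on-bit indices (binary mode)
    raw: object = field(repr=False, default=None)  # RDKit fp for similarity

    def to_dense(self, vocabulary: Vocabulary | None = None) -> np.ndarray:
        if self.counts is not None:
            if vocabulary is None:
                raise ValueError("counted vectors need a vocabulary")
            v = np.zeros(len(vocabulary))
            for k, c in self.counts.items():
                col = vocabulary.index.get(k)
                if col is not None:  # out-of-vocabulary keys dropped
                    v[col] = c
            return v
        v = np.zeros(self.spec.folded_length)
        v[list(self.bits)] = 1.0
        return v

    def out_of_vocabulary(self, vocabulary: Vocabulary) -> set[int]:
        if self.counts is None:
            raise ValueError("only counted vectors track OOV keys")
        return {k for k in self.counts if k not in vocabulary.index}


def featurize(record: MoleculeRecord, spec: FingerprintSpec) -> FeatureVector:
    """Compute one fingerprint; dummy atoms (atomic number 0) allowed."""
    gen = _generator(spec)
    if spec.counted:
        fp = gen.GetSparseCountFingerprint(record.mol)
        return FeatureVector(
            spec=spec, counts=dict(fp.GetNonzeroElements()), bits=None, raw=fp
        )
    fp = gen.GetFingerprint(record.mol)
    return FeatureVector(
        spec=spec, counts=None, bits=frozenset(fp.GetOnBits()), raw=fp
    )


class PLSDAEstimator(BaseEstimator, RegressorMixin):
    """PLS regression reused for classification via a 0/1 response.

    ``predict_proba`` clips the latent regression output to [0, 1].
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self._pls = PLSRegression(n_components=min(self.n_components, X.shape[1], len(y) - 1))
        self._pls.fit(X, np.asarray(y, dtype=float))
        return self

    def predict_proba(self, X):
        p = np.clip(self._pls.predict(X).ravel(), 0.0, 1.0)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _estimator_and_grid(algorithm: str, task: str, seed: int):
    if algorithm == "RF":
        if task == "regression":
            est = RandomForestRegressor(random_state=seed, n_jobs=1)
        else:
            est = RandomForestClassifier(random_state=seed, n_jobs=1)
        grid = {"n_estimators": [250], "max_features": ["sqrt", 0.3]}
    elif algorithm == "GBM":
        if task == "regression":
            est = GradientBoostingRegressor(random_state=seed)
        else:
            est = GradientBoostingClassifier(random_state=seed)
        grid = {"n_estimators": [300], "learning_rate": [0.1], "max_depth": [3]}
    elif algorithm == "SVM":
        if task == "regression":
            est = SVR(kernel="rbf")
            grid = {"C": [1.0, 10.0, 100.0], "gamma": ["scale"]}
        else:
            est = SVC(kernel="rbf", probability=True, random_state=seed)
            grid = {"C": [1.0, 10.0], "gamma": ["scale"]}
    elif algorithm == "PLS":
        if task == "regression":
            est = PLSRegression()
        else:
            est = PLSDAEstimator()
        grid = {"n_components": [2, 8, 32]}
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return est, grid


@dataclass
class PredictorHandle:
    """A fitted model bound to its fingerprint spec and frozen vocabulary.

    ``predict`` returns end-point values for regression and active-class
    probabilities for classification.
    """

    algorithm: str
    task: str
    spec: FingerprintSpec
    model: object
    vocabulary: Vocabulary | None
    best_params: dict
    featurizer: Callable[[MoleculeRecord], dict[int, int]] | None = None

    def _matrix(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        if self.featurizer is not None:
            assert self.vocabulary is not None
            rows = []
            for r in records:
                v = np.zeros(len(self.vocabulary))
                for k, c in self.featurizer(r).items():
                    col = self.vocabulary.index.get(k)
                    if col is not None:
                        v[col] = c
                rows.append(v)
            return np.vstack(rows)
        return np.vstack([featurize(r, self.spec).to_dense(self.vocabulary) for r in records])

    def predict(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        X = self._matrix(records)
        if self.task == "classification":
            proba = self.model.predict_proba(X)
            active_col = int(np.where(self.model.classes_ == 1)[0][0])
            return proba[:, active_col]
        return np.asarray(self.model.predict(X), dtype=float).ravel()

    def predict_labels(self, records: Sequence[MoleculeRecord]) -> list[str]:
        if self.task != "classification":
            raise ValueError("labels only defined for classification")
        return ["active" if p >= 0.5 else "inactive" for p in self.predict(records)]

    def save(self, path) -> None:
        payload = {
            "algorithm": self.algorithm,
            "task": self.task,
            "spec": (self.spec.family, self.spec.counted, self.spec.folded_length),
            "model": self.model,
            "vocabulary": self.vocabulary.index if self.vocabulary else None,
            "best_params": self.best_params,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "PredictorHandle":
        payload = joblib.load(path)
        fam, counted, length = payload["spec"]
        return cls(
            algorithm=payload["algorithm"],
            task=payload["task"],
            spec=FingerprintSpec(fam, counted, length),
            model=payload["model"],
            vocabulary=Vocabulary(payload["vocabulary"]) if payload["vocabulary"] else None,
            best_params=payload["best_params"],
        )


def _encode_y(activity_values: Sequence[object], task: str) -> np.ndarray:
    if task == "classification":
        return np.array([1 if a == "active" else 0 for a in activity_values])
    return np.asarray(activity_values, dtype=float)


def train_model(
    records: Sequence[MoleculeRecord],
    activity_values: Sequence[object],
    spec: FingerprintSpec,
    algorithm: str,
    task: str,
    cv_folds: int = 5,
    grid: dict | None = None,
    seed: int = 0,
    featurizer: Callable[[MoleculeRecord], dict[int, int]] | None = None,
) -> PredictorHandle:
    """Fit one model with grid search in k-fold CV, refit on all data.

    ``featurizer`` optionally replaces the fingerprint with a custom
    record -> {key: count} mapping (used for oracle-feature tests).
    A single-point grid skips the CV loop and fits directly.
    """
    if len(records) < 2 * cv_folds:
        raise ValueError(f"need >= {2 * cv_folds} training molecules, got {len(records)}")
    y = _encode_y(activity_values, task)
    if task == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate labels: single class")
    elif np.std(y) == 0:
        raise ValueError("degenerate labels: zero variance")

    if featurizer is not None:
        maps = [featurizer(r) for r in records]
        vocabulary = Vocabulary.from_feature_maps(maps)
        X = np.vstack([_project(m, vocabulary) for m in maps])
    elif spec.counted:
        maps = [featurize(r, spec).counts for r in records]
        vocabulary = Vocabulary.from_feature_maps(maps)
        X = np.vstack([_project(m, vocabulary) for m in maps])
    else:
        vocabulary = None
        X = np.vstack([featurize(r, spec).to_dense() for r in records])

    est, default_grid = _estimator_and_grid(algorithm, task, seed)
    grid = dict(grid) if grid is not None else default_grid
    if algorithm == "PLS" and "n_components" in grid:
        # smallest CV training fold bounds the usable component count
        fold = len(records) * (cv_folds - 1) // cv_folds
        cap = max(1, min(X.shape[1], fold - 1))
        kept = sorted({min(c, cap) for c in grid["n_components"]})
        grid["n_components"] = kept
    n_points = len(list(ParameterGrid(grid)))
    if n_points > 1:
        if task == "classification":
            cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            scoring = "balanced_accuracy"
        else:
            cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            scoring = "neg_root_mean_squared_error"
        search = GridSearchCV(est, grid, cv=cv, scoring=scoring, refit=True, n_jobs=1)
        search.fit(X, y)
        model = search.best_estimator_
        best_params = dict(search.best_params_)
    else:
        best_params = {k: v[0] for k, v in grid.items()}
        model = clone(est).set_params(**best_params)
        model.fit(X, y)

    return PredictorHandle(
        algorithm=algorithm,
        task=task,
        spec=spec,
        model=model,
        vocabulary=vocabulary,
        best_params=best_params,
        featurizer=featurizer,
    )


def _project(counts: dict[int, int], vocabulary: Vocabulary) -> np.ndarray:
    v = np.zeros(len(vocabulary))
    for k, c in counts.items():
        col = vocabulary.index.get(k)
        if col is not None:
            v[col] = c
    return v


def baseline_1nn(
    train_records: Sequence[MoleculeRecord],
    train_activity: Sequence[object],
    test_records: Sequence[MoleculeRecord],
    spec: FingerprintSpec,
) -> np.ndarray:
    """1-nearest-neighbor prediction by Tanimoto (binary) / Dice (counts).

    Returns the neighbor's activity for each test record (class label for
    classification inputs).  Used as a modelability/bias baseline.
    """
    train_fps = [featurize(r, spec).raw for r in train_records]
    sim = DataStructs.TanimotoSimilarity if not spec.counted else DataStructs.DiceSimilarity
    preds = []
    for rec in test_records:
        fp = featurize(rec, spec).raw
        sims = [sim(fp, tfp) for tfp in train_fps]
        preds.append(train_activity[int(np.argmax(sims))])
    return np.asarray(preds)
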