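"""Pairwise min-product kernel and the classifier-adapter contract.

Every learner that is audited goes through the same adapter surface:
``fit(X, y, seed)`` on pair-feature rows and ``score(X)`` returning
probabilities in [0, 1] (higher = more likely interacting).  Two
learners are bundled:

* a support-vector machine on the pairwise kernel
  K((A,B),(C,D)) = exp(-gamma * min(|A-C|^2 |B-D|^2, |A-D|^2 |B-C|^2)),
  which is invariant to the orientation of either pair by construction;
* a random forest on concatenated pair vectors, made
  orientation-respecting by training on both orientations and scoring
  their average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .core import PairAuditError, auc
from .features import FeatureMap, pair_matrix


@dataclass(frozen=True)
class KernelSpec:
    """Width parameter of the pairwise min-product kernel."""

    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise PairAuditError(f"gamma must be positive, got {self.gamma}")


def pair_kernel(spec: KernelSpec, A, B, C, D) -> float:
    """Kernel value between protein pairs (A, B) and (C, D).

    The min over the two cross-matchings makes the kernel symmetric
    under swapping the proteins within either pair, so identical and
    orientation-swapped pairs both evaluate to exactly 1.
    """
    A, B, C, D = (np.asarray(v, dtype=float) for v in (A, B, C, D))
    if not (A.shape == B.shape == C.shape == D.shape):
        raise PairAuditError("pair_kernel requires four vectors of one dimension")
    d_ac = float(np.sum((A - C) ** 2))
    d_bd = float(np.sum((B - D) ** 2))
    d_ad = float(np.sum((A - D) ** 2))
    d_bc = float(np.sum((B - C) ** 2))
    return float(np.exp(-spec.gamma * min(d_ac * d_bd, d_ad * d_bc)))


def pair_kernel_gram(spec: KernelSpec, X, Z=None) -> np.ndarray:
    """Gram matrix of the pairwise kernel between two sets of pair rows.

    Rows are concatenations [v_a || v_b]; the two halves are recovered
    by splitting each row at its midpoint.
    """
    X = np.asarray(X, dtype=float)
    Z = X if Z is None else np.asarray(Z, dtype=float)
    if X.shape[1] != Z.shape[1] or X.shape[1] % 2:
        raise PairAuditError("pair rows must share one even dimension")
    d = X.shape[1] // 2
    xa, xb = X[:, :d], X[:, d:]
    za, zb = Z[:, :d], Z[:, d:]
    straight = cdist(xa, za, "sqeuclidean") * cdist(xb, zb, "sqeuclidean")
    crossed = cdist(xa, zb, "sqeuclidean") * cdist(xb, za, "sqeuclidean")
    return np.exp(-spec.gamma * np.minimum(straight, crossed))


# ---------------------------------------------------------------------------
# Adapters
# ---------------------------------------------------------------------------

class ClassifierAdapter:
    """Behavioral contract every audited learner satisfies.

    ``symmetric`` declares whether the learner treats [A,B] and [B,A]
    differently; such learners are trained on both orientations and
    scored as the average of both (handled by :func:`fit_pairs` /
    :func:`score_pairs`).
    """

    name: str = "adapter"
    symmetric: bool = False

    def __init__(self, **hyperparameters):
        self.hyperparameters = dict(hyperparameters)
        self._model = None
        self._n_features: int | None = None

    @property
    def trained(self) -> bool:
        return self._model is not None

    def fit(self, X, y, seed: int) -> "ClassifierAdapter":
        X = np.asarray(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise PairAuditError("rows and labels are not aligned")
        if len(np.unique(y)) < 2:
            raise PairAuditError("training data contains a single class")
        self._n_features = X.shape[1]
        self._fit(X, y, seed)
        return self

    def score(self, X) -> np.ndarray:
        if not self.trained:
            raise PairAuditError(f"adapter {self.name!r} is not trained")
        X = np.asarray(X)
        if X.shape[1] != self._n_features:
            raise PairAuditError(
                f"row dimension {X.shape[1]} != training dimension {self._n_features}")
        s = self._score(X)
        return np.clip(np.asarray(s, dtype=float), 0.0, 1.0)

    # subclass hooks -------------------------------------------------------
    def _fit(self, X, y, seed: int) -> None:
        raise NotImplementedError

    def _score(self, X) -> np.ndarray:
        raise NotImplementedError


class PairKernelSVMAdapter(ClassifierAdapter):
    """SVM with the precomputed pairwise min-product kernel.

    Margins are mapped to [0, 1] through a logistic squashing; AUC is
    rank-based, so any monotone map leaves the audit unchanged.
    """

    name = "pair_kernel_svm"
    symmetric = False  # the kernel itself is orientation-invariant

    def __init__(self, gamma: float = 1.0, C: float = 1.0):
        super().__init__(gamma=gamma, C=C)
        self.spec = KernelSpec(gamma)

    def _fit(self, X, y, seed: int) -> None:
        self._train_rows = np.asarray(X, dtype=float)
        gram = pair_kernel_gram(self.spec, self._train_rows)
        self._model = SVC(kernel="precomputed", C=self.hyperparameters["C"],
                          random_state=seed)
        self._model.fit(gram, y)

    def _score(self, X) -> np.ndarray:
        gram = pair_kernel_gram(self.spec, X, self._train_rows)
        margin = self._model.decision_function(gram)
        return 1.0 / (1.0 + np.exp(-margin))


class RandomForestAdapter(ClassifierAdapter):
    """Decision forest on concatenated pair vectors."""

    name = "random_forest"
    symmetric = True

    def __init__(self, n_estimators: int = 100, max_features: str | float = "sqrt",
                 min_samples_leaf: int = 1):
        super().__init__(n_estimators=n_estimators, max_features=max_features,
                         min_samples_leaf=min_samples_leaf)

    def _fit(self, X, y, seed: int) -> None:
        self._model = RandomForestClassifier(
            n_estimators=self.hyperparameters["n_estimators"],
            max_features=self.hyperparameters["max_features"],
            min_samples_leaf=self.hyperparameters["min_samples_leaf"],
            random_state=seed, n_jobs=1)
        self._model.fit(X, y)

    def _score(self, X) -> np.ndarray:
        proba = self._model.predict_proba(X)
        return proba[:, list(self._model.classes_).index(1)]


ADAPTERS = {
    PairKernelSVMAdapter.name: PairKernelSVMAdapter,
    RandomForestAdapter.name: RandomForestAdapter,
}

#: Default hyperparameter grids, sized to the usual 10-20 combinations.
DEFAULT_GRIDS = {
    PairKernelSVMAdapter.name: [{"gamma": 2.0 ** k, "C": 1.0} for k in range(-7, 4)],
    RandomForestAdapter.name: [{"n_estimators": n} for n in (100, 300)],
}


def make_adapter(name: str, **hyperparameters) -> ClassifierAdapter:
    try:
        cls = ADAPTERS[name]
    except KeyError:
        raise PairAuditError(f"unknown adapter {name!r}; available: {sorted(ADAPTERS)}") from None
    return cls(**hyperparameters)


# ---------------------------------------------------------------------------
# Pair-level fit / score helpers
# ---------------------------------------------------------------------------

def fit_pairs(adapter: ClassifierAdapter, fm: FeatureMap, pairs, seed: int) -> ClassifierAdapter:
    """Fit an adapter on a pair list, augmenting orientations if required."""
    X, y = pair_matrix(fm, pairs, symmetric=adapter.symmetric)
    return adapter.fit(X, y, seed)


def score_pairs(adapter: ClassifierAdapter, fm: FeatureMap, pairs) -> np.ndarray:
    """Score pairs; orientation-sensitive adapters average both orientations."""
    X, _ = pair_matrix(fm, pairs, symmetric=False)
    scores = adapter.score(X)
    if adapter.symmetric:
        d = X.shape[1] // 2
        flipped = np.concatenate([X[:, d:], X[:, :d]], axis=1)
        scores = 0.5 * (scores + adapter.score(flipped))
    return scores


def evaluate_auc(adapter: ClassifierAdapter, fm: FeatureMap, dataset) -> float:
    """AUC of an adapter on a labeled pair set."""
    scores = score_pairs(adapter, fm, dataset.pairs)
    labels = np.array([p.label for p in dataset.pairs])
    return auc(scores[labels == 1], scores[labels == 0])


def grid_select(factory, grid, split_round, fm: FeatureMap, seed: int,
                max_grid: int = 32):
    """Fit every hyperparameter setting on train, pick argmax validation AUC.

    Ties break toward the earlier grid entry.  Returns the winning
    trained adapter plus a table of (setting, validation AUC).
    """
    grid = list(grid)
    if not grid:
        raise PairAuditError("hyperparameter grid is empty")
    if len(grid) > max_grid:
        raise PairAuditError(f"grid of {len(grid)} exceeds the cap of {max_grid}")
    rows = []
    best = None
    best_auc = -np.inf
    for setting in grid:
        adapter = factory(**setting)
        fit_pairs(adapter, fm, split_round.train.pairs, seed)
        val_auc = evaluate_auc(adapter, fm, split_round.validation)
        rows.append({**setting, "validation_auc": val_auc})
        if val_auc > best_auc:
            best, best_auc = adapter, val_auc
    return best, pd.DataFrame(rows)
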