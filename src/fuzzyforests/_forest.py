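"""Bagged classification trees with out-of-bag permutation importance.

The importance is the mean decrease in out-of-bag accuracy when a feature is
permuted within the OOB sample, averaged across trees — the classical
random-forest variable importance (VIM).  scikit-learn's forests do not
expose the OOB form of permutation importance, so the bagging loop lives
here, on top of :class:`sklearn.tree.DecisionTreeClassifier`.

Sizing note: trees are grown on half-size bootstrap resamples with a small
leaf floor, and OOB evaluation is capped per tree.  This keeps repeated
screening runs cheap at survey scale (n in the low thousands) while leaving
the importance estimator unbiased; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeClassifier


def _accuracy_drop(tree, X_oob, y_oob, col, perm) -> float:
    """OOB accuracy decrease for one tree when column ``col`` is re-indexed
    by ``perm``.  The identity permutation yields exactly 0."""
    base = (tree.predict(X_oob, check_input=False) == y_oob).mean()
    Xp = X_oob.copy()
    Xp[:, col] = Xp[perm, col]
    permuted = (tree.predict(Xp, check_input=False) == y_oob).mean()
    return float(base - permuted)


class PermutationForest:
    """A bagged-tree classifier exposing OOB accuracy and OOB permutation VIM.

    Parameters mirror the screening defaults of the surrounding package:
    ``ntree`` trees, each grown on a bootstrap resample of
    ``sample_fraction * n`` rows (with replacement), splitting on ``mtry``
    candidate features per node (default ceil(sqrt(p))).  All randomness is
    a pure function of ``seed``.
    """

    def __init__(
        self,
        ntree: int = 50,
        mtry: int | None = None,
        sample_fraction: float = 0.5,
        min_samples_leaf: int = 5,
        n_permutations: int = 1,
        max_oob_samples: int | None = 500,
        seed: int = 0,
    ):
        if ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not 0 < sample_fraction <= 1:
            raise ValueError("sample_fraction must lie in (0, 1]")
        self.ntree = int(ntree)
        self.mtry = mtry
        self.sample_fraction = float(sample_fraction)
        self.min_samples_leaf = int(min_samples_leaf)
        self.n_permutations = int(n_permutations)
        self.max_oob_samples = max_oob_samples
        self.seed = int(seed)

    def fit(self, X, y, sample_weight=None):
        """Grow the forest and accumulate OOB accuracy and permutation VIM.

        ``sample_weight``, when given, biases the bootstrap draw (weighted
        bootstrap); trees themselves are fit unweighted.
        """
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("outcome has a single class; need both classes present")
        n, p = X.shape
        mtry = self.mtry or int(np.ceil(np.sqrt(p)))
        mtry = min(mtry, p)
        rng = np.random.default_rng(self.seed)
        n_boot = max(1, int(round(self.sample_fraction * n)))
        pweights = None
        if sample_weight is not None:
            sw = np.asarray(sample_weight, dtype=float)
            pweights = sw / sw.sum()

        vim_sum = np.zeros(p)
        vim_sumsq = np.zeros(p)
        oob_correct = np.zeros(n)
        oob_counts = np.zeros(n)
        trees = []
        for _ in range(self.ntree):
            if pweights is None:
                idx = rng.integers(0, n, n_boot)
            else:
                idx = rng.choice(n, size=n_boot, replace=True, p=pweights)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            oob = np.flatnonzero(~mask)
            tree = DecisionTreeClassifier(
                max_features=mtry,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[idx], y[idx])
            trees.append(tree)
            if len(oob) == 0:
                continue
            if self.max_oob_samples is not None and len(oob) > self.max_oob_samples:
                oob = rng.choice(oob, size=self.max_oob_samples, replace=False)
                oob.sort()
            Xo = X[oob]
            yo = y[oob]
            m = len(oob)
            pred = tree.predict(Xo, check_input=False)
            correct = pred == yo
            oob_correct[oob] += correct
            oob_counts[oob] += 1
            base = correct.mean()
            drop = np.zeros(p)
            for _ in range(self.n_permutations):
                # permute every feature at once: one stacked predict per tree
                stack = np.repeat(Xo[None, :, :], p, axis=0)
                for f in range(p):
                    stack[f, :, f] = Xo[rng.permutation(m), f]
                preds = tree.predict(
                    np.ascontiguousarray(stack.reshape(p * m, p)), check_input=False
                ).reshape(p, m)
                drop += base - (preds == yo).mean(axis=1)
            drop /= self.n_permutations
            vim_sum += drop
            vim_sumsq += drop**2

        self.trees_ = trees
        self.classes_ = classes
        self.n_features_ = p
        self.importances_ = vim_sum / self.ntree
        with np.errstate(invalid="ignore"):
            var = vim_sumsq / self.ntree - self.importances_**2
        self.importances_se_ = np.sqrt(np.clip(var, 0, None) / self.ntree)
        seen = oob_counts > 0
        self.oob_accuracy_ = (
            float((oob_correct[seen] / oob_counts[seen]).round(12).mean())
            if seen.any()
            else float("nan")
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Majority vote over trees (ties go to the lower class label)."""
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=np.int64)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for tree in self.trees_:
            pred = tree.predict(X, check_input=False)
            for c, i in class_index.items():
                votes[:, i] += pred == c
        return self.classes_[np.argmax(votes, axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        """Fraction of tree votes per class."""
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=float)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for tree in self.trees_:
            pred = tree.predict(X, check_input=False)
            for c, i in class_index.items():
                votes[:, i] += pred == c
        return votes / len(self.trees_)
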