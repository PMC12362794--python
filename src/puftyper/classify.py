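"""Penalized multiclass logistic-regression PUF authentication.

A library of profiles is vectorized into a shared indel feature space
(union of training keys, deterministic order), one original sample per
class trains a multinomial logistic regression (liblinear solver,
one-vs-rest, L1 or L2 penalty), and replicate queries are scored with
class probabilities. A PCA embedding provides a model-free sanity check
that replicates cluster together.

Estimators follow scikit-learn conventions (``fit``/``transform``/
``predict_proba``, trailing-underscore fitted attributes) and compose with
sklearn pipelines; the module-level ``train``/``predict``/``accuracy``
functions are thin wrappers over them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.utils.validation import check_is_fitted

from .indel import key_sort_key
from .profile import IndelProfile, PUFLibrary


class IndelFeaturizer(BaseEstimator, TransformerMixin):
    """Map indel profiles onto a fixed feature space of key frequencies.

    The feature space is the union of keys seen at fit time, sorted by the
    deterministic key order. At transform time each profile row holds the
    frequency of every space key computed over *all* of the profile's reads,
    so keys outside the space are dropped and their mass excluded from
    renormalization (rows may sum to < 1). Set ``renormalize=True`` to
    renormalize over the seen keys instead.
    """

    def __init__(self, renormalize: bool = False):
        self.renormalize = renormalize

    def fit(self, profiles: Sequence[IndelProfile], y=None) -> "IndelFeaturizer":
        keys: set[str] = set()
        for p in profiles:
            p.require_nonempty()
            keys.update(p.counts)
        if not keys:
            raise ValueError("cannot derive an empty feature space")
        self.feature_keys_ = sorted(keys, key=key_sort_key)
        self.key_index_ = {k: i for i, k in enumerate(self.feature_keys_)}
        return self

    def transform(self, profiles: Sequence[IndelProfile]) -> np.ndarray:
        check_is_fitted(self, "feature_keys_")
        X = np.zeros((len(profiles), len(self.feature_keys_)))
        for row, p in enumerate(profiles):
            n = p.n_reads
            seen_mass = 0.0
            for key, count in p.counts.items():
                col = self.key_index_.get(key)
                if col is not None:
                    X[row, col] = count / n
                    seen_mass += count / n
            if seen_mass == 0.0:
                warnings.warn(
                    f"profile {p.sample_id!r} shares no indel key with the "
                    "feature space; vector is all zeros",
                    stacklevel=2,
                )
            elif self.renormalize:
                X[row] /= seen_mass
        return X


class PUFClassifier(BaseEstimator, ClassifierMixin):
    """L1/L2-penalized multiclass logistic regression over indel features.

    One-vs-rest logistic regression fitted with the liblinear solver
    (one binary model per class), the scheme the pipeline's authentication
    step relies on. ``C`` is the inverse regularization strength. Class
    probabilities are the per-class sigmoid scores normalized to the
    simplex, computed from the stored coefficients so that a fitted model
    and its JSON round-trip predict identically.

    With ``hellinger=True`` (default) the frequency features are
    square-root transformed before fitting and scoring. The Hellinger
    transform is the standard preparation of compositional frequency data
    for linear models: it equalizes row norms and up-weights the rare
    outcome keys that carry most of the PUF-identifying signal, making the
    decision margins insensitive to the regularization strength.
    """

    def __init__(
        self,
        penalty: str = "l2",
        C: float = 1.0,
        random_state: int = 0,
        max_iter: int = 1000,
        tol: float = 1e-6,
        hellinger: bool = True,
    ):
        self.penalty = penalty
        self.C = C
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.hellinger = hellinger

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.sqrt(X) if self.hellinger else X

    def fit(self, X, y) -> "PUFClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes")
        if self.penalty not in ("l1", "l2"):
            raise ValueError(f"penalty must be 'l1' or 'l2', got {self.penalty!r}")
        base = LogisticRegression(
            l1_ratio=1.0 if self.penalty == "l1" else 0.0,
            C=self.C,
            solver="liblinear",
            random_state=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        ovr = OneVsRestClassifier(base).fit(self._prepare(X), y)
        self.classes_ = np.asarray(ovr.classes_)
        self.coef_ = np.vstack([est.coef_ for est in ovr.estimators_])
        self.intercept_ = np.concatenate([est.intercept_ for est in ovr.estimators_])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._prepare(X) @ self.coef_.T + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        scores = expit(self.decision_function(X))
        if scores.shape[1] == 1 and len(self.classes_) == 2:
            scores = np.hstack([1.0 - scores, scores])
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def n_nonzero_weights(self) -> int:
        check_is_fitted(self, "coef_")
        return int(np.count_nonzero(self.coef_))


@dataclass
class ClassifierModel:
    """A fitted featurizer + classifier pair: the PUF authenticator."""

    featurizer: IndelFeaturizer
    classifier: PUFClassifier

    @property
    def feature_keys(self) -> List[str]:
        return self.featurizer.feature_keys_

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "feature_keys": self.featurizer.feature_keys_,
            "renormalize": self.featurizer.renormalize,
            "classes": [str(c) for c in self.classifier.classes_],
            "coef": self.classifier.coef_.tolist(),
            "intercept": self.classifier.intercept_.tolist(),
            "penalty": self.classifier.penalty,
            "C": self.classifier.C,
            "hellinger": self.classifier.hellinger,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        feat = IndelFeaturizer(renormalize=payload["renormalize"])
        feat.feature_keys_ = list(payload["feature_keys"])
        feat.key_index_ = {k: i for i, k in enumerate(feat.feature_keys_)}
        clf = PUFClassifier(
            penalty=payload["penalty"],
            C=payload["C"],
            hellinger=payload.get("hellinger", True),
        )
        clf.classes_ = np.array(payload["classes"])
        clf.coef_ = np.array(payload["coef"])
        clf.intercept_ = np.array(payload["intercept"])
        return cls(featurizer=feat, classifier=clf)


@dataclass(frozen=True)
class Prediction:
    """Class-probability scores for one query sample."""

    query_id: str
    probabilities: Dict[str, float]

    @property
    def predicted(self) -> str:
        # argmax with deterministic alphabetical tie-break
        return max(sorted(self.probabilities), key=lambda g: self.probabilities[g])


def vectorize(
    library: PUFLibrary, featurizer: Optional[IndelFeaturizer] = None
) -> tuple[np.ndarray, List[str], IndelFeaturizer]:
    """Frequency matrix (samples x union keys) for a library.

    If no fitted featurizer is given, the feature space is derived from the
    library itself.
    """
    if featurizer is None:
        featurizer = IndelFeaturizer().fit(library.profiles)
    X = featurizer.transform(library.profiles)
    return X, library.sample_ids, featurizer


def train(
    library: PUFLibrary,
    penalty: str = "l2",
    C: float = 1.0,
    seed: int = 0,
    renormalize: bool = False,
) -> ClassifierModel:
    """Fit the authenticator on one training profile per class (originals)."""
    featurizer = IndelFeaturizer(renormalize=renormalize).fit(library.profiles)
    X = featurizer.transform(library.profiles)
    y = [library.group_of(s) for s in library.sample_ids]
    clf = PUFClassifier(penalty=penalty, C=C, random_state=seed).fit(X, y)
    return ClassifierModel(featurizer=featurizer, classifier=clf)


def predict(model: ClassifierModel, queries: PUFLibrary) -> List[Prediction]:
    """Score query profiles (replicates) with class probabilities."""
    X = model.featurizer.transform(queries.profiles)
    proba = model.classifier.predict_proba(X)
    classes = [str(c) for c in model.classifier.classes_]
    return [
        Prediction(query_id=sid, probabilities=dict(zip(classes, row)))
        for sid, row in zip(queries.sample_ids, proba)
    ]


def accuracy(predictions: Sequence[Prediction], truth: Dict[str, str]) -> float:
    """Fraction of queries whose argmax class equals the true group."""
    if not predictions:
        raise ValueError("no predictions")
    hits = sum(1 for p in predictions if p.predicted == truth[p.query_id])
    return hits / len(predictions)


def pca_embed(library: PUFLibrary, n_components: int = 2) -> np.ndarray:
    """PCA coordinates of the mean-centered profile frequency matrix."""
    X, _, _ = vectorize(library)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds the matrix rank bound {min(X.shape)}"
        )
    return PCA(n_components=n_components, random_state=0).fit_transform(X)
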