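"""Kernel-SVM binder/non-binder classifier.

The classifier realizes the standard soft-margin dual decision function

    f(x) = sum_i alpha_i y_i K(s_i, x) + b,    0 <= alpha_i <= C,

over support vectors s_i, with the sign rule: f(x) > 0 -> binder (+1),
otherwise non-binder (-1); an exact zero is called negative so that
"greater than zero" is strict. The quadratic program is delegated to
sklearn's SVC; the fitted object exposes the dual solution (support vectors,
alpha_i * y_i, bias) so the decision function can be independently
re-evaluated and audited.

Default hyperparameters: C = 1, gamma = 1/d for the RBF kernel (d = feature
dimension), matching the common SVM baseline when no tuning information is
available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .errors import ConfigError, TrainingError, ValidationError

KernelKind = Literal["rbf", "linear", "polynomial"]

MODEL_FILE_VERSION = 1


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    kind: rbf (default; K(x,x)=1, values in (0,1]), linear, or polynomial.
    gamma: RBF/polynomial width; None means 1/d at fit time.
    degree, coef0: polynomial parameters.
    """

    kind: KernelKind = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear", "polynomial"):
            raise ConfigError(f"unsupported kernel {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigError(f"gamma must be positive, got {self.gamma}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ConfigError(f"polynomial degree must be >= 1, got {self.degree}")

    def resolve_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features

    def __call__(self, A: np.ndarray, B: np.ndarray, n_features: int) -> np.ndarray:
        """Evaluate the Gram matrix K(A, B) explicitly."""
        A = np.atleast_2d(A)
        B = np.atleast_2d(B)
        g = self.resolve_gamma(n_features)
        if self.kind == "linear":
            return A @ B.T
        if self.kind == "polynomial":
            return (g * (A @ B.T) + self.coef0) ** self.degree
        d2 = (
            np.sum(A * A, axis=1)[:, None]
            + np.sum(B * B, axis=1)[None, :]
            - 2.0 * (A @ B.T)
        )
        return np.exp(-g * np.maximum(d2, 0.0))


class TapBinderClassifier(BaseEstimator, ClassifierMixin):
    """Soft-margin kernel SVM with +1/-1 labels and a strict sign rule.

    Parameters
    ----------
    kernel : {"rbf", "linear", "polynomial"}
    C : float
        Box-constraint parameter; every dual coefficient satisfies
        ``|alpha_i * y_i| <= C``.
    gamma : float or None
        RBF/polynomial width; ``None`` resolves to ``1/n_features``.
    degree, coef0 : polynomial kernel parameters.

    Attributes (after ``fit``)
    ----------
    support_vectors_ : (n_sv, d) array
    dual_coef_ : (n_sv,) array of alpha_i * y_i
    intercept_ : float, the bias b
    kernel_spec_ : resolved KernelSpec (gamma made explicit)
    """

    def __init__(
        self,
        kernel: KernelKind = "rbf",
        C: float = 1.0,
        gamma: float | None = None,
        degree: int = 3,
        coef0: float = 0.0,
        config_id: str | None = None,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.config_id = config_id

    def fit(self, X, y) -> "TapBinderClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise TrainingError(
                f"X/y shape mismatch: {X.shape} vs {y.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise TrainingError("non-finite feature values in training matrix")
        classes = set(np.unique(y).tolist())
        if classes != {-1, 1}:
            raise TrainingError(
                f"training labels must contain both +1 and -1, got {sorted(classes)}"
            )
        if self.C <= 0:
            raise ConfigError(f"C must be positive, got {self.C}")
        spec = KernelSpec(
            kind=self.kernel, gamma=self.gamma, degree=self.degree, coef0=self.coef0
        )
        gamma = spec.resolve_gamma(X.shape[1])
        svc = SVC(
            kernel={"polynomial": "poly"}.get(spec.kind, spec.kind),
            C=self.C,
            gamma=gamma,
            degree=spec.degree,
            coef0=spec.coef0,
        )
        svc.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([-1, 1])
        self.support_vectors_ = svc.support_vectors_.copy()
        # sklearn orders dual_coef_ by class blocks; with classes (-1, +1)
        # the stored coefficients are already alpha_i * y_i.
        self.dual_coef_ = svc.dual_coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.kernel_spec_ = KernelSpec(
            kind=spec.kind, gamma=gamma, degree=spec.degree, coef0=spec.coef0
        )
        return self

    def _check_X(self, X) -> np.ndarray:
        if not hasattr(self, "support_vectors_"):
            raise TrainingError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"feature dimension mismatch: expected {self.n_features_in_}, "
                f"got {X.shape[1]}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """Raw decision values f(x) = sum_i (alpha_i y_i) K(s_i, x) + b."""
        X = self._check_X(X)
        K = self.kernel_spec_(X, self.support_vectors_, self.n_features_in_)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """+1 iff f(x) > 0, else -1 (exact zero is called non-binder)."""
        return np.where(self.decision_function(X) > 0, 1, -1)


@dataclass
class TrainedModel:
    """Persistable trained model: dual solution + kernel + encoding identity."""

    classifier: TapBinderClassifier
    config_id: str | None = None

    @property
    def support_vectors(self) -> np.ndarray:
        return self.classifier.support_vectors_

    @property
    def dual_coefs(self) -> np.ndarray:
        return self.classifier.dual_coef_

    @property
    def bias(self) -> float:
        return self.classifier.intercept_

    @property
    def kernel(self) -> KernelSpec:
        return self.classifier.kernel_spec_

    def save(self, path: str | Path, encoding_config: dict | None = None) -> None:
        clf = self.classifier
        payload = {
            "format_version": MODEL_FILE_VERSION,
            "kernel": {
                "kind": clf.kernel_spec_.kind,
                "gamma": clf.kernel_spec_.gamma,
                "degree": clf.kernel_spec_.degree,
                "coef0": clf.kernel_spec_.coef0,
            },
            "C": clf.C,
            "bias": clf.intercept_,
            "dual_coefs": clf.dual_coef_.tolist(),
            "support_vectors": clf.support_vectors_.tolist(),
            "n_features": clf.n_features_in_,
            "config_id": self.config_id,
            "encoding_config": encoding_config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(
        cls, path: str | Path, expect_config_id: str | None = None
    ) -> tuple["TrainedModel", dict | None]:
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != MODEL_FILE_VERSION:
            raise ValidationError(
                f"unsupported model file version {payload.get('format_version')}"
            )
        if (
            expect_config_id is not None
            and payload.get("config_id") != expect_config_id
        ):
            raise ValidationError(
                "encoding config hash mismatch: model was trained with "
                f"{payload.get('config_id')}, expected {expect_config_id}"
            )
        k = payload["kernel"]
        clf = TapBinderClassifier(
            kernel=k["kind"], C=payload["C"], gamma=k["gamma"],
            degree=k["degree"], coef0=k["coef0"],
        )
        clf.n_features_in_ = int(payload["n_features"])
        clf.classes_ = np.array([-1, 1])
        clf.support_vectors_ = np.asarray(payload["support_vectors"], dtype=float)
        clf.dual_coef_ = np.asarray(payload["dual_coefs"], dtype=float)
        clf.intercept_ = float(payload["bias"])
        clf.kernel_spec_ = KernelSpec(
            kind=k["kind"], gamma=k["gamma"], degree=k["degree"], coef0=k["coef0"]
        )
        return cls(classifier=clf, config_id=payload.get("config_id")), payload.get(
            "encoding_config"
        )


def train(
    X: np.ndarray,
    y: Sequence[int],
    kernel: KernelSpec | None = None,
    C: float = 1.0,
    config_id: str | None = None,
) -> TrainedModel:
    """Fit a kernel SVM; thin wrapper over :class:`TapBinderClassifier`."""
    kernel = kernel or KernelSpec()
    clf = TapBinderClassifier(
        kernel=kernel.kind, C=C, gamma=kernel.gamma,
        degree=kernel.degree, coef0=kernel.coef0, config_id=config_id,
    ).fit(X, y)
    return TrainedModel(classifier=clf, config_id=config_id)


def decision_value(model: TrainedModel, x: np.ndarray) -> float:
    """Decision value for a single feature vector."""
    return float(model.classifier.decision_function(np.atleast_2d(x))[0])


def classify(model: TrainedModel, x: np.ndarray) -> int:
    """+1 iff the decision value exceeds zero, else -1."""
    return 1 if decision_value(model, x) > 0 else -1
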