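"""SVM classification stage shared by the RANK, CURVE and MORPH baselines."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SvmSpec", "SvmClassifier", "fit_svm", "predict_scores"]


@dataclass(frozen=True)
class SvmSpec:
    """Kernel and regularization settings; one fixed default is shared by all
    baselines so method comparisons differ only in their feature stacks."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("numeric gamma must be positive")


class SvmClassifier:
    """SVC wrapper: training-fold standardization, constant-column dropping,
    named-feature validation and signed decision scores (malignant > 0)."""

    def __init__(self, spec: SvmSpec = SvmSpec()) -> None:
        self.spec = spec
        self.feature_names_: list[str] | None = None
        self.kept_: np.ndarray | None = None
        self.scaler_: StandardScaler | None = None
        self.svc_: SVC | None = None

    def fit(self, X: pd.DataFrame, y) -> "SvmClassifier":
        y = np.asarray([1 if lbl == "malignant" else 0 for lbl in y])
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        values = X.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("features must be finite")
        self.feature_names_ = list(X.columns)
        keep = values.std(axis=0) > 0
        if not keep.all():
            dropped = [n for n, k in zip(self.feature_names_, keep) if not k]
            warnings.warn(f"dropping constant feature columns: {dropped}", stacklevel=2)
        if not keep.any():
            raise ValueError("all feature columns are constant")
        self.kept_ = keep
        values = values[:, keep]
        if self.spec.standardize:
            self.scaler_ = StandardScaler().fit(values)
            values = self.scaler_.transform(values)
        self.svc_ = SVC(kernel=self.spec.kernel, C=self.spec.C, gamma=self.spec.gamma)
        self.svc_.fit(values, y)
        return self

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        if self.svc_ is None:
            raise RuntimeError("classifier is not fitted")
        if list(X.columns) != self.feature_names_:
            raise ValueError("feature names differ from the training table")
        values = X.to_numpy(dtype=float)[:, self.kept_]
        if self.scaler_ is not None:
            values = self.scaler_.transform(values)
        return values

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Signed SVM decision values; positive means malignant."""
        return self.svc_.decision_function(self._prepare(X))

    def predict_labels(self, X: pd.DataFrame) -> list[str]:
        return ["malignant" if s > 0 else "benign" for s in self.decision_scores(X)]


def fit_svm(X: pd.DataFrame, y, spec: SvmSpec = SvmSpec()) -> SvmClassifier:
    """Fit the shared SVM stage on a named feature table."""
    return SvmClassifier(spec).fit(X, y)


def predict_scores(clf: SvmClassifier, X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Per-sample decision score and hard label (score > 0 -> malignant)."""
    scores = clf.decision_scores(X)
    return scores, ["malignant" if s > 0 else "benign" for s in scores]
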