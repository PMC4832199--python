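"""End-to-end CADx method objects: SDAE, RANK, CURVE and MORPH.

Each method exposes the same two-call protocol the cross-validation harness
drives: ``fit(train_ids, strategy, seed)`` and ``score(test_ids, strategy)``
returning one continuous malignancy score and one hard label per test case.
Unsupervised per-case inputs (patches, texture features, morphology
features) are precomputed once per dataset, since they do not depend on the
train/test split; only classifier training happens inside each fold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import SvmSpec, fit_svm
from .dae import TrainSpec
from .morphology import breast_morph, lung_morph
from .roi_prep import extract_roi, to_patch
from .sdae import SdaeClassifier
from .slices import CaseRecord, expand_all, select_single, vote
from .synthdata import SynthCase
from .texture import curve_features, rank_features, bootstrap_select

__all__ = [
    "prepare_case_records",
    "SdaeMethod",
    "RankMethod",
    "CurveMethod",
    "MorphMethod",
    "build_method",
    "METHOD_NAMES",
]

METHOD_NAMES = ("sdae", "rank", "curve", "morph")
DEFAULT_MARGIN = 0.15


def prepare_case_records(cases: list[SynthCase], margin: float = DEFAULT_MARGIN) -> list[CaseRecord]:
    """Crop each slice's mask bounding box (with margin) and build 28x28 samples."""
    records = []
    for case in cases:
        samples = []
        for idx, (img, mask) in enumerate(zip(case.images, case.masks)):
            roi = extract_roi(img.astype(float) / 255.0, mask, margin=margin)
            samples.append(to_patch(roi, label=case.label, case_id=case.case_id, slice_index=idx))
        records.append(CaseRecord(case.case_id, case.label, samples, thickness=case.thickness))
    return records


def _case_vote_and_score(hard_labels: list[str], scores: np.ndarray) -> tuple[str, float]:
    """ALL-strategy aggregation: majority-vote hard label, mean score for AUC."""
    return vote(hard_labels), float(np.mean(scores))


class SdaeMethod:
    """The SDAE pipeline wrapped for the harness."""

    name = "sdae"

    def __init__(
        self,
        cases: list[SynthCase],
        pretrain_spec: TrainSpec | None = None,
        finetune_spec: TrainSpec | None = None,
        hidden_sizes: tuple[int, int] = (200, 100),
        margin: float = DEFAULT_MARGIN,
    ) -> None:
        self.records = {r.case_id: r for r in prepare_case_records(cases, margin)}
        self.pretrain_spec = pretrain_spec or TrainSpec(learning_rate=0.1, epochs=15)
        self.finetune_spec = finetune_spec or TrainSpec(learning_rate=0.05, epochs=100)
        self.hidden_sizes = hidden_sizes
        self.model: SdaeClassifier | None = None

    def fit(self, train_ids: list[str], strategy: str, seed: int) -> None:
        records = [self.records[i] for i in train_ids]
        if strategy == "single":
            samples = [select_single(r) for r in records]
        elif strategy == "all":
            samples = expand_all(records, np.random.default_rng(seed))
        else:
            raise ValueError("strategy must be 'single' or 'all'")
        pre = TrainSpec(self.pretrain_spec.learning_rate, self.pretrain_spec.epochs,
                        self.pretrain_spec.batch_size, seed)
        fine = TrainSpec(self.finetune_spec.learning_rate, self.finetune_spec.epochs,
                         self.finetune_spec.batch_size, seed + 1)
        self.model = SdaeClassifier(hidden_sizes=self.hidden_sizes)
        self.model.pretrain(samples, pre)
        self.model.finetune(samples, fine)

    def score(self, test_ids: list[str], strategy: str) -> tuple[np.ndarray, list[str]]:
        if self.model is None:
            raise RuntimeError("fit() must run before score()")
        scores, labels = [], []
        for cid in test_ids:
            record = self.records[cid]
            if strategy == "single":
                p = self.model.predict(select_single(record))
                scores.append(p.p_malignant)
                labels.append(p.hard_label)
            else:
                probs = self.model.predict_proba(record.slices)[:, 1]
                hard = ["malignant" if p > 0.5 else "benign" for p in probs]
                lbl, sc = _case_vote_and_score(hard, probs)
                scores.append(sc)
                labels.append(lbl)
        return np.array(scores), labels


class _SvmFeatureMethod:
    """Shared scaffolding for the feature-table + SVM baselines."""

    name = "base"
    case_level = False

    def __init__(self, cases: list[SynthCase], svm_spec: SvmSpec = SvmSpec(), margin: float = DEFAULT_MARGIN):
        self.svm_spec = svm_spec
        self.margin = margin
        self.labels = {c.case_id: c.label for c in cases}
        self.tables = self._precompute(cases)  # case_id -> per-slice (or 1-row) DataFrame
        self.clf = None
        self.selected: list[str] | None = None

    def _precompute(self, cases: list[SynthCase]) -> dict[str, pd.DataFrame]:
        raise NotImplementedError

    def _select(self, X: pd.DataFrame, y: list[str], seed: int) -> pd.DataFrame:
        return X  # no selection by default

    def _train_table(self, train_ids: list[str], strategy: str) -> tuple[pd.DataFrame, list[str]]:
        frames, y = [], []
        for cid in train_ids:
            t = self.tables[cid]
            if self.case_level or strategy == "all":
                frames.append(t)
                y += [self.labels[cid]] * len(t)
            else:  # single: middle slice row
                frames.append(t.iloc[[(len(t) - 1) // 2]])
                y.append(self.labels[cid])
        return pd.concat(frames, ignore_index=True), y

    def fit(self, train_ids: list[str], strategy: str, seed: int) -> None:
        X, y = self._train_table(train_ids, strategy)
        X = self._select(X, y, seed)
        self.clf = fit_svm(X, y, self.svm_spec)
        self.selected = list(X.columns)

    def score(self, test_ids: list[str], strategy: str) -> tuple[np.ndarray, list[str]]:
        if self.clf is None:
            raise RuntimeError("fit() must run before score()")
        scores, labels = [], []
        for cid in test_ids:
            t = self.tables[cid][self.selected]
            if self.case_level or strategy == "single":
                rows = t if self.case_level else t.iloc[[(len(t) - 1) // 2]]
                s = self.clf.decision_scores(rows)[0]
                scores.append(float(s))
                labels.append("malignant" if s > 0 else "benign")
            else:
                s = self.clf.decision_scores(t)
                hard = ["malignant" if v > 0 else "benign" for v in s]
                lbl, sc = _case_vote_and_score(hard, s)
                scores.append(sc)
                labels.append(lbl)
        return np.array(scores), labels


class RankMethod(_SvmFeatureMethod):
    """RANK baseline: ranklet + GLCM texture features, bootstrap-selected, SVM."""

    name = "rank"

    def __init__(self, cases, svm_spec: SvmSpec = SvmSpec(), margin: float = DEFAULT_MARGIN,
                 bootstrap_B: int = 30, bootstrap_k: int = 8, bootstrap_tau: float = 0.5):
        self.B, self.k, self.tau = bootstrap_B, bootstrap_k, bootstrap_tau
        super().__init__(cases, svm_spec, margin)

    def _precompute(self, cases):
        tables = {}
        for case in cases:
            rows = []
            for img, mask in zip(case.images, case.masks):
                roi = extract_roi(img.astype(float) / 255.0, mask, margin=self.margin)
                rows.append(rank_features(roi).as_dict())
            tables[case.case_id] = pd.DataFrame(rows)
        return tables

    def _select(self, X, y, seed):
        k = min(self.k, X.shape[1])
        names = bootstrap_select(X, y, B=self.B, k=k, tau=self.tau,
                                 rng=np.random.default_rng(seed))
        if not names:  # threshold left nothing: fall back to the full stack
            return X
        return X[names]


class CurveMethod(_SvmFeatureMethod):
    """CURVE baseline: sub-band decomposition + GLCM texture features, SVM."""

    name = "curve"

    def _precompute(self, cases):
        tables = {}
        for case in cases:
            rows = []
            for img, mask in zip(case.images, case.masks):
                roi = extract_roi(img.astype(float) / 255.0, mask, margin=self.margin)
                patch = to_patch(roi).patch  # fixed 28x28 grid for the decomposition
                rows.append(curve_features(patch).as_dict())
            tables[case.case_id] = pd.DataFrame(rows)
        return tables


class MorphMethod(_SvmFeatureMethod):
    """MORPH baseline: clinical morphology features from the supplied masks.

    Morphology pools over all member slices (volume, maxima), so this method
    is case-level and ignores the SINGLE/ALL switch.
    """

    name = "morph"
    case_level = True

    def _precompute(self, cases):
        multi = any(len(c.images) > 1 for c in cases)
        extract = lung_morph if multi else breast_morph
        return {c.case_id: pd.DataFrame([extract(c).as_dict()]) for c in cases}


def build_method(name: str, cases: list[SynthCase], **kwargs):
    """Instantiate a harness-ready method by name."""
    builders = {"sdae": SdaeMethod, "rank": RankMethod, "curve": CurveMethod, "morph": MorphMethod}
    if name not in builders:
        raise ValueError(f"unknown method {name!r}; choose from {METHOD_NAMES}")
    return builders[name](cases, **kwargs)
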