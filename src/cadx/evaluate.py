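"""Cross-validated evaluation protocol.

Ten repetitions of stratified case-level 10-fold cross-validation with the
same partitions shared by every method; six diagnostic metrics per fold
(AUC, ACC, SENS, SPEC, PPV, NPV, malignant = positive class); Bland-Altman
limits of agreement and pooled-variance two-sample t-tests for pairwise
method comparison; per-fold tables and plot data exported as CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .pipelines import build_method
from .synthdata import SynthCase

__all__ = [
    "FoldPlan",
    "make_folds",
    "six_metrics",
    "METRIC_NAMES",
    "BlandAltman",
    "bland_altman",
    "two_sample_t",
    "MetricsReport",
    "run_experiment",
]

METRIC_NAMES = ["AUC", "ACC", "SENS", "SPEC", "PPV", "NPV"]


# -- fold plans ---------------------------------------------------------------


@dataclass
class FoldPlan:
    """Repeated case-level k-fold partitions shared across methods.

    ``repetitions[r][f]`` is the list of test-set case ids of fold ``f`` in
    repetition ``r``; within a repetition the folds partition all cases, and
    the repetitions are pairwise distinct partitions.
    """

    repetitions: list[list[list[str]]]
    seed: int

    @property
    def n_repetitions(self) -> int:
        return len(self.repetitions)

    @property
    def n_folds(self) -> int:
        return len(self.repetitions[0])

    def all_case_ids(self) -> set[str]:
        return {cid for fold in self.repetitions[0] for cid in fold}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"seed": self.seed, "repetitions": self.repetitions}))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(repetitions=d["repetitions"], seed=d["seed"])


def _partition_signature(fold_sets: list[list[str]]) -> frozenset:
    return frozenset(frozenset(f) for f in fold_sets)


def make_folds(cases, seed: int, n_repetitions: int = 10, n_folds: int = 10) -> FoldPlan:
    """Stratified-by-class random k-fold partitions of the cases.

    ``cases`` may be objects with ``case_id``/``label`` or ``(id, label)``
    pairs.  Partition distinctness across repetitions is enforced by
    rejection sampling.
    """
    pairs = [(c.case_id, c.label) if hasattr(c, "case_id") else tuple(c) for c in cases]
    ids = np.array([p[0] for p in pairs])
    labels = np.array([p[1] for p in pairs])
    if len(ids) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} cases")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < n_folds:
        raise ValueError("too few cases in a class for stratified folding")
    if len(set(ids)) != len(ids):
        raise ValueError("case ids must be unique")

    repetitions: list[list[list[str]]] = []
    seen: set[frozenset] = set()
    attempt = 0
    while len(repetitions) < n_repetitions:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed * 1009 + attempt) % (2**31))
        folds = [list(ids[test_idx]) for _, test_idx in skf.split(ids, labels)]
        sig = _partition_signature(folds)
        if sig not in seen:
            seen.add(sig)
            repetitions.append(folds)
        attempt += 1
        if attempt > 1000:
            raise RuntimeError("could not draw distinct partitions")
    return FoldPlan(repetitions=repetitions, seed=seed)


# -- metrics ------------------------------------------------------------------


def six_metrics(labels, hard_preds, scores) -> dict[str, float]:
    """AUC/ACC/SENS/SPEC/PPV/NPV for one fold; malignant is positive.

    AUC is the rank statistic (Mann-Whitney U / (n1 n2), ties at one half).
    Ratios with zero denominator are reported as NaN, never as 0.
    """
    y = np.asarray([1 if l == "malignant" else 0 for l in labels])
    p = np.asarray([1 if l == "malignant" else 0 for l in hard_preds])
    if len(y) == 0 or len(y) != len(p):
        raise ValueError("labels and predictions must be nonempty and equal-length")
    scores = np.asarray(scores, dtype=float)
    tp = int(((y == 1) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    auc = roc_auc_score(y, scores) if len(np.unique(y)) == 2 else float("nan")
    return {
        "AUC": float(auc),
        "ACC": ratio(tp + tn, len(y)),
        "SENS": ratio(tp, tp + fn),
        "SPEC": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
    }


# -- agreement statistics -----------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    """Limits-of-agreement summary of paired per-fold metric values."""

    mean_diff: float
    sd_diff: float
    upper_limit: float  # mean_diff + 1.96 sd
    lower_limit: float  # mean_diff - 1.96 sd
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman agreement of two paired per-fold metric series (a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd,
        upper_limit=mean_diff + 1.96 * sd,
        lower_limit=mean_diff - 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=diffs,
    )


def two_sample_t(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test on per-fold metric values.

    Zero pooled variance with equal means returns (0, 1) by convention.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# -- experiment driver --------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-fold six-metric table plus aggregates and pairwise comparisons."""

    per_fold: pd.DataFrame  # columns: method, repetition, fold, AUC..NPV
    aggregate: pd.DataFrame  # mean/sd per metric per method (NaN folds excluded)
    comparisons: pd.DataFrame  # pairwise Bland-Altman + t-test on ACC and AUC

    def summary(self) -> str:
        lines = ["Per-method aggregate over all folds (mean ± sd):"]
        for _, row in self.aggregate.iterrows():
            vals = "  ".join(
                f"{m}={row[f'{m}_mean']:.3f}±{row[f'{m}_sd']:.3f}" for m in METRIC_NAMES
            )
            lines.append(f"  {row['method']:>6s}: {vals}")
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_fold.to_csv(out / "per_fold_metrics.csv", index=False)
        self.aggregate.to_csv(out / "aggregate_metrics.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)


def _fold_seed(plan_seed: int, rep: int, fold: int) -> int:
    return (plan_seed * 100003 + rep * 1009 + fold * 13 + 7) % (2**31)


def run_experiment(
    cases: list[SynthCase],
    methods,
    strategy: str,
    plan: FoldPlan,
    method_kwargs: dict | None = None,
) -> MetricsReport:
    """Run every method through the shared fold plan and report six metrics.

    ``methods`` is a list of method names ({'sdae','rank','curve','morph'})
    or prebuilt method objects.  Training uses the strategy's sample
    expansion (ALL) or middle-slice selection (SINGLE); evaluation is always
    at case level (ALL aggregates slices by majority vote, with the mean
    slice malignancy score as the case score for AUC).  A leak check asserts
    that no case id appears on both sides of any split.
    """
    if strategy not in ("single", "all"):
        raise ValueError("strategy must be 'single' or 'all'")
    case_ids = {c.case_id for c in cases}
    if plan.all_case_ids() != case_ids:
        raise ValueError("fold plan does not cover exactly the given cases")
    method_kwargs = method_kwargs or {}
    objs = [m if not isinstance(m, str) else build_method(m, cases, **method_kwargs.get(m, {}))
            for m in methods]
    truth = {c.case_id: c.label for c in cases}

    rows = []
    for rep_idx, folds in enumerate(plan.repetitions):
        for fold_idx, test_ids in enumerate(folds):
            test_set = set(test_ids)
            train_ids = sorted(case_ids - test_set)
            if test_set & set(train_ids) or test_set | set(train_ids) != case_ids:
                raise AssertionError("train/test leakage or incomplete partition")
            seed = _fold_seed(plan.seed, rep_idx, fold_idx)
            labels = [truth[cid] for cid in test_ids]
            for m in objs:
                m.fit(train_ids, strategy, seed)
                scores, hard = m.score(list(test_ids), strategy)
                row = {"method": m.name, "repetition": rep_idx, "fold": fold_idx}
                row.update(six_metrics(labels, hard, scores))
                rows.append(row)
    per_fold = pd.DataFrame(rows)

    agg_rows = []
    for name, grp in per_fold.groupby("method", sort=False):
        row = {"method": name}
        for metric in METRIC_NAMES:
            vals = grp[metric].dropna()
            row[f"{metric}_mean"] = vals.mean() if len(vals) else float("nan")
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else float("nan")
        agg_rows.append(row)
    aggregate = pd.DataFrame(agg_rows)

    comp_rows = []
    names = [m.name for m in objs]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = per_fold[per_fold["method"] == names[i]].sort_values(["repetition", "fold"])
            b = per_fold[per_fold["method"] == names[j]].sort_values(["repetition", "fold"])
            for metric in ("ACC", "AUC"):
                ba = bland_altman(a[metric].to_numpy(), b[metric].to_numpy())
                t, p = two_sample_t(a[metric].to_numpy(), b[metric].to_numpy())
                comp_rows.append(
                    {
                        "pair": f"{names[i]}-{names[j]}",
                        "metric": metric,
                        "mean_diff": ba.mean_diff,
                        "sd_diff": ba.sd_diff,
                        "upper_limit": ba.upper_limit,
                        "lower_limit": ba.lower_limit,
                        "t": t,
                        "p": p,
                    }
                )
    comparisons = pd.DataFrame(
        comp_rows, columns=["pair", "metric", "mean_diff", "sd_diff",
                            "upper_limit", "lower_limit", "t", "p"]
    )
    return MetricsReport(per_fold=per_fold, aggregate=aggregate, comparisons=comparisons)
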