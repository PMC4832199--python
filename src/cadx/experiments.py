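"""Canned end-to-end studies used by the examples and the reproduction script.

These wire the synthetic generator, patch preparation, the SDAE classifier
and the evaluation harness into single calls with fixed, documented problem
sizes, so a whole study is reproducible from one seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .dae import TrainSpec
from .evaluate import MetricsReport, make_folds, run_experiment
from .pipelines import prepare_case_records
from .sdae import SdaeClassifier
from .synthdata import SynthConfig, generate_ct_dataset, generate_us_dataset

__all__ = ["us_holdout_auc", "sdae_seed_study", "ct_voting_experiment"]


def us_holdout_auc(
    seed: int,
    n_train_per_class: int = 400,
    n_test_per_class: int = 100,
    hidden_sizes: tuple[int, int] = (200, 100),
    pretrain_spec: TrainSpec | None = None,
    finetune_spec: TrainSpec | None = None,
) -> float:
    """Train the SDAE on synthetic US data and return the held-out test AUC.

    Cases are generated with the default class effect sizes; the first
    ``n_train_per_class`` of each class train the model, the remainder are
    the test set (generation is i.i.d., so the split is exchangeable).
    """
    n_per_class = n_train_per_class + n_test_per_class
    cfg = SynthConfig(modality="us", n_benign=n_per_class, n_malignant=n_per_class, seed=seed)
    records = prepare_case_records(generate_us_dataset(cfg))
    benign = [r for r in records if r.label == "benign"]
    malignant = [r for r in records if r.label == "malignant"]
    train = [r.slices[0] for r in benign[:n_train_per_class] + malignant[:n_train_per_class]]
    test = [r.slices[0] for r in benign[n_train_per_class:] + malignant[n_train_per_class:]]

    model = SdaeClassifier(hidden_sizes=hidden_sizes)
    model.pretrain(train, pretrain_spec or TrainSpec(learning_rate=0.1, epochs=15, seed=seed))
    model.finetune(train, finetune_spec or TrainSpec(learning_rate=0.05, epochs=100, seed=seed + 1))
    scores = model.predict_proba(test)[:, 1]
    y = [1 if s.label == "malignant" else 0 for s in test]
    return float(roc_auc_score(y, scores))


def sdae_seed_study(base_seed: int, n_seeds: int = 10, **kwargs) -> list[float]:
    """Held-out SDAE AUC across ``n_seeds`` consecutive seeds."""
    return [us_holdout_auc(base_seed + i, **kwargs) for i in range(n_seeds)]


def ct_voting_experiment(
    seed: int,
    n_per_class: int = 30,
    methods: tuple[str, ...] = ("morph", "curve"),
) -> MetricsReport:
    """10x10-fold ALL-strategy comparison on a synthetic CT nodule set.

    Runs the full shared-partition protocol (leak checking included) with
    the fast baseline methods at a desk-scale case count.
    """
    cfg = SynthConfig(
        modality="ct", n_benign=n_per_class, n_malignant=n_per_class,
        image_size=48, pixel_spacing=0.7, slice_thickness=1.5,
        slices_per_case_range=(3, 9), seed=seed,
    )
    cases = generate_ct_dataset(cfg)
    plan = make_folds(cases, seed=seed)
    return run_experiment(cases, list(methods), "all", plan)
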