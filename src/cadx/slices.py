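"""Slice-selection strategies and nodule-level majority voting.

CT nodules span several axial slices.  Two ways of presenting a nodule to a
2-D classifier are supported: SINGLE, which keeps only the middle member
slice, and ALL, which trains on every member slice and aggregates test-time
slice predictions by majority vote — a nodule is called malignant iff
strictly more than half of its slices are called malignant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi_prep import RoiSample

__all__ = ["CaseRecord", "select_single", "expand_all", "vote"]


@dataclass
class CaseRecord:
    """One lesion/nodule: ordered member-slice samples plus metadata."""

    case_id: str
    label: str
    slices: list[RoiSample]
    thickness: float = 1.0

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a case must have at least one slice")
        self.slices = sorted(self.slices, key=lambda s: s.slice_index)


def select_single(case: CaseRecord) -> RoiSample:
    """The representative middle slice: index floor((n-1)/2) (lower middle for even n)."""
    n = len(case.slices)
    return case.slices[(n - 1) // 2]


def expand_all(cases: list[CaseRecord], rng: np.random.Generator) -> list[RoiSample]:
    """All member slices of all training cases, in a seeded random permutation.

    Each slice carries its case's label; the permutation is a bijection on
    the multiset of slices.
    """
    pool = [s for c in cases for s in c.slices]
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


def vote(case_predictions: list[str]) -> str:
    """Majority vote over slice-level hard labels.

    Malignant iff count(malignant) > n/2; an exact half (even n) is benign,
    per the strict "more than half" rule.
    """
    if not case_predictions:
        raise ValueError("cannot vote over an empty prediction list")
    n_mal = sum(1 for p in case_predictions if p == "malignant")
    return "malignant" if n_mal > len(case_predictions) / 2 else "benign"
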