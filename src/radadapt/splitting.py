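"""Patient-level train/test partition and stratified cross-validation folds.

The held-out test set is drawn per class so that its prevalence is as close
to the overall prevalence as integer counts allow; no patient id ever
appears on both sides.  Folds are a stratified k-fold partition of the
train-CV ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class SplitPlan:
    """Train-CV / test partition with optional CV folds.

    ``folds`` lists disjoint validation id-sets covering ``train_ids``.
    """

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    folds: list[list[str]] = field(default_factory=list)

    def validate(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"patient leakage: ids in both train and test: {sorted(overlap)[:5]}")
        if self.folds:
            fold_union: set[str] = set()
            for f in self.folds:
                fs = set(f)
                if fs & fold_union:
                    raise ValueError("folds are not pairwise disjoint")
                fold_union |= fs
            if fold_union != set(self.train_ids):
                raise ValueError("folds do not partition train_ids")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": list(self.train_ids),
                    "test_ids": list(self.test_ids),
                    "folds": [list(f) for f in self.folds],
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        plan = cls(
            train_ids=d["train_ids"],
            test_ids=d["test_ids"],
            seed=d["seed"],
            folds=[list(f) for f in d.get("folds", [])],
        )
        plan.validate()
        return plan


def _best_class1_test_count(n_test: int, n1: int, n0: int, prevalence: float) -> int:
    """Integer class-1 allocation minimizing |test prevalence - overall|."""
    lo = max(0, n_test - n0)
    hi = min(n1, n_test)
    candidates = range(lo, hi + 1)
    return min(candidates, key=lambda k: (abs(k / n_test - prevalence), k))


def make_split(labels: pd.Series, test_fraction: float = 0.15, seed: int = 0) -> SplitPlan:
    """Stratified patient-level split into train-CV and held-out test ids.

    The test size is ``round(test_fraction * n)``; the class-1 test count is
    chosen to minimize the gap between test prevalence and overall
    prevalence, then patients are sampled per class without replacement.
    Deterministic for a fixed seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0,1), got {test_fraction}")
    labels = pd.Series(labels)
    n = len(labels)
    if n < 10:
        raise ValueError(f"need at least 10 patients, got {n}")
    y = labels.to_numpy()
    ids = np.asarray(labels.index)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to stratify the split")

    n_test = int(round(test_fraction * n))
    n_test = max(1, min(n - 1, n_test))
    prevalence = n1 / n
    n1_test = _best_class1_test_count(n_test, n1, n0, prevalence)
    n0_test = n_test - n1_test

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for cls, k in ((1, n1_test), (0, n0_test)):
        cls_ids = ids[y == cls]
        chosen = rng.choice(len(cls_ids), size=k, replace=False)
        test_ids.extend(cls_ids[np.sort(chosen)])
    test_set = set(test_ids)
    train_ids = [i for i in ids if i not in test_set]
    plan = SplitPlan(train_ids=train_ids, test_ids=list(test_ids), seed=seed)
    plan.validate()
    return plan


def make_folds(plan: SplitPlan, labels: pd.Series, k: int = 5) -> SplitPlan:
    """Populate ``plan.folds`` with a stratified k-fold partition of train ids.

    Fold sizes differ by at most one and per-fold class-1 counts stay within
    one of proportional allocation.  Returns the same plan, mutated.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    train_ids = np.asarray(plan.train_ids)
    if len(train_ids) < k:
        raise ValueError(f"k={k} exceeds train size {len(train_ids)}")
    y = pd.Series(labels).loc[train_ids].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=plan.seed)
    folds = [list(train_ids[val_idx]) for _, val_idx in skf.split(np.zeros(len(y)), y)]
    for f in folds:
        fy = pd.Series(labels).loc[f].to_numpy()
        if fy.min() == fy.max():
            raise ValueError("a fold contains a single class; reduce k or rebalance")
    plan.folds = folds
    plan.validate()
    return plan
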