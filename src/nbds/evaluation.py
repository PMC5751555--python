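"""Balanced repeated-holdout evaluation protocol and metrics.

The healthy class typically outnumbers the disease class by a wide margin
(595 vs 119 in the reference cohort).  To evaluate on balanced data the
healthy set is shuffled once and cut into equal parts (five by default, each
the size of the disease set); each part is paired with the whole disease set
to form one round's dataset, which is then split in half per class —
``floor(c/2)`` samples train, the rest test, so 119-per-class rounds give
118 training and 120 testing samples.  Reported metrics are the arithmetic
mean of the per-round accuracy, sensitivity (true-positive rate on disease),
and specificity (true-negative rate on healthy); pooled-confusion metrics
are reported alongside.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import make_classifier
from .errors import InputValidationError
from .types import DEFAULT_FEATURE_BLOCKS, LabeledDataset

__all__ = [
    "SplitPlan",
    "MetricReport",
    "make_split_plan",
    "compute_metrics",
    "expand_grid",
    "block_combinations",
    "run_rounds",
    "run_experiment",
    "summarize",
]


@dataclass
class SplitPlan:
    """Round-wise train/test indices over a disease+healthy dataset.

    Indices refer to a dataset laid out as disease samples first
    (0 .. n_disease-1) followed by healthy samples.
    """

    rounds: list[tuple[np.ndarray, np.ndarray]]
    parts: list[np.ndarray] = field(repr=False)
    seed: int = 0


def make_split_plan(
    n_disease: int, n_healthy: int, parts: int = 5, seed: int = 0
) -> SplitPlan:
    """Build the balanced repeated-holdout plan.

    The healthy indices are shuffled with ``seed`` and cut into ``parts``
    equal parts; round r pairs part r with all disease samples and halves
    each class (``floor(c/2)`` train) with a per-round seed ``seed + r``.
    """
    if n_disease < 2:
        raise InputValidationError("need at least 2 disease samples")
    if parts < 1 or n_healthy % parts != 0:
        raise InputValidationError(
            f"{n_healthy} healthy samples not divisible into {parts} equal parts"
        )
    rng = np.random.default_rng(seed)
    healthy = n_disease + rng.permutation(n_healthy)
    part_list = [np.sort(p) for p in np.split(healthy, parts)]
    disease = np.arange(n_disease)

    rounds = []
    for r, part in enumerate(part_list):
        round_rng = np.random.default_rng(seed + r)
        train_idx, test_idx = [], []
        for cls_idx in (disease, part):
            perm = round_rng.permutation(cls_idx)
            half = len(cls_idx) // 2
            train_idx.append(perm[:half])
            test_idx.append(perm[half:])
        rounds.append(
            (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))
        )
    return SplitPlan(rounds=rounds, parts=part_list, seed=seed)


@dataclass
class MetricReport:
    """Confusion counts and the three ratios, disease as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self):
        def ratio(num, den, name):
            if den == 0:
                warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
                return float("nan")
            return num / den

        total = self.tp + self.tn + self.fp + self.fn
        self.accuracy = ratio(self.tp + self.tn, total, "accuracy")
        self.sensitivity = ratio(self.tp, self.tp + self.fn, "sensitivity")
        self.specificity = ratio(self.tn, self.tn + self.fp, "specificity")


def compute_metrics(predictions, truth, positive) -> MetricReport:
    """Accuracy, sensitivity, and specificity from two label sequences."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise InputValidationError("predictions and truth must have equal length")
    labels = set(np.unique(truth)) | set(np.unique(predictions))
    if len(labels - {positive}) > 1:
        raise InputValidationError(
            f"labels {sorted(map(str, labels))} are not binary around {positive!r}"
        )
    pos_t = truth == positive
    pos_p = predictions == positive
    return MetricReport(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def expand_grid(spec) -> list[float]:
    """Expand a parameter grid written as values and "a:step:b" range strings.

    ``[0.001, 0.01, "0.1:0.1:1.0"]`` expands to 12 values: the two literals
    plus 0.1, 0.2, ..., 1.0 (both endpoints included).
    """
    out: list[float] = []
    for item in spec:
        if isinstance(item, str) and ":" in item:
            start, step, stop = (float(v) for v in item.split(":"))
            n = int(round((stop - start) / step)) + 1
            out.extend(round(start + i * step, 12) for i in range(n))
        else:
            out.append(float(item))
    return out


def block_combinations(
    blocks: tuple[str, ...] = DEFAULT_FEATURE_BLOCKS,
) -> list[tuple[str, ...]]:
    """All non-empty subsets of the employed blocks, order preserved."""
    combos = []
    for r in range(1, len(blocks) + 1):
        combos.extend(itertools.combinations(blocks, r))
    return combos


def run_rounds(
    dataset: LabeledDataset,
    plan: SplitPlan,
    classifier: str,
    params: dict,
    positive,
) -> list[MetricReport]:
    """Fit and score the classifier on every round of the plan."""
    reports = []
    for train_idx, test_idx in plan.rounds:
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        clf = make_classifier(classifier, **params)
        clf.fit(*train.to_sklearn())
        preds = clf.predict(test.features.T)
        reports.append(compute_metrics(preds, test.labels, positive))
    return reports


def run_experiment(
    dataset: LabeledDataset,
    combinations: list[tuple[str, ...]],
    classifier: str,
    param_grid: dict[str, list],
    plan: SplitPlan,
    positive,
) -> pd.DataFrame:
    """Sweep block combinations and parameter grids under the split plan.

    Returns a tidy per-round table with columns combination, classifier,
    the swept parameters, round, accuracy, sensitivity, specificity.
    """
    if not combinations:
        raise InputValidationError("need at least one block combination")
    names = sorted(param_grid)
    grids = [param_grid[k] for k in names]
    rows = []
    for combo in combinations:
        sub = dataset.select_blocks(combo)
        for point in itertools.product(*grids):
            params = dict(zip(names, point))
            reports = run_rounds(sub, plan, classifier, params, positive)
            for r, rep in enumerate(reports):
                rows.append(
                    {
                        "combination": "+".join(combo),
                        "classifier": classifier,
                        **params,
                        "round": r,
                        "accuracy": rep.accuracy,
                        "sensitivity": rep.sensitivity,
                        "specificity": rep.specificity,
                    }
                )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-rounds summary (the primary report) per configuration."""
    keys = [
        c
        for c in results.columns
        if c not in ("round", "accuracy", "sensitivity", "specificity")
    ]
    return (
        results.groupby(keys, as_index=False)[
            ["accuracy", "sensitivity", "specificity"]
        ]
        .mean()
        .assign(error=lambda df: 1.0 - df["accuracy"])
    )
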